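"""Teacher-forced training with warmup/cosine learning-rate schedule.

Training minimizes cross-entropy between the decoder's softmax scores and
the one-hot ground-truth peptide (stop token included). The learning rate
rises linearly from zero to its peak over the warmup steps, then follows a
cosine decay to zero at the final step. The returned model carries the
weight snapshot with the lowest validation loss.

Train/validation splits are peptide-disjoint: all spectra generated by the
same peptide land in the same split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelConfig, SpectrumTransformer, collate
from .nn import AdamW
from .spectra_io import Spectrum

logger = logging.getLogger(__name__)


def learning_rate(step: int, peak_lr: float, warmup_steps: int, total_steps: int) -> float:
    """LR at a given (zero-based) step: linear warmup then cosine decay."""
    if step < warmup_steps:
        return peak_lr * step / max(warmup_steps, 1)
    span = max(total_steps - warmup_steps, 1)
    frac = min((step - warmup_steps) / span, 1.0)
    return peak_lr * 0.5 * (1.0 + np.cos(np.pi * frac))


def peptide_disjoint_split(
    spectra: list[Spectrum],
    fractions: tuple[float, ...] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> list[list[Spectrum]]:
    """Partition spectra so each unique peptide occurs in exactly one part."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    by_peptide: dict[str, list[Spectrum]] = {}
    for s in spectra:
        if s.annotation is None:
            raise ValueError("peptide-disjoint split requires annotated spectra")
        by_peptide.setdefault(str(s.annotation), []).append(s)
    peptides = sorted(by_peptide)
    rng = np.random.default_rng(seed)
    rng.shuffle(peptides)
    bounds = np.floor(np.cumsum(fractions) * len(peptides)).astype(int)
    parts: list[list[Spectrum]] = []
    start = 0
    for end in bounds:
        part = []
        for pep in peptides[start:end]:
            part.extend(by_peptide[pep])
        parts.append(part)
        start = end
    return parts


def validate_corpus(spectra: list[Spectrum]) -> None:
    for s in spectra:
        if s.annotation is None:
            raise ValueError(f"training spectrum {s.identifier!r} lacks an annotation")
        if not s.peaks:
            raise ValueError(f"training spectrum {s.identifier!r} has no peaks")


def _evaluate_teacher_forced(
    model: SpectrumTransformer, spectra: list[Spectrum], batch_size: int
) -> tuple[float, float]:
    losses, accs, weights = [], [], []
    for i in range(0, len(spectra), batch_size):
        batch = collate(spectra[i : i + batch_size])
        loss, acc = model.forward_loss(batch)
        n = batch.mz.shape[0]
        losses.append(float(loss.data) * n)
        accs.append(acc * n)
        weights.append(n)
    total = sum(weights)
    return sum(losses) / total, sum(accs) / total


@dataclass
class TrainResult:
    model: SpectrumTransformer
    history: pd.DataFrame
    best_val_loss: float
    best_step: int


def _clip_gradients(params, max_norm: float) -> None:
    total = 0.0
    grads = [p.grad for p in params if p.grad is not None]
    for g in grads:
        total += float((g * g).sum())
    norm = np.sqrt(total)
    if norm > max_norm:
        factor = max_norm / norm
        for g in grads:
            g *= factor


def train(
    corpus: list[Spectrum],
    cfg: ModelConfig,
    n_epochs: int = 1,
    validation: list[Spectrum] | None = None,
    val_fraction: float = 0.1,
    model: SpectrumTransformer | None = None,
    learning_rate_peak: float | None = None,
    warmup_steps: int | None = None,
    val_every: int | None = None,
    grad_clip: float = 5.0,
    log_path=None,
) -> TrainResult:
    """Train (or fine-tune, by passing an existing ``model``) on annotated,
    preprocessed spectra.

    Checkpoint selection is by minimum validation loss, evaluated every
    ``val_every`` optimizer steps (default: once per epoch) and at the end.
    """
    validate_corpus(corpus)
    if validation is None:
        train_set, validation = peptide_disjoint_split(
            corpus, (1.0 - val_fraction, val_fraction), seed=cfg.seed
        )
    else:
        train_set = list(corpus)
        validate_corpus(validation)
    if not train_set or not validation:
        raise ValueError("empty training or validation split")

    if model is None:
        model = SpectrumTransformer(cfg)
    peak_lr = learning_rate_peak if learning_rate_peak is not None else cfg.peak_lr
    warmup = warmup_steps if warmup_steps is not None else cfg.warmup_steps

    steps_per_epoch = int(np.ceil(len(train_set) / cfg.batch_size))
    total_steps = steps_per_epoch * n_epochs
    # the publication-scale warmup is longer than a toy run; never spend more
    # than a tenth of the run warming up
    warmup = min(warmup, max(total_steps // 10, 1))
    if val_every is None:
        val_every = min(cfg.val_interval, steps_per_epoch)

    optimizer = AdamW(
        model.parameters(), lr=0.0, weight_decay=cfg.weight_decay
    )
    rng = np.random.default_rng(cfg.seed + 1)

    history_rows = []
    best_val = np.inf
    best_step = -1
    best_weights = model.copy_weights()
    step = 0

    for epoch in range(n_epochs):
        order = rng.permutation(len(train_set))
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch = collate([train_set[i] for i in idx])
            optimizer.lr = learning_rate(step, peak_lr, warmup, total_steps)
            optimizer.zero_grad()
            loss, acc = model.forward_loss(batch)
            loss.backward()
            _clip_gradients(optimizer.params, grad_clip)
            optimizer.step()
            step += 1
            if step % val_every == 0 or step == total_steps:
                val_loss, val_acc = _evaluate_teacher_forced(
                    model, validation, cfg.batch_size
                )
                history_rows.append(
                    {
                        "step": step,
                        "epoch": epoch,
                        "lr": optimizer.lr,
                        "train_loss": float(loss.data),
                        "train_acc": acc,
                        "val_loss": val_loss,
                        "val_acc": val_acc,
                    }
                )
                logger.info(
                    "step %d lr %.2e train %.4f val %.4f acc %.3f",
                    step, optimizer.lr, float(loss.data), val_loss, val_acc,
                )
                if val_loss < best_val:
                    best_val = val_loss
                    best_step = step
                    best_weights = model.copy_weights()

    model.load_state_dict(best_weights)
    history = pd.DataFrame(history_rows)
    if log_path is not None:
        history.to_csv(log_path, index=False)
    return TrainResult(model=model, history=history, best_val_loss=best_val, best_step=best_step)
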