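"""Encoder-decoder transformer for de novo peptide sequencing.

The encoder ingests a spectrum as an unordered bag of peak embeddings
(sinusoidal m/z encoding plus a learned linear projection of intensity; no
positional encoding, so the peak representation is permutation-equivariant).
The decoder autoregressively predicts the peptide from C-terminus to
N-terminus, conditioned on the contextualized peak encodings and a precursor
embedding (sinusoidal encoding of the neutral precursor mass plus a learned
per-charge vector) that occupies the first decoder position.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .encoding import EncodingConfig, embed_mz, positional_encoding
from .spectra_io import Spectrum
from .vocabulary import (
    MAX_PEPTIDE_LENGTH,
    STOP_INDEX,
    VOCAB_SIZE,
    PeptideSequence,
    token_ids,
    vocabulary_hash,
)

NEG_INF = -1e9
MAX_CHARGE = 10


@dataclass
class ModelConfig:
    n_layers: int = 9
    d: int = 512
    n_heads: int = 8
    d_ff: int | None = None  # defaults to 2*d
    vocab_size: int = VOCAB_SIZE
    max_length: int = MAX_PEPTIDE_LENGTH
    batch_size: int = 32
    peak_lr: float = 5e-4
    weight_decay: float = 1e-5
    warmup_steps: int = 100_000
    fine_tune_lr: float = 5e-5
    val_interval: int = 50_000
    dropout: float = 0.0
    norm_first: bool = False
    # sinusoidal m/z encoding wavelength band (m/z units)
    lambda_min: float = 0.001
    lambda_max: float = 10_000.0
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        if self.d % self.n_heads:
            raise ValueError("d must be divisible by n_heads")
        if self.d_ff is None:
            self.d_ff = 2 * self.d

    @property
    def np_dtype(self):
        return np.dtype(self.dtype).type


@dataclass
class Batch:
    """Collated model inputs for a list of annotated, preprocessed spectra."""

    mz: np.ndarray  # (B, K) padded with zeros
    intensity: np.ndarray  # (B, K)
    peak_mask: np.ndarray  # (B, K) bool, True where a real peak exists
    precursor_mass: np.ndarray  # (B,)
    precursor_charge: np.ndarray  # (B,) int
    dec_in: np.ndarray | None = None  # (B, L) internal C->N token ids
    labels: np.ndarray | None = None  # (B, L+1), -1 marks padding


def internal_order_ids(p: PeptideSequence) -> list[int]:
    """Token ids in the decoder's internal C->N order (reporting order
    reversed; an N-terminal modification is therefore decoded last)."""
    return token_ids(p)[::-1]


def collate(spectra: list[Spectrum], with_targets: bool = True) -> Batch:
    B = len(spectra)
    if B == 0:
        raise ValueError("empty batch")
    K = max(len(s.peaks) for s in spectra)
    mz = np.zeros((B, K))
    inten = np.zeros((B, K))
    mask = np.zeros((B, K), dtype=bool)
    pmass = np.zeros(B)
    pcharge = np.zeros(B, dtype=np.int64)
    for i, s in enumerate(spectra):
        k = len(s.peaks)
        if k == 0:
            raise ValueError(f"spectrum {s.identifier!r} has no peaks")
        mz[i, :k] = s.mz_array
        inten[i, :k] = s.intensity_array
        mask[i, :k] = True
        pmass[i] = s.precursor.mass
        pcharge[i] = s.precursor.charge
    batch = Batch(mz, inten, mask, pmass, pcharge)
    if with_targets:
        seqs = []
        for s in spectra:
            if s.annotation is None:
                raise ValueError(f"spectrum {s.identifier!r} lacks an annotation")
            seqs.append(internal_order_ids(s.annotation))
        L = max(len(q) for q in seqs)
        dec_in = np.zeros((B, L), dtype=np.int64)
        labels = np.full((B, L + 1), -1, dtype=np.int64)
        for i, q in enumerate(seqs):
            dec_in[i, : len(q)] = q
            labels[i, : len(q)] = q
            labels[i, len(q)] = STOP_INDEX
        batch.dec_in = dec_in
        batch.labels = labels
    return batch


def _causal_mask(T: int, dtype) -> np.ndarray:
    m = np.triu(np.full((T, T), NEG_INF, dtype=dtype), k=1)
    return m[None, None]


def _key_mask(peak_mask: np.ndarray, dtype) -> np.ndarray:
    return np.where(peak_mask[:, None, None, :], 0.0, NEG_INF).astype(dtype)


class SpectrumTransformer(nn.Module):
    def __init__(self, config: ModelConfig):
        self.config = config
        dtype = config.np_dtype
        rng = np.random.default_rng(config.seed)
        self.enc_cfg = EncodingConfig(
            d=config.d, lambda_max=config.lambda_max, lambda_min=config.lambda_min
        )
        self.intensity_proj = nn.Linear(1, config.d, rng, dtype)
        # normalized intensities are individually tiny (they sum to 1 over
        # ~10^2 peaks); widen the projection init so intensity is visible to
        # attention from the first steps
        self.intensity_proj.W.data *= 10.0
        self.charge_embedding = nn.EmbeddingTable(MAX_CHARGE, config.d, rng, dtype)
        self.encoder_layers = [
            nn.EncoderLayer(
                config.d, config.n_heads, config.d_ff, rng, dtype, config.norm_first
            )
            for _ in range(config.n_layers)
        ]
        self.token_embedding = nn.EmbeddingTable(config.vocab_size, config.d, rng, dtype)
        self.decoder_layers = [
            nn.DecoderLayer(
                config.d, config.n_heads, config.d_ff, rng, dtype, config.norm_first
            )
            for _ in range(config.n_layers)
        ]
        self.output_proj = nn.Linear(config.d, config.vocab_size, rng, dtype)
        # start near-uniform over the vocabulary: a fresh model's first-batch
        # cross-entropy is then ~ln(v), and early training is better behaved
        self.output_proj.W.data *= 0.1
        # positional table covers the precursor slot + max_length tokens
        self._pos_table = positional_encoding(
            config.max_length + 2, self.enc_cfg
        ).astype(dtype)

    # ------------------------------------------------------------------ encoder

    def embed_peaks(self, mz: np.ndarray, intensity: np.ndarray) -> nn.Tensor:
        dtype = self.config.np_dtype
        fixed = embed_mz(mz, self.enc_cfg).astype(dtype)
        learned = self.intensity_proj(nn.Tensor(intensity[..., None].astype(dtype)))
        return nn.add(learned, nn.Tensor(fixed))

    def encode(self, batch: Batch) -> tuple[nn.Tensor, np.ndarray]:
        dtype = self.config.np_dtype
        x = self.embed_peaks(batch.mz, batch.intensity)
        key_mask = _key_mask(batch.peak_mask, dtype)
        for layer in self.encoder_layers:
            x = layer(x, key_mask)
        return x, key_mask

    def encode_spectrum(self, s: Spectrum) -> np.ndarray:
        """Contextualized peak encodings for one preprocessed spectrum (k, d)."""
        if not s.peaks:
            raise ValueError("cannot encode a spectrum with zero peaks")
        batch = collate([s], with_targets=False)
        memory, _ = self.encode(batch)
        return memory.data[0]

    # ------------------------------------------------------------------ decoder

    def embed_precursor(self, mass: np.ndarray, charge: np.ndarray) -> nn.Tensor:
        dtype = self.config.np_dtype
        charge = np.clip(np.asarray(charge), 1, MAX_CHARGE)
        fixed = embed_mz(np.asarray(mass, dtype=np.float64), self.enc_cfg).astype(dtype)
        learned = self.charge_embedding(charge - 1)
        return nn.add(learned, nn.Tensor(fixed))

    def decode(
        self,
        memory: nn.Tensor,
        memory_mask: np.ndarray,
        precursor_mass: np.ndarray,
        precursor_charge: np.ndarray,
        dec_in: np.ndarray,
    ) -> nn.Tensor:
        """Logits (B, L+1, v): position t scores the token following the
        first t decoded tokens (position 0 is conditioned on the precursor
        alone)."""
        dtype = self.config.np_dtype
        B, L = dec_in.shape
        prec = nn.reshape(
            self.embed_precursor(precursor_mass, precursor_charge), (B, 1, self.config.d)
        )
        if L:
            # decoder input sequence: [precursor, tok_1, ..., tok_L]
            x = nn.concat_seq(prec, self.token_embedding(dec_in))
        else:
            x = prec
        T = L + 1
        x = nn.add(x, nn.Tensor(self._pos_table[None, :T]))
        causal = _causal_mask(T, dtype)
        for layer in self.decoder_layers:
            x = layer(x, memory, causal, memory_mask)
        return self.output_proj(x)

    def decode_step(
        self,
        prefix_ids: list[int],
        memory: nn.Tensor,
        memory_mask: np.ndarray,
        precursor_mass: float,
        precursor_charge: int,
    ) -> np.ndarray:
        """Unnormalized next-token scores (v,) after a C->N prefix."""
        if len(prefix_ids) >= self.config.max_length + 1:
            raise ValueError("prefix at maximum length; decoding must terminate")
        dec_in = np.asarray([prefix_ids], dtype=np.int64).reshape(1, len(prefix_ids))
        logits = self.decode(
            memory,
            memory_mask,
            np.asarray([precursor_mass]),
            np.asarray([precursor_charge]),
            dec_in,
        )
        return logits.data[0, -1]

    # ------------------------------------------------------------------ training

    def forward_loss(self, batch: Batch) -> tuple[nn.Tensor, float]:
        """Teacher-forced cross-entropy and token accuracy for one batch."""
        memory, key_mask = self.encode(batch)
        mem_mask = key_mask  # (B, 1, 1, K) broadcasts over decoder queries
        logits = self.decode(
            memory,
            mem_mask,
            batch.precursor_mass,
            batch.precursor_charge,
            batch.dec_in,
        )
        loss = nn.cross_entropy(logits, batch.labels, ignore_index=-1)
        valid = batch.labels >= 0
        pred = logits.data.argmax(axis=-1)
        acc = float((pred[valid] == batch.labels[valid]).mean()) if valid.any() else 0.0
        return loss, acc

    # ------------------------------------------------------------------ misc

    def count_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            if name not in state:
                raise KeyError(f"missing parameter {name!r} in checkpoint")
            if state[name].shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name!r}: checkpoint "
                    f"{state[name].shape} vs model {p.data.shape}"
                )
            p.data = state[name].astype(p.data.dtype)

    def copy_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.state_dict().items()}


def count_parameters(cfg: ModelConfig | None = None) -> int:
    """Trainable parameter count for a configuration (defaults to the
    publication-scale model: 9+9 layers, d=512, 8 heads, 28 tokens)."""
    return SpectrumTransformer(cfg or ModelConfig()).count_parameters()


def save_checkpoint(model: SpectrumTransformer, path) -> None:
    meta = {"config": asdict(model.config), "vocab_hash": vocabulary_hash()}
    np.savez(
        path,
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **model.state_dict(),
    )


def load_checkpoint(path, expect_config: ModelConfig | None = None) -> SpectrumTransformer:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    if meta["vocab_hash"] != vocabulary_hash():
        raise ValueError("checkpoint vocabulary does not match this package")
    cfg = ModelConfig(**meta["config"])
    if expect_config is not None:
        for key in ("n_layers", "d", "n_heads", "d_ff", "vocab_size"):
            if getattr(expect_config, key) != getattr(cfg, key):
                raise ValueError(
                    f"config mismatch: checkpoint {key}={getattr(cfg, key)} "
                    f"vs requested {getattr(expect_config, key)}"
                )
    model = SpectrumTransformer(cfg)
    model.load_state_dict(state)
    return model
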