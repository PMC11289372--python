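"""Scikit-learn style estimator wrapping the full sequencing pipeline.

``DeNovoSequencer`` is fit on annotated MS/MS spectra and predicts peptide
sequences for new spectra; it composes with sklearn model selection via
``get_params``/``set_params``. The heavy lifting lives in the library
modules (:mod:`massnovo.training`, :mod:`massnovo.decoder`); this class only
validates inputs, wires configuration, and stores fitted state.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .decoder import FilterConfig, Prediction, sequence_spectra
from .evaluation import MatchTolerances, evaluate
from .model import ModelConfig, SpectrumTransformer
from .spectra_io import Spectrum, preprocess_spectrum
from .training import train, validate_corpus


class DeNovoSequencer(BaseEstimator):
    """Transformer-based de novo peptide sequencer.

    Parameters mirror the model and decoding configuration; defaults are the
    publication-scale settings (9+9 layers, d=512, 8 heads). Pass smaller
    values for desk-scale experiments.

    After :meth:`fit`, the trained network is in ``model_`` and the training
    history in ``history_``.
    """

    def __init__(
        self,
        n_layers: int = 9,
        d_model: int = 512,
        n_heads: int = 8,
        d_ff: int | None = None,
        batch_size: int = 32,
        peak_lr: float = 5e-4,
        weight_decay: float = 1e-5,
        warmup_steps: int = 100_000,
        n_epochs: int = 1,
        beam_width: int = 5,
        precursor_ppm: float = 30.0,
        isotope_offsets: tuple[int, ...] = (0, 1),
        preprocess: bool = True,
        random_state: int = 0,
    ):
        self.n_layers = n_layers
        self.d_model = d_model
        self.n_heads = n_heads
        self.d_ff = d_ff
        self.batch_size = batch_size
        self.peak_lr = peak_lr
        self.weight_decay = weight_decay
        self.warmup_steps = warmup_steps
        self.n_epochs = n_epochs
        self.beam_width = beam_width
        self.precursor_ppm = precursor_ppm
        self.isotope_offsets = isotope_offsets
        self.preprocess = preprocess
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            n_layers=self.n_layers,
            d=self.d_model,
            n_heads=self.n_heads,
            d_ff=self.d_ff,
            batch_size=self.batch_size,
            peak_lr=self.peak_lr,
            weight_decay=self.weight_decay,
            warmup_steps=self.warmup_steps,
            seed=self.random_state,
        )

    def _filter_config(self) -> FilterConfig:
        return FilterConfig(
            epsilon_ppm=self.precursor_ppm,
            isotope_offsets=tuple(self.isotope_offsets),
        )

    def _prepare(self, X: list[Spectrum]) -> list[Spectrum]:
        if not isinstance(X, (list, tuple)) or not all(
            isinstance(s, Spectrum) for s in X
        ):
            raise TypeError("X must be a list of Spectrum objects")
        if self.preprocess:
            X = [preprocess_spectrum(s) for s in X]
        return [s for s in X if not s.flagged_empty]

    # ------------------------------------------------------------------

    def fit(self, X: list[Spectrum], y=None, validation: list[Spectrum] | None = None):
        """Train on annotated spectra. ``y`` may supply peptide annotations
        (as `PeptideSequence` or strings) for spectra lacking them."""
        X = list(X)
        if y is not None:
            from .vocabulary import PeptideSequence, tokenize
            from dataclasses import replace

            if len(y) != len(X):
                raise ValueError("X and y length mismatch")
            X = [
                replace(s, annotation=a if isinstance(a, PeptideSequence) else tokenize(a))
                for s, a in zip(X, y)
            ]
        X = self._prepare(X)
        validate_corpus(X)
        if validation is not None:
            validation = self._prepare(list(validation))
        result = train(
            X,
            self._model_config(),
            n_epochs=self.n_epochs,
            validation=validation,
        )
        self.model_ = result.model
        self.history_ = result.history
        self.best_val_loss_ = result.best_val_loss
        self.n_parameters_ = result.model.count_parameters()
        return self

    def predict(self, X: list[Spectrum]) -> list[Prediction]:
        self._check_fitted()
        return sequence_spectra(
            self._prepare(list(X)),
            self.model_,
            k=self.beam_width,
            filt=self._filter_config(),
        )

    def score(self, X: list[Spectrum], y=None) -> float:
        """Peptide-level precision at full coverage on annotated spectra."""
        self._check_fitted()
        X = list(X)
        annotations = {}
        for i, s in enumerate(X):
            truth = s.annotation
            if truth is None and y is not None:
                from .vocabulary import tokenize

                truth = y[i] if not isinstance(y[i], str) else tokenize(y[i])
            if truth is None:
                raise ValueError("scoring requires annotated spectra")
            annotations[s.identifier] = truth
        preds = self.predict(X)
        result = evaluate(preds, annotations, MatchTolerances(), n_orig=len(X))
        return result.counts.peptide_precision or 0.0

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit() first")
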