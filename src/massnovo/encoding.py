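"""Fixed sinusoidal encodings for m/z values, masses, and decoder positions.

An m/z value is projected to a d-dimensional vector using sine waveforms for
the first ``d_sin = ceil(d/2)`` features and cosine waveforms for the
remaining ``d_cos = d - d_sin``, with wavelengths spaced geometrically from
``lambda_min`` (0.001 m/z) to ``lambda_max`` (10,000 m/z), endpoints
included. Feature i (zero-based) of the sine block divides the input by
``(lambda_min / 2π) · (lambda_max / lambda_min)^(i / (d_sin - 1))``; the
cosine block uses exponent ``(i - d_sin) / (d_cos - 1)``. High-frequency
features resolve fine mass differences (isotopes, near-isobaric residues)
while low-frequency features encode coarse position on the m/z axis.

The same machinery encodes the precursor's neutral mass and, over integer
sequence indices, the decoder's positional embedding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class EncodingConfig:
    d: int = 512
    lambda_max: float = 10_000.0
    lambda_min: float = 0.001

    def __post_init__(self):
        if self.d < 2:
            raise ValueError("embedding dimension must be >= 2")
        if not self.lambda_max > self.lambda_min > 0:
            raise ValueError("require lambda_max > lambda_min > 0")

    @property
    def d_sin(self) -> int:
        return math.ceil(self.d / 2)

    @property
    def d_cos(self) -> int:
        return self.d - self.d_sin


def _wavelength_divisors(cfg: EncodingConfig) -> tuple[np.ndarray, np.ndarray]:
    ratio = cfg.lambda_max / cfg.lambda_min
    base = cfg.lambda_min / (2.0 * np.pi)

    def exponents(n: int) -> np.ndarray:
        i = np.arange(n, dtype=np.float64)
        # n == 1 would divide by zero; a single waveform sits at lambda_min
        return i / (n - 1) if n > 1 else np.zeros(n)

    sin_div = base * ratio ** exponents(cfg.d_sin)
    cos_div = base * ratio ** exponents(cfg.d_cos)
    return sin_div, cos_div


def embed_mz(m, cfg: EncodingConfig = EncodingConfig()) -> np.ndarray:
    """Sinusoidally encode m/z value(s) to shape ``(..., d)``.

    Deterministic, no trainable state; all outputs lie in [-1, 1].
    """
    m = np.asarray(m, dtype=np.float64)
    if np.any(m < 0):
        raise ValueError("m/z values must be non-negative")
    sin_div, cos_div = _wavelength_divisors(cfg)
    sin_part = np.sin(m[..., None] / sin_div)
    cos_part = np.cos(m[..., None] / cos_div)
    return np.concatenate([sin_part, cos_part], axis=-1)


def positional_encoding(n_positions: int, cfg: EncodingConfig) -> np.ndarray:
    """Sinusoidal embedding of integer sequence positions 0..n-1, shape (n, d)."""
    return embed_mz(np.arange(n_positions, dtype=np.float64), cfg)
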