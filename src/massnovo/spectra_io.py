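"""Spectrum containers, MGF reading/writing, preprocessing, prediction tables.

Raw MS/MS peak lists are read from Mascot Generic Format (MGF) files via
pyteomics. Preprocessing applies, in order: an m/z range filter, removal of
peaks near the precursor, a relative-intensity floor, a cap on the number of
peaks, and finally square-root transformation of intensities followed by
normalization to unit sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .vocabulary import PROTON_MASS, PeptideSequence, tokenize

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError("peak m/z must be positive")
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")


@dataclass(frozen=True)
class PrecursorInfo:
    """Observed precursor m/z and charge; neutral mass is derived."""

    mz_observed: float
    charge: int

    def __post_init__(self):
        if self.charge < 1:
            raise ValueError("precursor charge must be >= 1")
        if self.mass <= 0:
            raise ValueError("non-positive precursor mass")

    @property
    def mass(self) -> float:
        """Neutral monoisotopic mass: charge * (m/z - proton)."""
        return self.charge * (self.mz_observed - PROTON_MASS)


@dataclass
class Spectrum:
    peaks: list[Peak]
    precursor: PrecursorInfo
    identifier: str = ""
    annotation: PeptideSequence | None = None
    preprocessed: bool = False
    low_quality: bool = False
    flagged_empty: bool = False

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks], dtype=np.float64)

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks], dtype=np.float64)


@dataclass(frozen=True)
class PreprocessConfig:
    mz_min: float = 50.0
    mz_max: float = 2500.0
    precursor_exclusion_tol: float = 2.0  # Th, around the precursor m/z
    rel_intensity_min: float = 0.01
    max_peaks: int = 150
    min_peaks_quality: int = 20


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF file into a list of raw (unpreprocessed) spectra.

    One spectrum per BEGIN IONS/END IONS block. Blocks without a charge are
    skipped with a warning; an optional SEQ line is kept as the ground-truth
    annotation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spectra: list[Spectrum] = []
    with _mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry.get("params", {})
            title = str(params.get("title", f"scan={i}"))
            pepmass = params.get("pepmass")
            if pepmass is None:
                raise ValueError(f"malformed MGF block (no PEPMASS): {title}")
            mz_obs = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            charge_field = params.get("charge")
            if not charge_field:
                logger.warning("skipping spectrum %r: missing charge", title)
                continue
            charge = int(charge_field[0])
            peaks = [
                Peak(float(m), float(h))
                for m, h in zip(entry["m/z array"], entry["intensity array"])
            ]
            annotation = None
            seq = params.get("seq")
            if seq:
                annotation = tokenize(str(seq))
            spectra.append(
                Spectrum(
                    peaks=peaks,
                    precursor=PrecursorInfo(mz_obs, charge),
                    identifier=title,
                    annotation=annotation,
                )
            )
    return spectra


def write_mgf(spectra: list[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF; annotations are stored on SEQ lines."""
    entries = []
    for s in spectra:
        params = {
            "title": s.identifier,
            "pepmass": s.precursor.mz_observed,
            "charge": f"{s.precursor.charge}+",
        }
        if s.annotation is not None:
            params["seq"] = str(s.annotation)
        entries.append(
            {
                "params": params,
                "m/z array": s.mz_array,
                "intensity array": s.intensity_array,
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def preprocess_spectrum(s: Spectrum, cfg: PreprocessConfig = PreprocessConfig()) -> Spectrum:
    """Filter and normalize a spectrum's peaks.

    Steps, in order: keep peaks inside [mz_min, mz_max] (inclusive); drop
    peaks within ``precursor_exclusion_tol`` of the precursor m/z; drop peaks
    with intensity strictly below ``rel_intensity_min`` of the base peak;
    keep the ``max_peaks`` most intense (ties broken toward lower m/z); then
    replace intensities by sqrt(I) / sum(sqrt(I)).

    A spectrum with zero surviving peaks is returned flagged
    (``flagged_empty``) rather than raising. Spectra with fewer than
    ``min_peaks_quality`` surviving peaks are flagged ``low_quality`` but are
    still eligible for sequencing.
    """
    if s.preprocessed:
        # intensities are already sqrt-normalized; re-applying the transform
        # would change them, so preprocessing is a no-op on processed spectra
        return s
    if not s.peaks:
        raise ValueError("cannot preprocess a spectrum with no raw peaks")
    mz = s.mz_array
    inten = s.intensity_array

    keep = (mz >= cfg.mz_min) & (mz <= cfg.mz_max)
    keep &= np.abs(mz - s.precursor.mz_observed) > cfg.precursor_exclusion_tol
    mz, inten = mz[keep], inten[keep]

    if mz.size:
        keep = inten >= cfg.rel_intensity_min * inten.max()
        mz, inten = mz[keep], inten[keep]

    if mz.size == 0:
        logger.warning("spectrum %r: no peaks survive preprocessing", s.identifier)
        return replace(
            s, peaks=[], preprocessed=True, flagged_empty=True, low_quality=True
        )

    if mz.size > cfg.max_peaks:
        # most intense first; ties at the boundary broken by lower m/z
        order = np.lexsort((mz, -inten))[: cfg.max_peaks]
        mz, inten = mz[order], inten[order]

    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]

    inten = np.sqrt(inten)
    total = inten.sum()
    # all-zero intensities carry no abundance information: weight uniformly
    inten = inten / total if total > 0 else np.full_like(inten, 1.0 / inten.size)

    return replace(
        s,
        peaks=[Peak(float(m), float(h)) for m, h in zip(mz, inten)],
        preprocessed=True,
        flagged_empty=False,
        low_quality=mz.size < cfg.min_peaks_quality,
    )


PREDICTION_COLUMNS = [
    "spectrum_id",
    "peptide",
    "peptide_score",
    "aa_scores",
    "passes_filter",
    "delta_m_ppm",
]


def write_predictions(preds, path: str | Path) -> None:
    """Write predictions as a tab-delimited table (one row per spectrum)."""
    rows = []
    for p in preds:
        rows.append(
            {
                "spectrum_id": p.spectrum_id,
                "peptide": str(p.peptide),
                "peptide_score": f"{p.peptide_score:.6g}",
                "aa_scores": ",".join(f"{a:.6g}" for a in p.aa_scores),
                "passes_filter": p.passes_filter,
                "delta_m_ppm": f"{p.delta_m_ppm:.6g}",
            }
        )
    df = pd.DataFrame(rows, columns=PREDICTION_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_predictions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"peptide": str}, keep_default_na=False)
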