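"""Mass-tolerance evaluation metrics: amino-acid and peptide precision,
coverage, and precision-coverage curves with average precision.

A predicted amino acid counts as matched when (1) its residue mass differs
from the corresponding ground-truth residue by < 0.1 Da, and (2) either the
preceding prefix masses or the following suffix masses of the two sequences
differ by no more than 0.5 Da. Correspondence is established by a greedy
two-pass mass alignment: a forward pass over prefix masses, then a backward
pass over suffix masses for the positions the forward pass did not reach.
Isobaric substitutions (I/L, and e.g. deamidated N vs D) therefore count as
matches. A peptide is correct when all of its amino acids are matched and
its length equals the ground-truth length.

Average precision is the trapezoidal area under the precision-coverage
curve obtained by sorting predictions by confidence (filter-failing
predictions ranked last).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decoder import Prediction, rank_predictions
from .vocabulary import PeptideSequence


@dataclass(frozen=True)
class MatchTolerances:
    aa_mass_tol: float = 0.1  # Da, strict <
    context_mass_tol: float = 0.5  # Da, <=

    def __post_init__(self):
        if self.aa_mass_tol <= 0 or self.context_mass_tol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class EvalCounts:
    n_match_aa: int = 0
    n_pred_aa: int = 0
    n_orig_aa: int = 0
    n_match_pep: int = 0
    n_pred_pep: int = 0
    n_orig_pep: int = 0

    @property
    def aa_precision(self) -> float | None:
        return self.n_match_aa / self.n_pred_aa if self.n_pred_aa else None

    @property
    def peptide_precision(self) -> float | None:
        return self.n_match_pep / self.n_pred_pep if self.n_pred_pep else None

    @property
    def coverage(self) -> float | None:
        return self.n_pred_pep / self.n_orig_pep if self.n_orig_pep else None


def _match_masses(
    masses_pred: list[float], masses_truth: list[float], tol: MatchTolerances
) -> np.ndarray:
    """Greedy two-pass prefix/suffix mass alignment; returns a matched flag
    per predicted token."""
    n1, n2 = len(masses_pred), len(masses_truth)
    matched = np.zeros(n1, dtype=bool)
    matched_truth = np.zeros(n2, dtype=bool)

    # forward pass over prefix masses
    i1 = i2 = 0
    cum1 = cum2 = 0.0
    while i1 < n1 and i2 < n2:
        a, b = masses_pred[i1], masses_truth[i2]
        if abs((cum1 + a) - (cum2 + b)) <= tol.context_mass_tol:
            hit = abs(a - b) < tol.aa_mass_tol
            matched[i1] = hit
            matched_truth[i2] = hit
            cum1 += a
            cum2 += b
            i1 += 1
            i2 += 1
        elif cum1 + a < cum2 + b:
            cum1 += a
            i1 += 1
        else:
            cum2 += b
            i2 += 1

    # the backward pass may rescue anything from the first unmatched
    # position onward (suffix masses can align where prefixes diverge)
    unmatched1 = np.flatnonzero(~matched)
    unmatched2 = np.flatnonzero(~matched_truth)
    stop1 = int(unmatched1[0]) if unmatched1.size else n1
    stop2 = int(unmatched2[0]) if unmatched2.size else n2

    j1, j2 = n1 - 1, n2 - 1
    cum1 = cum2 = 0.0
    while j1 >= stop1 and j2 >= stop2:
        a, b = masses_pred[j1], masses_truth[j2]
        if abs((cum1 + a) - (cum2 + b)) <= tol.context_mass_tol:
            matched[j1] = matched[j1] or abs(a - b) < tol.aa_mass_tol
            cum1 += a
            cum2 += b
            j1 -= 1
            j2 -= 1
        elif cum1 + a < cum2 + b:
            cum1 += a
            j1 -= 1
        else:
            cum2 += b
            j2 -= 1
    return matched


def _token_masses(p: PeptideSequence) -> list[float]:
    return [t.residue_mass for t in p.tokens]


def aa_match(
    pred: PeptideSequence, truth: PeptideSequence, tol: MatchTolerances = MatchTolerances()
) -> tuple[np.ndarray, bool]:
    """Per-token matched flags for the prediction, and peptide correctness."""
    if not pred.tokens:
        return np.zeros(0, dtype=bool), False
    matched = _match_masses(_token_masses(pred), _token_masses(truth), tol)
    peptide_ok = bool(matched.all()) and len(pred.tokens) == len(truth.tokens)
    return matched, peptide_ok


def match_amino_acids(
    pred: PeptideSequence, truth: PeptideSequence, tol: MatchTolerances = MatchTolerances()
) -> int:
    """Number of matched predicted amino acids."""
    matched, _ = aa_match(pred, truth, tol)
    return int(matched.sum())


@dataclass
class PrecisionCoverageCurve:
    coverage: np.ndarray
    precision: np.ndarray
    average_precision: float | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"coverage": self.coverage, "precision": self.precision})


def _curve(correct_flags: np.ndarray, n_orig: int, weights=None) -> PrecisionCoverageCurve:
    """Precision-coverage curve over a ranked list of unit predictions.

    ``weights`` generalizes to amino-acid level, where each ranked peptide
    contributes several predicted tokens.
    """
    if correct_flags.size == 0 or n_orig == 0:
        return PrecisionCoverageCurve(np.array([]), np.array([]), None)
    w = np.ones_like(correct_flags, dtype=float) if weights is None else weights
    cum_pred = np.cumsum(w)
    cum_correct = np.cumsum(correct_flags)
    precision = cum_correct / cum_pred
    coverage = cum_pred / n_orig
    # prepend the zero-coverage point so a perfect predictor integrates to 1
    cov = np.concatenate([[0.0], coverage])
    prec = np.concatenate([[precision[0]], precision])
    ap = float(np.trapezoid(prec, cov))
    return PrecisionCoverageCurve(coverage, precision, ap)


@dataclass
class EvalResult:
    counts: EvalCounts
    peptide_curve: PrecisionCoverageCurve
    aa_curve: PrecisionCoverageCurve


def evaluate(
    predictions: list[Prediction],
    annotations: dict[str, PeptideSequence],
    tol: MatchTolerances = MatchTolerances(),
    n_orig: int | None = None,
) -> EvalResult:
    """Score predictions against ground-truth peptides.

    ``annotations`` maps spectrum identifiers to true peptides; ``n_orig``
    is the total number of spectra in the evaluated set (defaults to the
    number of annotations). Every prediction must have an annotation.
    """
    n_orig = len(annotations) if n_orig is None else n_orig
    counts = EvalCounts(n_orig_pep=n_orig)
    counts.n_orig_aa = sum(len(p.tokens) for p in annotations.values())

    ranked = rank_predictions(predictions)
    pep_correct = []
    aa_flags: list[np.ndarray] = []
    aa_scores: list[np.ndarray] = []
    for pred in ranked:
        if pred.spectrum_id not in annotations:
            raise KeyError(f"no annotation for spectrum {pred.spectrum_id!r}")
        truth = annotations[pred.spectrum_id]
        matched, pep_ok = aa_match(pred.peptide, truth, tol)
        counts.n_pred_pep += 1
        counts.n_pred_aa += len(pred.peptide.tokens)
        counts.n_match_aa += int(matched.sum())
        counts.n_match_pep += int(pep_ok)
        pep_correct.append(pep_ok)
        aa_flags.append(matched)
        aa_scores.append(np.asarray(pred.aa_scores))

    peptide_curve = _curve(np.asarray(pep_correct, dtype=float), n_orig)

    if aa_flags and counts.n_pred_aa:
        flat_flags = np.concatenate(aa_flags).astype(float)
        flat_scores = np.concatenate(aa_scores)
        order = np.argsort(-flat_scores, kind="stable")
        aa_curve = _curve(flat_flags[order], counts.n_orig_aa)
    else:
        aa_curve = PrecisionCoverageCurve(np.array([]), np.array([]), None)

    return EvalResult(counts=counts, peptide_curve=peptide_curve, aa_curve=aa_curve)
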