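"""Beam-search decoding under precursor-mass constraints, and confidence
scoring of the resulting peptide-spectrum matches.

Decoding proceeds from C-terminus to N-terminus. At each step the k
top-scoring tokens of every live beam are proposed and the k best partial
sequences overall are retained. A beam terminates when it predicts the stop
token, when its running peptide mass reaches the precursor mass (within the
ppm tolerance, allowing the configured isotope errors), when it exceeds the
precursor mass, or at the maximum peptide length. The final prediction is
the top-scoring completed beam that fits the precursor tolerance; if none
fits, the top-scoring non-matching beam is returned and flagged.

The peptide-level confidence score is the mean softmax probability over the
predicted amino acids; the per-amino-acid score is the mean of the peptide
score and that residue's own probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import SpectrumTransformer, collate
from .nn import Tensor, log_softmax_data
from .spectra_io import Spectrum
from .vocabulary import (
    NEUTRON_MASS,
    NTERM_MOD_INDICES,
    STOP_INDEX,
    WATER_MASS,
    PeptideSequence,
    from_token_ids,
    get_vocabulary,
)

_VOCAB = get_vocabulary()
_TOKEN_MASSES = np.array([t.residue_mass for t in _VOCAB])
_NTERM_SET = set(NTERM_MOD_INDICES)


@dataclass(frozen=True)
class FilterConfig:
    epsilon_ppm: float = 30.0
    isotope_offsets: tuple[int, ...] = (0, 1)
    neutron_mass: float = NEUTRON_MASS

    def __post_init__(self):
        if self.epsilon_ppm <= 0:
            raise ValueError("epsilon must be positive")


def precursor_filter(
    p: PeptideSequence | float, precursor_mass: float, filt: FilterConfig = FilterConfig()
) -> tuple[bool, float]:
    """Check a predicted peptide's mass against the observed precursor mass.

    Passes iff ``min_q |m_prec - (m_pred + q*neutron)| * 1e6 / m_prec`` over
    the allowed isotope offsets q is below the ppm tolerance. Returns the
    pass flag and the minimizing offset's signed ppm error magnitude.
    """
    m_pred = p.mass() if isinstance(p, PeptideSequence) else float(p)
    deltas = [
        abs(precursor_mass - (m_pred + q * filt.neutron_mass)) * 1e6 / precursor_mass
        for q in filt.isotope_offsets
    ]
    best = min(deltas)
    return best < filt.epsilon_ppm, best


@dataclass
class Beam:
    prefix: list[int] = field(default_factory=list)  # internal C->N token ids
    log_probs: list[float] = field(default_factory=list)
    probs: list[float] = field(default_factory=list)
    terminated: bool = False
    termination_reason: str | None = None

    @property
    def log_score(self) -> float:
        return float(sum(self.log_probs))

    @property
    def residue_mass(self) -> float:
        return float(_TOKEN_MASSES[self.prefix].sum()) if self.prefix else 0.0


@dataclass
class Prediction:
    spectrum_id: str
    peptide: PeptideSequence
    aa_probabilities: list[float]
    peptide_score: float
    aa_scores: list[float]
    passes_filter: bool
    delta_m_ppm: float
    log_score: float = 0.0
    termination_reason: str | None = None


def _legal_token_mask(beam: Beam) -> np.ndarray:
    """Additive mask over the vocabulary for the next token of a beam."""
    mask = np.zeros(len(_VOCAB))
    if beam.prefix and beam.prefix[-1] in _NTERM_SET:
        # an N-terminal modification is only legal as the final token before
        # stop (decoding runs C->N)
        mask[:] = -np.inf
        mask[STOP_INDEX] = 0.0
    return mask


def _mass_termination(
    residue_mass: float, precursor_mass: float, filt: FilterConfig
) -> str | None:
    peptide_mass = residue_mass + WATER_MASS
    passes, _ = precursor_filter(peptide_mass, precursor_mass, filt)
    if passes:
        return "mass_reached"
    tol_da = filt.epsilon_ppm * 1e-6 * precursor_mass
    heaviest_target = precursor_mass - min(filt.isotope_offsets) * filt.neutron_mass
    if peptide_mass > heaviest_target + tol_da:
        return "mass_exceeded"
    return None


def _finalize(beam: Beam, spectrum: Spectrum, filt: FilterConfig) -> Prediction:
    ids_cn = list(beam.prefix)
    probs_cn = list(beam.probs)
    if ids_cn and ids_cn[-1] == STOP_INDEX:  # defensive; stop is never stored
        ids_cn = ids_cn[:-1]
    peptide = from_token_ids(ids_cn[::-1])
    aa_probs = probs_cn[::-1]
    pep_score = float(np.mean(aa_probs)) if aa_probs else 0.0
    aa_scores = [(pep_score + p) / 2.0 for p in aa_probs]
    if peptide.tokens:
        passes, delta = precursor_filter(peptide, spectrum.precursor.mass, filt)
    else:
        passes, delta = False, float("inf")
    return Prediction(
        spectrum_id=spectrum.identifier,
        peptide=peptide,
        aa_probabilities=aa_probs,
        peptide_score=pep_score,
        aa_scores=aa_scores,
        passes_filter=passes,
        delta_m_ppm=delta,
        log_score=beam.log_score,
        termination_reason=beam.termination_reason,
    )


def beam_search(
    spectrum: Spectrum,
    model: SpectrumTransformer,
    k: int = 5,
    filt: FilterConfig = FilterConfig(),
) -> Prediction:
    """Decode one preprocessed spectrum with k beams.

    For k > 1 the width-1 (greedy) solution is merged into the completed
    set before final selection, so widening the beam never returns a
    lower-scoring sequence than greedy decoding (plain breadth-limited
    search can drop the greedy path mid-search).
    """
    if k < 1:
        raise ValueError("beam count must be >= 1")
    if not spectrum.peaks:
        raise ValueError("cannot decode a spectrum with zero peaks")
    batch = collate([spectrum], with_targets=False)
    memory, mem_mask = model.encode(batch)
    _, prediction = _beam_search_encoded(spectrum, model, memory, mem_mask, k, filt)
    return prediction


def _beam_search_encoded(
    spectrum: Spectrum,
    model: SpectrumTransformer,
    memory,
    mem_mask,
    k: int,
    filt: FilterConfig,
) -> Prediction:
    prec_mass = spectrum.precursor.mass
    prec_charge = spectrum.precursor.charge
    max_tokens = model.config.max_length + 1  # residues + optional N-term mod

    live = [Beam()]
    completed: list[Beam] = []
    for _ in range(max_tokens):
        if not live:
            break
        L = max(len(b.prefix) for b in live)
        dec_in = np.zeros((len(live), L), dtype=np.int64)
        for i, b in enumerate(live):
            dec_in[i, : len(b.prefix)] = b.prefix
        logits = model.decode(
            Tensor(np.repeat(memory.data, len(live), axis=0)),
            mem_mask,
            np.full(len(live), prec_mass),
            np.full(len(live), prec_charge, dtype=np.int64),
            dec_in,
        )
        # position len(prefix) scores the next token of each beam
        candidates: list[tuple[float, tuple[int, ...], Beam, int, float]] = []
        for i, b in enumerate(live):
            row = logits.data[i, len(b.prefix)]
            logp = log_softmax_data(row + _legal_token_mask(b))
            order = np.argsort(-logp, kind="stable")[:k]
            for tok in order:
                if not np.isfinite(logp[tok]):
                    continue
                score = b.log_score + float(logp[tok])
                candidates.append(
                    (score, tuple(b.prefix) + (int(tok),), b, int(tok), float(logp[tok]))
                )
        if not candidates:
            break
        candidates.sort(key=lambda c: (-c[0], c[1]))
        next_live: list[Beam] = []
        for score, _, parent, tok, lp in candidates[:k]:
            new = Beam(
                prefix=list(parent.prefix),
                log_probs=list(parent.log_probs) + [lp],
                probs=list(parent.probs),
            )
            if tok == STOP_INDEX:
                new.terminated = True
                new.termination_reason = "stop_token"
                completed.append(new)
                continue
            new.prefix.append(tok)
            new.probs.append(float(np.exp(lp)))
            reason = _mass_termination(new.residue_mass, prec_mass, filt)
            if reason is not None:
                new.terminated = True
                new.termination_reason = reason
                completed.append(new)
            elif len(new.prefix) >= max_tokens:
                new.terminated = True
                new.termination_reason = "max_length"
                completed.append(new)
            else:
                next_live.append(new)
        live = next_live

    completed.extend(live)  # safety net; loop bound guarantees termination
    if k > 1:
        greedy_beam, _ = _beam_search_encoded(spectrum, model, memory, mem_mask, 1, filt)
        if greedy_beam is not None and not any(
            tuple(b.prefix) == tuple(greedy_beam.prefix) for b in completed
        ):
            completed.append(greedy_beam)
    if not completed:
        empty = Beam(terminated=True, termination_reason="stop_token")
        return None, _finalize(empty, spectrum, filt)

    scored = [(b, _finalize(b, spectrum, filt)) for b in completed]
    scored.sort(
        key=lambda bp: (
            not bp[1].passes_filter,
            -bp[0].log_score,
            tuple(bp[0].prefix),
        )
    )
    return scored[0]


def sequence_spectra(
    spectra: list[Spectrum],
    model: SpectrumTransformer,
    k: int = 5,
    filt: FilterConfig = FilterConfig(),
) -> list[Prediction]:
    """Decode a list of preprocessed spectra; empty-flagged spectra are
    skipped."""
    preds = []
    for s in spectra:
        if s.flagged_empty or not s.peaks:
            continue
        preds.append(beam_search(s, model, k=k, filt=filt))
    return preds


def rank_predictions(preds: list[Prediction]) -> list[Prediction]:
    """Stable sort: filter-passing predictions first, then by descending
    peptide score; predictions failing the precursor filter rank last."""
    return sorted(preds, key=lambda p: (not p.passes_filter, -p.peptide_score))
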