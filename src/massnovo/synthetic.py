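"""Annotated synthetic spectrum corpora.

The generator emulates the statistical structure of peptide fragmentation
spectra well enough to exercise every stage of the sequencing pipeline
without external downloads: complete b/y fragment-ion ladders (charge 1,
plus charge 2 when the precursor charge is at least 2), log-normal
intensities with the y series drawn higher on average than the b series,
optional ppm-scale m/z jitter, uniform background noise peaks kept below
the signal intensities, and random fragment dropout. It makes no claim to
fragmentation physics: intensities carry no sequence information beyond the
b/y asymmetry, and no isotope envelopes or internal/immonium ions are
produced.

Peptides are sampled either non-enzymatically (uniform C-terminal residue)
or tryptically (C-terminal K/R). The balanced C-terminal sampler caps
spectra per unique peptide and per C-terminal residue, mirroring how a
non-enzymatic training set is assembled from tryptic-biased corpora.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .spectra_io import Peak, PrecursorInfo, Spectrum
from .vocabulary import (
    NTERM_MOD_MASSES,
    PROTON_MASS,
    RESIDUE_MASSES,
    WATER_MASS,
    PeptideSequence,
    tokenize,
)

logger = logging.getLogger(__name__)

_CANONICAL = list(RESIDUE_MASSES)
_MODIFIABLE = {"M": "M+15.994915", "N": "N+0.984016", "Q": "Q+0.984016"}


@dataclass(frozen=True)
class SimulationConfig:
    n_spectra: int = 1000
    min_length: int = 6
    max_length: int = 20
    # precursor charge distribution; roughly one in ten precursors is 4+
    charge_probs: tuple[tuple[int, float], ...] = ((2, 0.55), (3, 0.34), (4, 0.11))
    tryptic: bool = False
    p_nterm_mod: float = 0.05
    p_modified_residue: float = 0.03
    jitter_ppm: float = 5.0
    n_noise_peaks: int = 10
    p_missing_fragment: float = 0.1
    y_over_b_intensity: float = 2.0  # mean intensity ratio of y to b series
    intensity_sigma: float = 0.5  # log-normal shape
    seed: int = 0

    def __post_init__(self):
        for _, p in self.charge_probs:
            if not 0 <= p <= 1:
                raise ValueError("charge probabilities must be in [0, 1]")
        for p in (self.p_nterm_mod, self.p_modified_residue, self.p_missing_fragment):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")


def noiseless(cfg: SimulationConfig) -> SimulationConfig:
    """A copy of the configuration with jitter, noise, and dropout removed."""
    from dataclasses import replace

    return replace(cfg, jitter_ppm=0.0, n_noise_peaks=0, p_missing_fragment=0.0)


def sample_peptides(
    n: int, cfg: SimulationConfig, rng: np.random.Generator
) -> list[PeptideSequence]:
    """Draw n distinct peptides from the vocabulary."""
    seen: set[str] = set()
    out: list[PeptideSequence] = []
    while len(out) < n:
        length = int(rng.integers(cfg.min_length, cfg.max_length + 1))
        residues = list(rng.choice(_CANONICAL, size=length))
        if cfg.tryptic:
            residues[-1] = "K" if rng.random() < 0.5 else "R"
        symbols = []
        for r in residues:
            if r in _MODIFIABLE and rng.random() < cfg.p_modified_residue:
                symbols.append(_MODIFIABLE[r])
            else:
                symbols.append(r)
        if rng.random() < cfg.p_nterm_mod:
            symbols.insert(0, str(rng.choice(list(NTERM_MOD_MASSES))))
        pep = "".join("C" if s == "C+57.021464" else s for s in symbols)
        if pep in seen:
            continue
        seen.add(pep)
        out.append(tokenize(pep))
    return out


def _sample_charge(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    charges, probs = zip(*cfg.charge_probs)
    probs = np.asarray(probs) / sum(probs)
    return int(rng.choice(charges, p=probs))


def theoretical_spectrum(
    p: PeptideSequence,
    charge: int,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    identifier: str = "",
) -> Spectrum:
    """Simulate the annotated spectrum of a peptide at a precursor charge.

    Fragment m/z values follow standard b/y-ion chemistry: the singly
    charged b_i ion is the N-terminal prefix mass (N-terminal modification
    included) plus a proton; y_i is the C-terminal suffix mass plus water
    and a proton; multiply charged fragments are (mass + (z-1)*proton)/z.
    """
    if not p.tokens:
        raise ValueError("empty peptide")
    residues = p.residue_masses()
    n = len(residues)
    nterm = p.nterm_mod.residue_mass if p.nterm_mod else 0.0

    prefix = np.cumsum([nterm] + residues)  # prefix[i] = mass of first i residues + mod
    total = prefix[-1]
    frag_charges = [1, 2] if charge >= 2 else [1]

    mzs, intensities = [], []
    for i in range(1, n):  # b_1..b_{n-1}, y_1..y_{n-1}
        b_mass = prefix[i] + PROTON_MASS
        y_mass = total - prefix[i] + WATER_MASS + PROTON_MASS
        for z in frag_charges:
            for mass, is_y in ((b_mass, False), (y_mass, True)):
                if rng.random() < cfg.p_missing_fragment:
                    continue
                mz = (mass + (z - 1) * PROTON_MASS) / z
                mu = np.log(cfg.y_over_b_intensity) if is_y else 0.0
                inten = float(np.exp(rng.normal(mu, cfg.intensity_sigma)))
                mzs.append(mz)
                intensities.append(inten)
    if not mzs:  # dropout removed everything; keep one y1 peak
        y1 = residues[-1] + WATER_MASS + PROTON_MASS
        mzs, intensities = [y1], [1.0]

    mzs = np.asarray(mzs)
    if cfg.jitter_ppm > 0:
        mzs = mzs * (1.0 + rng.normal(0.0, cfg.jitter_ppm, size=mzs.size) * 1e-6)
    intensities = np.asarray(intensities)

    if cfg.n_noise_peaks > 0:
        floor = np.percentile(intensities, 20.0)
        noise_mz = rng.uniform(50.0, 2500.0, size=cfg.n_noise_peaks)
        noise_inten = rng.uniform(0.0, floor, size=cfg.n_noise_peaks)
        mzs = np.concatenate([mzs, noise_mz])
        intensities = np.concatenate([intensities, noise_inten])

    order = np.argsort(mzs, kind="stable")
    mzs, intensities = mzs[order], intensities[order]

    precursor_mz = (p.mass() + charge * PROTON_MASS) / charge
    if cfg.jitter_ppm > 0:
        precursor_mz *= 1.0 + rng.normal(0.0, cfg.jitter_ppm) * 1e-6

    return Spectrum(
        peaks=[Peak(float(m), float(h)) for m, h in zip(mzs, intensities) if m > 0],
        precursor=PrecursorInfo(float(precursor_mz), charge),
        identifier=identifier,
        annotation=p,
    )


def generate_corpus(cfg: SimulationConfig, peptides=None) -> list[Spectrum]:
    """Generate ``cfg.n_spectra`` annotated spectra (one distinct peptide
    each unless ``peptides`` is supplied). Fixed seed, identical corpus."""
    rng = np.random.default_rng(cfg.seed)
    if peptides is None:
        peptides = sample_peptides(cfg.n_spectra, cfg, rng)
    spectra = []
    for i, pep in enumerate(peptides):
        charge = _sample_charge(cfg, rng)
        spectra.append(
            theoretical_spectrum(pep, charge, cfg, rng, identifier=f"synthetic:{i}")
        )
    return spectra


def balanced_cterm_sample(
    spectra: list[Spectrum],
    per_residue_cap: int,
    per_peptide_cap: int = 100,
    seed: int = 0,
) -> list[Spectrum]:
    """Balanced non-enzymatic subsample of an annotated corpus.

    First at most ``per_peptide_cap`` spectra are kept per unique peptide,
    then up to ``per_residue_cap`` spectra per C-terminal residue, both
    sampled with the run seed. Residue strata without candidates are left
    empty with a warning.
    """
    rng = np.random.default_rng(seed)
    by_peptide: dict[str, list[Spectrum]] = defaultdict(list)
    for s in spectra:
        if s.annotation is None:
            raise ValueError("balanced sampling requires annotated spectra")
        by_peptide[str(s.annotation)].append(s)

    capped: list[Spectrum] = []
    for pep in sorted(by_peptide):
        group = by_peptide[pep]
        if len(group) > per_peptide_cap:
            idx = rng.choice(len(group), size=per_peptide_cap, replace=False)
            group = [group[i] for i in sorted(idx)]
        capped.extend(group)

    by_cterm: dict[str, list[Spectrum]] = defaultdict(list)
    for s in capped:
        cterm = s.annotation.residues[-1].symbol[0]
        by_cterm[cterm].append(s)

    out: list[Spectrum] = []
    for residue in sorted(set(r[0] for r in _CANONICAL)):
        group = by_cterm.get(residue, [])
        if not group:
            logger.warning("no spectra with C-terminal %s; stratum empty", residue)
            continue
        if len(group) > per_residue_cap:
            idx = rng.choice(len(group), size=per_residue_cap, replace=False)
            group = [group[i] for i in sorted(idx)]
        out.extend(group)
    return out
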