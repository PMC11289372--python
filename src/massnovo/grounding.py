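"""Grounding de novo predictions in protein databases.

Three analyses, in the order a metaproteomics or "dark proteome" study
would run them:

* **Target-decoy grounding** — each predicted peptide is searched as a
  substring (I and L collapsed, since they are indistinguishable by mass)
  against the target proteins and against per-protein residue shuffles
  (decoys). Within each peptide length, predictions are sorted by
  confidence and the accepted set is the largest rank k whose estimated
  random-match rate D_k/T_k stays below alpha.
* **Cluster-level peptide assignment** — a spectrum cluster is assigned a
  peptide either by plurality vote (winner must have at least two votes and
  be unique) followed by proteome matching, or by first discarding
  predictions absent from the proteome and then requiring unanimity.
* **Substitution plausibility** — single-mismatch matches to a proteome are
  annotated with whether the substitution is reachable by one nucleotide
  change in the standard genetic code, and with its BLOSUM62 score.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from .vocabulary import PeptideSequence, tokenize

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


def _collapse_il(s: str) -> str:
    return s.replace("I", "L")


def _plain_sequence(p: PeptideSequence | str) -> str:
    """Residue letters only: modifications stripped, for database matching."""
    if isinstance(p, str):
        p = tokenize(p)
    return "".join(t.symbol[0] for t in p.residues)


@dataclass
class DecoyDatabase:
    """Target proteins plus per-protein residue shuffles of identical length
    and composition."""

    target_names: list[str]
    targets: list[str]
    decoys: list[str]
    seed: int

    @classmethod
    def from_sequences(cls, named_seqs: list[tuple[str, str]], seed: int = 0):
        if not named_seqs:
            raise ValueError("empty protein database")
        rng = np.random.default_rng(seed)
        names, targets, decoys = [], [], []
        for name, seq in named_seqs:
            seq = str(seq).upper()
            names.append(name)
            targets.append(seq)
            letters = np.array(list(seq))
            rng.shuffle(letters)
            decoys.append("".join(letters))
        return cls(names, targets, decoys, seed)

    @classmethod
    def from_fasta(cls, path: str | Path, seed: int = 0):
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
        return cls.from_sequences(records, seed=seed)

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, seq in zip(self.target_names, self.targets):
                fh.write(f">{name}\n{seq}\n")
            for name, seq in zip(self.target_names, self.decoys):
                fh.write(f">decoy_{name}\n{seq}\n")

    def _concat(self, seqs: list[str]) -> str:
        return "#".join(_collapse_il(s) for s in seqs)

    def matches_target(self, peptide: str) -> bool:
        if not hasattr(self, "_target_blob"):
            self._target_blob = self._concat(self.targets)
        return _collapse_il(peptide) in self._target_blob

    def matches_decoy(self, peptide: str) -> bool:
        if not hasattr(self, "_decoy_blob"):
            self._decoy_blob = self._concat(self.decoys)
        return _collapse_il(peptide) in self._decoy_blob


@dataclass
class GroundedPeptide:
    peptide: str
    score: float
    label: str  # target | decoy | none
    accepted: bool = False


@dataclass
class GroundingResult:
    peptides: list[GroundedPeptide]
    cutoffs: dict[int, int]  # peptide length -> accepted rank k*
    alpha: float
    seed: int

    @property
    def accepted(self) -> list[GroundedPeptide]:
        return [g for g in self.peptides if g.accepted]


def ground_predictions(
    predictions,
    db: DecoyDatabase,
    alpha: float = 0.01,
    seed: int = 0,
) -> GroundingResult:
    """Label predictions target/decoy/none and accept by the D_k/T_k rule.

    ``predictions`` is a list of objects with ``peptide`` and
    ``peptide_score`` attributes (or ``(peptide_string, score)`` pairs).
    Peptides matching both target and decoy are assigned randomly with the
    given seed. Within each peptide-length stratum, predictions are sorted
    by descending score and the largest k with D_k/T_k < alpha is accepted
    (a stratum with no decoy matches accepts all its targets).
    """
    rng = np.random.default_rng(seed)
    grounded: list[GroundedPeptide] = []
    for pred in predictions:
        if isinstance(pred, tuple):
            pep, score = pred
            pep = _plain_sequence(pep)
        else:
            pep = _plain_sequence(pred.peptide)
            score = pred.peptide_score
        in_t = db.matches_target(pep)
        in_d = db.matches_decoy(pep)
        if in_t and in_d:
            label = "target" if rng.random() < 0.5 else "decoy"
        elif in_t:
            label = "target"
        elif in_d:
            label = "decoy"
        else:
            label = "none"
        grounded.append(GroundedPeptide(pep, float(score), label))

    by_length: dict[int, list[GroundedPeptide]] = defaultdict(list)
    for g in grounded:
        if g.label != "none":
            by_length[len(g.peptide)].append(g)

    cutoffs: dict[int, int] = {}
    for length, group in by_length.items():
        group = sorted(group, key=lambda g: -g.score)
        t = d = 0
        best_k = 0
        for k, g in enumerate(group, start=1):
            if g.label == "target":
                t += 1
            else:
                d += 1
            # a stratum with no decoy matches so far estimates a zero random
            # match rate and is accepted at any alpha
            if d == 0 or (t > 0 and d / t < alpha):
                best_k = k
        cutoffs[length] = best_k
        for g in group[:best_k]:
            if g.label == "target":
                g.accepted = True
    return GroundingResult(grounded, cutoffs, alpha, seed)


# --------------------------------------------------------------------------
# Cluster-level assignment


def assign_cluster_peptides(
    clusters: dict[str, list],
    proteome: list[str],
    mode: str = "plurality_first",
) -> dict[str, str]:
    """Assign one peptide per spectrum cluster.

    ``clusters`` maps cluster ids to lists of predictions (objects with a
    ``peptide`` attribute, or peptide strings). ``proteome`` is a list of
    protein sequences; matching allows at most one amino-acid mismatch
    (I/L-collapsed).

    ``plurality_first``: the unique plurality winner with at least two votes
    is assigned, then kept only if it matches the proteome.
    ``proteome_first``: predictions absent from the proteome are discarded,
    then the cluster must be unanimous with at least two remaining spectra.
    """
    if mode not in ("plurality_first", "proteome_first"):
        raise ValueError(f"unknown mode {mode!r}")
    index = ProteomeIndex(proteome)
    assigned: dict[str, str] = {}
    for cid, preds in clusters.items():
        peptides = [
            _plain_sequence(p if isinstance(p, str) else p.peptide) for p in preds
        ]
        if mode == "proteome_first":
            peptides = [p for p in peptides if index.match_one_mismatch(p)]
            if len(peptides) >= 2 and len(set(peptides)) == 1:
                assigned[cid] = peptides[0]
            continue
        counts = defaultdict(int)
        for p in peptides:
            counts[p] += 1
        if not counts:
            continue
        top = max(counts.values())
        winners = [p for p, c in counts.items() if c == top]
        if top >= 2 and len(winners) == 1 and index.match_one_mismatch(winners[0]):
            assigned[cid] = winners[0]
    return assigned


@dataclass
class SubstitutionCall:
    peptide: str
    protein_index: int
    position: int  # offset of the peptide within the protein
    mismatch_position: int | None  # within the peptide; None for exact match
    from_residue: str | None  # proteome residue
    to_residue: str | None  # predicted residue
    snp_explainable: bool | None = None
    blosum62_score: float | None = None

    @property
    def exact(self) -> bool:
        return self.mismatch_position is None


class ProteomeIndex:
    """Substring search over a protein list with at most one mismatch,
    treating I and L as equivalent."""

    def __init__(self, proteins: list[str]):
        self.proteins = [str(p).upper() for p in proteins]
        self._collapsed = [_collapse_il(p) for p in self.proteins]

    def match_one_mismatch(self, peptide: str, annotate: bool = False) -> list[SubstitutionCall]:
        pep = _collapse_il(peptide.upper())
        n = len(pep)
        if n == 0:
            return []
        pep_arr = np.frombuffer(pep.encode(), dtype=np.uint8)
        calls: list[SubstitutionCall] = []
        for pi, prot in enumerate(self._collapsed):
            if len(prot) < n:
                continue
            prot_arr = np.frombuffer(prot.encode(), dtype=np.uint8)
            windows = np.lib.stride_tricks.sliding_window_view(prot_arr, n)
            mismatches = (windows != pep_arr).sum(axis=1)
            for off in np.flatnonzero(mismatches <= 1):
                mm = int(mismatches[off])
                if mm == 0:
                    calls.append(SubstitutionCall(peptide, pi, int(off), None, None, None))
                else:
                    pos = int(np.flatnonzero(windows[off] != pep_arr)[0])
                    frm = self.proteins[pi][off + pos]
                    to = peptide[pos]
                    call = SubstitutionCall(peptide, pi, int(off), pos, frm, to)
                    if annotate:
                        call.snp_explainable = snp_explainable(frm, to)
                        call.blosum62_score = blosum62_score(frm, to)
                    calls.append(call)
        return calls


def match_one_mismatch(
    p: PeptideSequence | str, proteome: list[str], annotate: bool = True
) -> list[SubstitutionCall]:
    """All loci in the proteome matching the peptide with Hamming distance
    <= 1 (I/L equivalent); exact matches carry ``mismatch_position=None``."""
    return ProteomeIndex(proteome).match_one_mismatch(_plain_sequence(p), annotate=annotate)


# --------------------------------------------------------------------------
# Substitution plausibility

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]  # standard genetic code


def _codons_by_residue(include_selenocysteine: bool = False) -> dict[str, list[str]]:
    codons: dict[str, list[str]] = defaultdict(list)
    for codon, aa in _CODON_TABLE.forward_table.items():
        codons[aa].append(codon)
    if include_selenocysteine:
        codons["U"] = ["TGA"]  # stop-codon recoding
    return dict(codons)


def snp_explainable(a: str, b: str, include_selenocysteine: bool = False) -> bool:
    """True iff some codon of ``a`` and some codon of ``b`` differ at exactly
    one nucleotide position (standard genetic code; stop codons are not
    allowed as intermediates)."""
    codons = _codons_by_residue(include_selenocysteine)
    if a == b:
        raise ValueError("residues must differ")
    for r in (a, b):
        if r not in codons:
            raise ValueError(f"non-standard residue {r!r}")
    return any(
        sum(x != y for x, y in zip(ca, cb)) == 1
        for ca in codons[a]
        for cb in codons[b]
    )


def snp_explainable_fraction(include_selenocysteine: bool = True) -> float:
    """Fraction of ordered distinct residue substitutions reachable by a
    single nucleotide change.

    By default the enumeration includes selenocysteine (UGA-recoded), the
    21st residue of the human reference proteome, giving 162/420 = 38.6%;
    restricted to the 20 standard residues it is 150/380 = 39.5%.
    """
    codons = _codons_by_residue(include_selenocysteine)
    residues = sorted(codons)
    n = tot = 0
    for a in residues:
        for b in residues:
            if a == b:
                continue
            tot += 1
            n += snp_explainable(a, b, include_selenocysteine)
    return n / tot


_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def blosum62_score(a: str, b: str) -> float:
    return float(_BLOSUM62[a.upper()][b.upper()])


def blosum62_stats() -> tuple[float, dict[tuple[str, str], float]]:
    """Fraction of positive entries among the 380 off-diagonal cells of the
    20x20 BLOSUM62 matrix, plus the score lookup table."""
    scores: dict[tuple[str, str], float] = {}
    positive = 0
    total = 0
    for a in STANDARD_RESIDUES:
        for b in STANDARD_RESIDUES:
            scores[(a, b)] = blosum62_score(a, b)
            if a != b:
                total += 1
                if scores[(a, b)] > 0:
                    positive += 1
    return positive / total, scores
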