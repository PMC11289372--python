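"""Amino-acid vocabulary, monoisotopic masses, and peptide-mass arithmetic.

The sequencing model emits tokens from a fixed 28-token vocabulary: the 20
canonical residues (cysteine always carbamidomethylated), three modified
residues (oxidized methionine, deamidated asparagine/glutamine), four
N-terminal modifications (acetylation, carbamylation, NH3 loss, and the
combination of carbamylation and NH3 loss), and a stop token that signals
the end of decoding.

Peptide strings use single-letter residue codes with bare ``+mass``/``-mass``
suffixes for modifications, e.g. ``"+43.005814AM+15.994915K"`` is a
carbamylated peptide with oxidized methionine.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

PROTON_MASS = 1.007276466
WATER_MASS = 18.010565
NEUTRON_MASS = 1.00335

MAX_PEPTIDE_LENGTH = 100

# Monoisotopic residue masses (Da), carbamidomethylated cysteine fixed.
RESIDUE_MASSES = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047679,
    "C+57.021464": 160.030649,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
}

MODIFIED_RESIDUE_MASSES = {
    "M+15.994915": RESIDUE_MASSES["M"] + 15.994915,
    "N+0.984016": RESIDUE_MASSES["N"] + 0.984016,
    "Q+0.984016": RESIDUE_MASSES["Q"] + 0.984016,
}

# N-terminal modifications. The combined carbamylation + NH3-loss mass is the
# conventional printed value, which differs from the sum of its components by
# 0.001 Da; it is kept verbatim for compatibility with standard search tooling.
NTERM_MOD_MASSES = {
    "+42.010565": 42.010565,
    "+43.005814": 43.005814,
    "-17.026549": -17.026549,
    "+25.980265": 25.980265,
}

STOP_SYMBOL = "$"

KIND_RESIDUE = "residue"
KIND_NTERM_MOD = "nterm_mod"
KIND_STOP = "stop"


@dataclass(frozen=True)
class Token:
    symbol: str
    residue_mass: float
    kind: str

    def __post_init__(self):
        if self.kind == KIND_RESIDUE and self.residue_mass <= 0:
            raise ValueError(f"residue token {self.symbol!r} must have mass > 0")
        if self.kind == KIND_STOP and self.residue_mass != 0.0:
            raise ValueError("stop token must have mass 0")


class VocabularyError(ValueError):
    """Raised when a peptide string contains an unknown token symbol."""


def build_vocabulary() -> list[Token]:
    """Return the 28 tokens in canonical order (residues, N-term mods, stop)."""
    tokens = [Token(s, m, KIND_RESIDUE) for s, m in RESIDUE_MASSES.items()]
    tokens += [Token(s, m, KIND_RESIDUE) for s, m in MODIFIED_RESIDUE_MASSES.items()]
    tokens += [Token(s, m, KIND_NTERM_MOD) for s, m in NTERM_MOD_MASSES.items()]
    tokens.append(Token(STOP_SYMBOL, 0.0, KIND_STOP))
    return tokens


_VOCAB = build_vocabulary()
TOKEN_INDEX = {t.symbol: i for i, t in enumerate(_VOCAB)}
STOP_INDEX = TOKEN_INDEX[STOP_SYMBOL]
RESIDUE_INDICES = [i for i, t in enumerate(_VOCAB) if t.kind == KIND_RESIDUE]
NTERM_MOD_INDICES = [i for i, t in enumerate(_VOCAB) if t.kind == KIND_NTERM_MOD]
VOCAB_SIZE = len(_VOCAB)

_TOKEN_RE = re.compile(r"([A-Z](?:[+-]\d+\.\d+)?|[+-]\d+\.\d+)")


def vocabulary_hash() -> str:
    """Stable fingerprint of the token set, stored in checkpoints."""
    import hashlib

    payload = ";".join(f"{t.symbol}:{t.residue_mass:.6f}" for t in _VOCAB)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PeptideSequence:
    """An ordered list of tokens in N→C reporting order.

    At most one N-terminal modification token is allowed, and only at
    position 0. The stop token never appears inside a sequence.
    """

    tokens: list[Token] = field(default_factory=list)

    def __post_init__(self):
        for i, t in enumerate(self.tokens):
            if t.kind == KIND_STOP:
                raise ValueError("stop token inside a peptide sequence")
            if t.kind == KIND_NTERM_MOD and i != 0:
                raise ValueError("N-terminal modification not at position 0")
        if self.n_residues > MAX_PEPTIDE_LENGTH:
            raise ValueError(f"peptide exceeds {MAX_PEPTIDE_LENGTH} residues")

    @property
    def residues(self) -> list[Token]:
        return [t for t in self.tokens if t.kind == KIND_RESIDUE]

    @property
    def nterm_mod(self) -> Token | None:
        if self.tokens and self.tokens[0].kind == KIND_NTERM_MOD:
            return self.tokens[0]
        return None

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.tokens)

    def __eq__(self, other) -> bool:
        return isinstance(other, PeptideSequence) and [
            t.symbol for t in self.tokens
        ] == [t.symbol for t in other.tokens]

    def __hash__(self) -> int:
        return hash(tuple(t.symbol for t in self.tokens))

    def mass(self) -> float:
        """Neutral monoisotopic mass (Da): residue masses + mods + water."""
        return sum(t.residue_mass for t in self.tokens) + WATER_MASS

    def residue_masses(self) -> list[float]:
        """Masses of the residues only, N→C (any N-term mod folded into the
        first residue is *not* applied here; mods are separate tokens)."""
        return [t.residue_mass for t in self.residues]

    def __str__(self) -> str:
        return detokenize(self)


def peptide_mass(p: PeptideSequence, charge: int) -> tuple[float, float]:
    """Neutral monoisotopic mass and m/z of a peptide at a given charge."""
    if not p.tokens:
        raise ValueError("empty peptide")
    if charge < 1:
        raise ValueError("charge must be >= 1")
    neutral = p.mass()
    mz = (neutral + charge * PROTON_MASS) / charge
    return neutral, mz


def tokenize(peptide_string: str) -> PeptideSequence:
    """Parse a peptide string into a :class:`PeptideSequence`.

    Accepts the ASCII hyphen and the Unicode minus sign for losses, and bare
    ``C`` as carbamidomethylated cysteine.
    """
    s = peptide_string.replace("−", "-").strip()
    tokens: list[Token] = []
    pos = 0
    while pos < len(s):
        m = _TOKEN_RE.match(s, pos)
        if not m:
            raise VocabularyError(f"unrecognized token at {s[pos:pos + 12]!r}")
        sym = m.group(1)
        if sym == "C":
            sym = "C+57.021464"
        if sym not in TOKEN_INDEX:
            raise VocabularyError(f"unknown vocabulary symbol {sym!r}")
        tok = _VOCAB[TOKEN_INDEX[sym]]
        if tok.kind == KIND_STOP:
            raise VocabularyError("stop token not allowed in peptide strings")
        tokens.append(tok)
        pos = m.end()
    return PeptideSequence(tokens)


def detokenize(p: PeptideSequence) -> str:
    out = []
    for t in p.tokens:
        sym = "C" if t.symbol == "C+57.021464" else t.symbol
        out.append(sym)
    return "".join(out)


def token_ids(p: PeptideSequence) -> list[int]:
    return [TOKEN_INDEX[t.symbol] for t in p.tokens]


def from_token_ids(ids: Iterable[int]) -> PeptideSequence:
    return PeptideSequence([_VOCAB[i] for i in ids])


def get_vocabulary() -> list[Token]:
    return list(_VOCAB)
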