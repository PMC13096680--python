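"""Residue and side-chain atom statistics for tropocollagen molecules.

Every downstream energy mechanism consumes statistics produced here:
triplet counts (water bridges), side-chain element frequencies (van der
Waals contacts), charged-residue tallies (salt bridges), and CH2/CH3 group
counts (hydrophobic association).

Collagen chains are handled as plain one-letter sequences.  Two internal
extension codes are accepted for the collagen-specific hydroxylated
residues: ``O`` for 4-hydroxyproline and ``J`` for 5-hydroxylysine.
Database sequences encode these positions as P/K, so the built-in fixtures
use the plain codes; the extensions only matter when hydroxylation is
modelled explicitly.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

ELEMENTS = ("C", "H", "O", "N", "S")

# Full amino-acid formulas (free amino acid, C/H/N/O/S).
FULL_FORMULAS: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 5, "N": 1, "O": 2, "S": 0},
    "A": {"C": 3, "H": 7, "N": 1, "O": 2, "S": 0},
    "V": {"C": 5, "H": 11, "N": 1, "O": 2, "S": 0},
    "L": {"C": 6, "H": 13, "N": 1, "O": 2, "S": 0},
    "I": {"C": 6, "H": 13, "N": 1, "O": 2, "S": 0},
    "P": {"C": 5, "H": 9, "N": 1, "O": 2, "S": 0},
    "F": {"C": 9, "H": 11, "N": 1, "O": 2, "S": 0},
    "W": {"C": 11, "H": 12, "N": 2, "O": 2, "S": 0},
    "M": {"C": 5, "H": 11, "N": 1, "O": 2, "S": 1},
    "S": {"C": 3, "H": 7, "N": 1, "O": 3, "S": 0},
    "T": {"C": 4, "H": 9, "N": 1, "O": 3, "S": 0},
    "C": {"C": 3, "H": 7, "N": 1, "O": 2, "S": 1},
    "Y": {"C": 9, "H": 11, "N": 1, "O": 3, "S": 0},
    "N": {"C": 4, "H": 8, "N": 2, "O": 3, "S": 0},
    "Q": {"C": 5, "H": 10, "N": 2, "O": 3, "S": 0},
    "D": {"C": 4, "H": 7, "N": 1, "O": 4, "S": 0},
    "E": {"C": 5, "H": 9, "N": 1, "O": 4, "S": 0},
    "K": {"C": 6, "H": 14, "N": 2, "O": 2, "S": 0},
    "R": {"C": 6, "H": 14, "N": 4, "O": 2, "S": 0},
    "H": {"C": 6, "H": 9, "N": 3, "O": 2, "S": 0},
    # collagen-specific extensions: 4-hydroxyproline, 5-hydroxylysine
    "O": {"C": 5, "H": 9, "N": 1, "O": 3, "S": 0},
    "J": {"C": 6, "H": 14, "N": 2, "O": 3, "S": 0},
}

ALPHABET = frozenset(FULL_FORMULAS)

# Repeating peptide unit -NH-CH-CO- shared by every residue in a chain.
BACKBONE_FORMULA: dict[str, int] = {"C": 2, "H": 4, "N": 1, "O": 2, "S": 0}

# Aliphatic CH2/CH3 groups per side chain.  Only side chains that are
# predominantly nonpolar contribute: single-hydrogen alpha-C-H groups and
# methylenes that are part of polar or aromatic side chains (Ser, Thr, Asp,
# Glu, Asn, Gln, His, Phe, Tyr, Trp, Cys) are excluded because they provide
# little stabilisation upon burial.  Lys/Arg methylenes are counted; their
# charged termini are handled by the electrostatic mechanism.
CHX_GROUPS: dict[str, int] = {
    "A": 1,
    "V": 2,
    "L": 3,
    "I": 3,
    "P": 3,
    "M": 3,
    "K": 4,
    "R": 3,
    "O": 2,
    "J": 3,
}

CHARGED_RESIDUES = ("D", "E", "K", "R")


class SequenceError(ValueError):
    """Raised for malformed FASTA records or illegal residue codes."""


@dataclass(frozen=True)
class ChainSequence:
    """One collagen alpha-chain with an assembly multiplicity.

    Type I tropocollagen is a heterotrimer (alpha1 x2 + alpha2 x1), type II
    a homotrimer (alpha1 x3); ``multiplicity`` lets a single chain record
    stand for its copies in the molecule.
    """

    id: str
    residues: str
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if len(self.residues) < 3:
            raise SequenceError(f"chain {self.id!r}: need at least 3 residues")
        for pos, code in enumerate(self.residues):
            if code not in ALPHABET:
                raise SequenceError(
                    f"chain {self.id!r}: illegal residue {code!r} at position {pos + 1}"
                )
        if self.multiplicity < 1:
            raise SequenceError(f"chain {self.id!r}: multiplicity must be >= 1")

    def __len__(self) -> int:
        return len(self.residues)

    def triplet_fraction(self) -> float:
        """Fraction of first-triplet positions (i % 3 == 0) holding Gly."""
        first = self.residues[::3]
        return first.count("G") / len(first)


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


@dataclass(frozen=True)
class ResidueCounts:
    """Residue tallies summed over the three chains of one TC molecule."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        for code, n in self.counts.items():
            if code not in ALPHABET:
                raise SequenceError(f"unknown residue code {code!r}")
            if n < 0:
                raise ValueError(f"negative count for residue {code!r}")

    @property
    def n_residues(self) -> int:
        return sum(self.counts.values())

    @property
    def n_triplets(self) -> int:
        """Gly-X-Y triplets per TC (round-half-up of n_residues / 3)."""
        return _round_half_up(self.n_residues / 3)

    def __add__(self, other: "ResidueCounts") -> "ResidueCounts":
        merged = Counter(self.counts)
        merged.update(other.counts)
        return ResidueCounts(dict(merged))


@dataclass(frozen=True)
class AtomComposition:
    """Side-chain element counts and frequencies for one TC molecule."""

    side_chain_atoms: dict[str, int]
    total_side_chain_atoms: int
    frequencies: dict[str, float]


@dataclass(frozen=True)
class ChargeAndHydrophobicStats:
    """Charged-residue and CH2/CH3 tallies per TC molecule."""

    n_charged: int
    charged_fraction: float
    n_hydrophobic_residues: int
    n_chx_groups: int


@dataclass(frozen=True)
class CompositionProfile:
    """Bundle of all composition statistics for one fibril type."""

    label: str
    residue_counts: ResidueCounts
    atoms: AtomComposition = field(compare=False)
    stats: ChargeAndHydrophobicStats = field(compare=False)

    @classmethod
    def from_counts(cls, label: str, rc: ResidueCounts) -> "CompositionProfile":
        return cls(label, rc, atom_composition(rc), charge_stats(rc))


def read_fasta(path: str | Path) -> list[ChainSequence]:
    """Read chains from a FASTA file, upcasing and validating residues."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    chains = []
    for rec in records:
        seq = str(rec.seq).upper()
        if not seq:
            raise SequenceError(f"{path}: record {rec.id!r} has an empty sequence")
        chains.append(ChainSequence(id=rec.id, residues=seq))
    return chains


def read_composition_tsv(path: str | Path) -> ResidueCounts:
    """Read a per-TC residue table (columns: residue, count_per_TC)."""
    df = pd.read_csv(path, sep="\t", dtype={"residue": str})
    missing = {"residue", "count_per_TC"} - set(df.columns)
    if missing:
        raise SequenceError(f"{path}: missing columns {sorted(missing)}")
    return ResidueCounts({str(r): int(c) for r, c in zip(df["residue"], df["count_per_TC"])})


def profile_tc(chains: list[ChainSequence]) -> ResidueCounts:
    """Sum residue counts over the chains of a TC molecule (with multiplicity)."""
    if not chains:
        raise ValueError("a TC molecule needs at least one chain")
    counts: Counter[str] = Counter()
    for chain in chains:
        for code, n in Counter(chain.residues).items():
            counts[code] += n * chain.multiplicity
    return ResidueCounts(dict(counts))


def sidechain_formula(residue: str) -> dict[str, int]:
    """Element counts of one side chain (full formula minus the -NH-CH-CO- unit).

    Glycine keeps its single side-chain hydrogen under this convention;
    arginine yields C4 H10 N3.
    """
    try:
        full = FULL_FORMULAS[residue]
    except KeyError:
        raise SequenceError(f"unknown residue code {residue!r}") from None
    side = {el: full[el] - BACKBONE_FORMULA[el] for el in ELEMENTS}
    if any(v < 0 for v in side.values()):
        raise SequenceError(f"residue {residue!r}: backbone subtraction went negative")
    return side


def atom_composition(rc: ResidueCounts) -> AtomComposition:
    """Side-chain element counts and normalised frequencies for a TC molecule."""
    totals = {el: 0 for el in ELEMENTS}
    for code, n in rc.counts.items():
        side = sidechain_formula(code)
        for el in ELEMENTS:
            totals[el] += n * side[el]
    grand = sum(totals.values())
    freqs = {el: (totals[el] / grand if grand else 0.0) for el in ELEMENTS}
    return AtomComposition(totals, grand, freqs)


def _class_stats(rc: ResidueCounts) -> ChargeAndHydrophobicStats:
    n_charged = sum(rc.counts.get(code, 0) for code in CHARGED_RESIDUES)
    n_res = rc.n_residues
    n_hydro = sum(n for code, n in rc.counts.items() if CHX_GROUPS.get(code, 0) > 0)
    n_chx = sum(n * CHX_GROUPS.get(code, 0) for code, n in rc.counts.items())
    return ChargeAndHydrophobicStats(
        n_charged=n_charged,
        charged_fraction=n_charged / n_res if n_res else 0.0,
        n_hydrophobic_residues=n_hydro,
        n_chx_groups=n_chx,
    )


def charge_stats(rc: ResidueCounts) -> ChargeAndHydrophobicStats:
    """Asp/Glu/Lys/Arg tally and charged fraction (plus CH2/CH3 tallies)."""
    return _class_stats(rc)


def chx_stats(rc: ResidueCounts) -> ChargeAndHydrophobicStats:
    """CH2/CH3 group and hydrophobic-residue tallies (plus charge tallies)."""
    return _class_stats(rc)
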