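"""Collagen-like synthetic sequences and composition fixtures.

Real collagen alpha-chain sequences are not bundled; instead this module
provides (a) a seedable generator for strict Gly-X-Y triplet chains with
configurable X/Y residue frequencies, and (b) frozen per-TC residue
tables for the two fibril types.  The fixture tables are synthetic: they
were constructed by constrained integer search (see
``scripts/build_fixture_tables.py``) so that all published composition
statistics hold simultaneously — for type I: 3,233 residues, 1,078
triplets, 522 charged residues, 165 Arg, side-chain carbon/oxygen
frequencies of 29.22%/3.95%, 3,073 CH2/CH3 groups; for type II: 3,648
residues, 1,216 triplets, 551 charged residues, 1,683 hydrophobic
residues, 4,152 CH2/CH3 groups.  They do not reproduce any real chain
residue-by-residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .composition import ALPHABET, ChainSequence, CompositionProfile, ResidueCounts

# Frozen synthetic per-TC residue tables (all three chains summed).
TYPE_I_COUNTS: dict[str, int] = {
    "G": 1078, "P": 378, "A": 498, "V": 75, "L": 81, "I": 36, "M": 23,
    "K": 94, "R": 165, "D": 110, "E": 153, "S": 55, "T": 58, "N": 48,
    "Q": 115, "H": 110, "Y": 13, "F": 98, "W": 4, "C": 41,
}

TYPE_II_COUNTS: dict[str, int] = {
    "G": 1216, "P": 700, "A": 448, "V": 101, "L": 90, "I": 40, "M": 24,
    "K": 100, "R": 180, "D": 130, "E": 141, "S": 150, "T": 90, "N": 80,
    "Q": 120, "H": 15, "Y": 13, "F": 10, "W": 0, "C": 0,
}


@dataclass(frozen=True)
class SequenceRecipe:
    """Recipe for a strict Gly-X-Y chain with stochastic X/Y positions."""

    n_triplets: int
    x_freq: dict[str, float]
    y_freq: dict[str, float]
    seed: int = 0
    hydroxylation: dict[str, float] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.n_triplets < 1:
            raise ValueError("need at least one triplet")
        for name, freq in (("x_freq", self.x_freq), ("y_freq", self.y_freq)):
            if abs(sum(freq.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
            bad = set(freq) - ALPHABET
            if bad:
                raise ValueError(f"{name}: unknown residues {sorted(bad)}")
            if any(v < 0 for v in freq.values()):
                raise ValueError(f"{name}: negative frequency")


def generate_chain(recipe: SequenceRecipe, chain_id: str = "synthetic") -> ChainSequence:
    """Draw a Gly-X-Y chain; identical seeds give identical sequences."""
    rng = np.random.default_rng(recipe.seed)
    xs = _draw(rng, recipe.x_freq, recipe.n_triplets)
    ys = _draw(rng, recipe.y_freq, recipe.n_triplets)
    if recipe.hydroxylation:
        xs = _hydroxylate(rng, xs, recipe.hydroxylation)
        ys = _hydroxylate(rng, ys, recipe.hydroxylation)
    seq = "".join(f"G{x}{y}" for x, y in zip(xs, ys))
    return ChainSequence(id=chain_id, residues=seq)


def _draw(rng: np.random.Generator, freq: dict[str, float], n: int) -> list[str]:
    codes = sorted(freq)
    probs = np.array([freq[c] for c in codes], dtype=float)
    probs /= probs.sum()
    return list(rng.choice(codes, size=n, p=probs))


def _hydroxylate(
    rng: np.random.Generator, residues: list[str], fractions: dict[str, float]
) -> list[str]:
    # P -> O (4-hydroxyproline), K -> J (5-hydroxylysine)
    mapping = {"P": "O", "K": "J"}
    out = []
    for code in residues:
        frac = fractions.get(code, 0.0)
        if code in mapping and rng.random() < frac:
            out.append(mapping[code])
        else:
            out.append(code)
    return out


def recipe_from_counts(
    counts: dict[str, int], n_triplets: int, seed: int = 0
) -> SequenceRecipe:
    """X/Y frequency recipe matching a fixture's non-Gly residue mix."""
    non_gly = {c: n for c, n in counts.items() if c != "G" and n > 0}
    total = sum(non_gly.values())
    freq = {c: n / total for c, n in non_gly.items()}
    return SequenceRecipe(n_triplets=n_triplets, x_freq=freq, y_freq=dict(freq), seed=seed)


def type_i_recipe(seed: int = 0, n_triplets: int = 1078) -> SequenceRecipe:
    """Recipe anchored to the type I fixture's non-Gly composition."""
    return recipe_from_counts(TYPE_I_COUNTS, n_triplets, seed)


def type_ii_recipe(seed: int = 0, n_triplets: int = 1216) -> SequenceRecipe:
    """Recipe anchored to the type II fixture's non-Gly composition."""
    return recipe_from_counts(TYPE_II_COUNTS, n_triplets, seed)


def fixture_profiles() -> tuple[CompositionProfile, CompositionProfile]:
    """The frozen synthetic composition profiles for both fibril types."""
    return (
        CompositionProfile.from_counts("typeI", ResidueCounts(dict(TYPE_I_COUNTS))),
        CompositionProfile.from_counts("typeII", ResidueCounts(dict(TYPE_II_COUNTS))),
    )


def fixture_counts(label: str) -> ResidueCounts:
    """Residue counts for a built-in fixture label."""
    if label == "typeI":
        return ResidueCounts(dict(TYPE_I_COUNTS))
    if label == "typeII":
        return ResidueCounts(dict(TYPE_II_COUNTS))
    raise ValueError(f"unknown fixture label {label!r}")


def write_fasta(chains: list[ChainSequence], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for chain in chains:
            fh.write(f">{chain.id}\n")
            for i in range(0, len(chain.residues), 60):
                fh.write(chain.residues[i : i + 60] + "\n")
    return path


def write_composition_tsv(rc: ResidueCounts, path: str | Path) -> Path:
    path = Path(path)
    lines = ["residue\tcount_per_TC"]
    lines += [f"{code}\t{rc.counts[code]}" for code in sorted(rc.counts)]
    path.write_text("\n".join(lines) + "\n")
    return path
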