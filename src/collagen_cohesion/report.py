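"""Assembly, comparison, and serialization of cohesion decompositions.

A decomposition collects the five mechanism components computed by the
``hbond``, ``water_bridges``, ``vdw``, ``hydrophobic`` and ``coulomb``
modules into one record per fibril type, with totals and fractional
shares.  A coarse-grained bead-spring reference energy is provided as an
external consistency check on the overall energy scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

MECHANISMS = ("hbond", "water_bridge", "vdw", "hydrophobic", "coulomb")


def round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


@dataclass(frozen=True)
class EnergyComponent:
    """One cohesion mechanism: interaction count, per-interaction energy,
    applied divisors, and the resulting total per TC molecule.

    ``n_interactions`` may be fractional where the count is a statistical
    expectation; display rounding happens only at serialization time.
    """

    mechanism: str
    n_interactions: float
    e_per_interaction: float
    divisors: tuple[float, ...] = ()
    total_kcal_mol: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.n_interactions < 0 or self.e_per_interaction < 0:
            raise ValueError("counts and energies must be non-negative")
        if self.total_kcal_mol is None:
            div = math.prod(self.divisors) if self.divisors else 1.0
            object.__setattr__(
                self, "total_kcal_mol", self.n_interactions * self.e_per_interaction / div
            )

    @property
    def total_display(self) -> int:
        """Total rounded to the nearest kcal/mol for reporting."""
        return round_half_up(self.total_kcal_mol)


@dataclass(frozen=True)
class CohesionDecomposition:
    """Five-mechanism decomposition of lateral cohesion for one fibril type."""

    fibril_type: str
    components: dict[str, EnergyComponent]
    total_kcal_mol: float
    fractions: dict[str, float]


@dataclass(frozen=True)
class BuehlerReference:
    """Bead-spring reference for the type I cohesion energy scale.

    A TC molecule is represented as ``n_beads`` beads, each interacting
    with 6 hexagonal neighbours through a Lennard-Jones well of depth
    ``epsilon_kcal``; ``f_gap`` discounts the bead pairs that face the
    D-period gap zones (calibrated, no independent derivation), and the
    factor 2 removes double counting of shared pairs.
    """

    epsilon_kcal: float = 6.72
    sigma_nm: float = 1.34
    n_beads: int = 218
    coordination: int = 6
    f_gap: float = 0.89


def buehler_reference(br: BuehlerReference = BuehlerReference()) -> float:
    """Reference cohesion energy: eps * n_beads * coordination * f_gap / 2."""
    if br.epsilon_kcal < 0 or br.n_beads < 0 or br.f_gap < 0:
        raise ValueError("reference parameters must be non-negative")
    return br.epsilon_kcal * br.n_beads * br.coordination * br.f_gap / 2.0


def assemble(components: list[EnergyComponent], label: str) -> CohesionDecomposition:
    """Combine exactly one component per mechanism into a decomposition."""
    by_mech = {}
    for comp in components:
        if comp.mechanism in by_mech:
            raise ValueError(f"duplicate component for mechanism {comp.mechanism!r}")
        by_mech[comp.mechanism] = comp
    missing = set(MECHANISMS) - set(by_mech)
    if missing:
        raise ValueError(f"missing components: {sorted(missing)}")
    total = sum(c.total_kcal_mol for c in by_mech.values())
    if total <= 0:
        raise ValueError("total cohesive energy must be positive")
    fractions = {m: by_mech[m].total_kcal_mol / total for m in MECHANISMS}
    return CohesionDecomposition(label, {m: by_mech[m] for m in MECHANISMS}, total, fractions)


def compare(d1: CohesionDecomposition, d2: CohesionDecomposition) -> dict:
    """Absolute/relative differences per mechanism and overall reduction."""
    if set(d1.components) != set(d2.components):
        raise ValueError("decompositions cover different mechanism sets")
    deltas = {
        m: d1.components[m].total_kcal_mol - d2.components[m].total_kcal_mol
        for m in MECHANISMS
    }
    return {
        "a": d1.fibril_type,
        "b": d2.fibril_type,
        "total_a": d1.total_kcal_mol,
        "total_b": d2.total_kcal_mol,
        "delta_total": d1.total_kcal_mol - d2.total_kcal_mol,
        "reduction": (d1.total_kcal_mol - d2.total_kcal_mol) / d1.total_kcal_mol,
        "delta_by_mechanism": deltas,
    }


def _as_dict(d: CohesionDecomposition, config_echo: dict | None) -> dict:
    from . import __version__

    return {
        "fibril_type": d.fibril_type,
        "package_version": __version__,
        "total_kcal_mol": round(d.total_kcal_mol, 1),
        "total_display": round_half_up(d.total_kcal_mol),
        "components": {
            m: {
                "n_interactions": round(c.n_interactions, 3),
                "e_per_interaction_kcal_mol": round(c.e_per_interaction, 4),
                "divisors": list(c.divisors),
                "total_kcal_mol": round(c.total_kcal_mol, 1),
                "total_display": c.total_display,
                "share": round(d.fractions[m], 4),
                "share_percent": round_half_up(100 * d.fractions[m]),
            }
            for m, c in d.components.items()
        },
        "config": config_echo or {},
    }


def write_report(
    d: CohesionDecomposition,
    path: str | Path,
    format: str = "json",
    config_echo: dict | None = None,
) -> Path:
    """Serialize a decomposition deterministically (no timestamps)."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(_as_dict(d, config_echo), indent=2, sort_keys=True) + "\n")
    elif format == "tsv":
        lines = ["mechanism\tn_interactions\te_per_interaction\ttotal_kcal_mol\tshare"]
        for m in MECHANISMS:
            c = d.components[m]
            lines.append(
                f"{m}\t{c.n_interactions:.3f}\t{c.e_per_interaction:.4f}"
                f"\t{c.total_kcal_mol:.1f}\t{d.fractions[m]:.4f}"
            )
        lines.append(f"total\t\t\t{d.total_kcal_mol:.1f}\t1.0000")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def read_report(path: str | Path) -> CohesionDecomposition:
    """Read back a JSON report written by :func:`write_report`."""
    data = json.loads(Path(path).read_text())
    components = {
        m: EnergyComponent(
            mechanism=m,
            n_interactions=c["n_interactions"],
            e_per_interaction=c["e_per_interaction_kcal_mol"],
            divisors=tuple(c["divisors"]),
            total_kcal_mol=c["total_kcal_mol"],
        )
        for m, c in data["components"].items()
    }
    total = data["total_kcal_mol"]
    fractions = {m: c.total_kcal_mol / total for m, c in components.items()}
    return CohesionDecomposition(data["fibril_type"], components, total, fractions)
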