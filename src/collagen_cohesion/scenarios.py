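"""Scenario configuration: every tunable constant of the model in one place.

A :class:`Scenario` bundles the hydration state, lattice reference,
dielectric constants and per-mechanism energy constants for one fibril
type.  ``scenario("typeI")`` / ``scenario("typeII")`` return the two
built-in parameterisations; any field can be overridden by keyword.
Scenarios round-trip through YAML for use as external config files.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml


@dataclass(frozen=True)
class Scenario:
    """Full parameterisation of the cohesion model for one fibril type."""

    label: str
    # hydration and geometry
    hydration_gg: float
    ref_hydration_gg: float = 1.6
    ref_lattice_A: float = 16.52
    rho_collagen: float = 1.35
    rho_water: float = 1.00
    core_diameter_A: float = 10.0
    eps_protein: float = 4.0
    eps_water: float = 78.0
    # hydrogen bonds
    hbond_n_total: int = 5017
    hbond_direct_ref: int = 392
    hbond_c_ref: float = 1.6
    hill_n: float = 1.0
    e_hbond: float = 2.64
    # water bridges
    bridge_type: str = "single"
    e_bridge_single: float = 0.46
    bridge_leg_A: float = 3.02
    donor_acceptor_single_A: float = 4.92
    ow_ow_A: float = 2.8
    decay_exponent: int = 3
    bridge_sharing: float = 2.0
    # van der Waals
    vdw_accessibility: float = 0.5
    vdw_sharing: float = 2.0
    vdw_total_pinned: float | None = None
    # hydrophobic
    e_chx_ref: float = 1.1
    waters_displaced_ref: float = 19.2
    waters_displaced: float = 19.2
    hydrophobic_accessibility_divisor: float = 2.0
    hydrophobic_sharing_divisor: float = 2.0
    # coulomb
    n_window: int = 9
    e_salt_ref: float = 3.0
    # composition source: a built-in fixture label or a TSV path
    composition: str = "typeI"

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Scenario":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


_TYPE_I = Scenario(
    label="typeI",
    hydration_gg=1.6,
    e_hbond=2.64,
    bridge_type="single",
    vdw_total_pinned=414.0,
    waters_displaced=16.5,
    n_window=9,
    composition="typeI",
)

_TYPE_II = Scenario(
    label="typeII",
    hydration_gg=2.39,
    e_hbond=1.58,
    bridge_type="double",
    vdw_total_pinned=125.0,
    waters_displaced=19.2,
    n_window=7,
    composition="typeII",
)


def scenario(label: str, **overrides) -> Scenario:
    """Return a built-in scenario (``typeI``/``typeII``), with overrides.

    ``label="custom"`` builds a scenario from overrides alone (hydration
    required).
    """
    if label == "typeI":
        base = _TYPE_I
    elif label == "typeII":
        base = _TYPE_II
    elif label == "custom":
        if "hydration_gg" not in overrides:
            raise ValueError("custom scenario needs hydration_gg")
        base = Scenario(label="custom", hydration_gg=overrides.pop("hydration_gg"))
    else:
        raise ValueError(f"unknown scenario label {label!r}")
    if overrides:
        unknown = set(overrides) - set(base.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown scenario fields: {sorted(unknown)}")
        base = replace(base, **overrides)
    return base
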