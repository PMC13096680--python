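"""Salt-bridge statistics and dielectric-scaled electrostatic energy.

Only the four principal charged residues (Asp-, Glu-, Lys+, Arg+) are
considered; each is a unit point charge at the tip of its side chain.
A charged residue faces a window of n consecutive residues on the
neighbouring molecule (9 for type I, 7 for the wider-spaced type II);
with charged-residue fraction P the chance that at least one facing
residue is charged is 1 - (1-P)^n, and each realised pair is shared
between the two molecules (divisor 2).  The per-pair energy is a
representative salt-bridge value (3.0 kcal/mol at type I hydration)
scaled by the inverse ratio of effective dielectric constants for other
hydration states.
"""

from __future__ import annotations

from dataclasses import dataclass

from .report import EnergyComponent, round_half_up

#: Side-chain reach from the backbone C-alpha to the charged terminus (A).
SIDE_CHAIN_REACH_A = {"R": 6.3, "K": 6.2, "D": 3.6, "E": 4.8}

#: Typical salt-bridge contact distance (A); descriptive only — energies
#: come from the representative per-pair value, not a Coulomb-law
#: evaluation at this distance.
CONTACT_DISTANCE_A = 3.07

#: Accessibility windows per fibril type (facing residues reachable by a
#: charged side chain across the radial gap).
DEFAULT_WINDOWS = {"typeI": 9, "typeII": 7}


@dataclass(frozen=True)
class SaltBridgeModel:
    """Inputs of the statistical salt-bridge count for one fibril type."""

    charged_fraction: float
    n_window: int
    n_charged: int
    e_ref: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 < self.charged_fraction < 1.0:
            raise ValueError("charged fraction must lie strictly in (0, 1)")
        if self.n_window < 1 or self.n_charged < 0 or self.e_ref <= 0:
            raise ValueError("invalid salt-bridge model parameters")


def pairing_probability(p: float, n_window: int) -> float:
    """Chance that at least one of n facing residues is oppositely charged."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("charged fraction must lie in [0, 1]")
    if n_window < 1:
        raise ValueError("window must contain at least one residue")
    return 1.0 - (1.0 - p) ** n_window


def salt_bridge_count(p_pair: float, n_charged: int) -> int:
    """Salt bridges per TC (display value): round(p x N_charged / 2)."""
    if n_charged < 0:
        raise ValueError("charged-residue count must be non-negative")
    return round_half_up(p_pair * n_charged / 2.0)


def scaled_bridge_energy(e_ref: float, eps_ref: float, eps_new: float) -> float:
    """Per-pair energy rescaled by the dielectric ratio eps_ref / eps_new."""
    if eps_ref <= 0 or eps_new <= 0:
        raise ValueError("permittivities must be positive")
    return e_ref * eps_ref / eps_new


def accessibility_window(
    gap_A: float, axial_rise_A: float, n_default: int
) -> int:
    """Facing-residue window for a charged side chain.

    The geometric rule linking side-chain reach, radial gap and axial rise
    to the window size is not reconstructible from published intermediate
    values, so the per-type defaults (9 / 7) are returned as configured.
    """
    if gap_A <= 0 or axial_rise_A <= 0:
        raise ValueError("gap and axial rise must be positive")
    if n_default < 1:
        raise ValueError("window must contain at least one residue")
    return n_default


def coulomb_component(p_pair: float, n_charged: int, e_pair: float) -> EnergyComponent:
    """Electrostatic energy component from unrounded intermediates.

    The expected bridge count p x N/2 is kept fractional internally so the
    total is not contaminated by display rounding; ``salt_bridge_count``
    supplies the rounded count for reporting.
    """
    if e_pair < 0:
        raise ValueError("per-pair energy must be non-negative")
    n_bridges = p_pair * n_charged / 2.0
    return EnergyComponent("coulomb", n_bridges, e_pair)
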