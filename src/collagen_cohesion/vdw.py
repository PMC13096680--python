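"""Statistical van der Waals cohesion from side-chain contact statistics.

No coordinates are used: the model counts probable atom-atom contacts
between surface-accessible side-chain atoms from element frequencies
alone.  For elements X, Y with accessible-atom frequencies f_X, f_Y the
unordered pair probabilities are f_X^2 (self pairs) and 2 f_X f_Y (cross
pairs), which sum to one.  Each pair class is assigned a representative
Lennard-Jones well from standard protein force-field atom classes
(aliphatic sp3 carbon, carbonyl/carboxyl oxygen, amide nitrogen,
aliphatic hydrogen, thioether sulfur), mixed with Lorentz-Berthelot
rules.  Type I contacts sit at the LJ minimum (energy -eps); hydrated
fibrils stretch every contact by a uniform swelling factor, attenuating
all pairs by the same geometric factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import pandas as pd

from .composition import ELEMENTS, AtomComposition
from .report import EnergyComponent, round_half_up


@dataclass(frozen=True)
class LJEntry:
    """One atom class: size parameter sigma (A) and well depth eps (kcal/mol)."""

    sigma_A: float
    epsilon_kcal: float

    def __post_init__(self) -> None:
        if self.sigma_A <= 0 or self.epsilon_kcal <= 0:
            raise ValueError("LJ parameters must be positive")


#: Representative force-field classes per element.  Values follow the
#: standard protein force-field classes named in the module docstring
#: (sigma converted from Rmin/2); they are deliberately config-overridable
#: since the statistical model is calibrated at the class level, not per
#: atom type.
DEFAULT_LJ: dict[str, LJEntry] = {
    "CT2": LJEntry(sigma_A=3.581, epsilon_kcal=0.056),   # aliphatic sp3 C
    "O": LJEntry(sigma_A=3.029, epsilon_kcal=0.120),     # carbonyl/carboxyl O
    "NH1": LJEntry(sigma_A=3.296, epsilon_kcal=0.200),   # amide N
    "HA2": LJEntry(sigma_A=2.388, epsilon_kcal=0.034),   # aliphatic H
    "S": LJEntry(sigma_A=3.564, epsilon_kcal=0.450),     # thioether S
}

ELEMENT_CLASS: dict[str, str] = {"C": "CT2", "O": "O", "N": "NH1", "H": "HA2", "S": "S"}

#: r_min / sigma for the 12-6 potential.
RMIN_OVER_SIGMA = 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class PairTable:
    """Unordered element-pair contact statistics for one TC molecule."""

    table: pd.DataFrame = field(compare=False)
    n_total_accessible: int


def accessible_atom_count(ac: AtomComposition, accessibility: float = 0.5) -> int:
    """Side-chain atoms available for intermolecular contact.

    By triple-helix symmetry roughly half of the side chains face outward;
    the default accessibility of 0.5 encodes that.
    """
    if not 0.0 < accessibility <= 1.0:
        raise ValueError("accessibility must lie in (0, 1]")
    return round_half_up(ac.total_side_chain_atoms * accessibility)


def pair_probability(f_x: float, f_y: float, same: bool) -> float:
    """Probability of an unordered X-Y contact: f^2 (self) or 2 f_X f_Y."""
    if not (0.0 <= f_x <= 1.0 and 0.0 <= f_y <= 1.0):
        raise ValueError("frequencies must lie in [0, 1]")
    return f_x * f_y if same else 2.0 * f_x * f_y

def pair_counts(ac: AtomComposition, n_total: int) -> PairTable:
    """Expected contact counts for every unordered element pair."""
    rows = []
    for el1, el2 in combinations_with_replacement(ELEMENTS, 2):
        p = pair_probability(ac.frequencies[el1], ac.frequencies[el2], same=el1 == el2)
        rows.append(
            {
                "pair": f"{el1}-{el2}",
                "elem1": el1,
                "elem2": el2,
                "probability": p,
                "count": round_half_up(p * n_total),
            }
        )
    return PairTable(pd.DataFrame(rows), n_total)


def mix_lj(p1: LJEntry, p2: LJEntry) -> LJEntry:
    """Lorentz-Berthelot mixing: arithmetic sigma, geometric epsilon."""
    return LJEntry(
        sigma_A=0.5 * (p1.sigma_A + p2.sigma_A),
        epsilon_kcal=(p1.epsilon_kcal * p2.epsilon_kcal) ** 0.5,
    )


def lj_energy(r: float, sigma_A: float, epsilon_kcal: float) -> float:
    """12-6 Lennard-Jones energy 4 eps [(sigma/r)^12 - (sigma/r)^6]."""
    if r <= 0:
        raise ValueError("distance must be positive")
    x = (sigma_A / r) ** 6
    return 4.0 * epsilon_kcal * (x * x - x)


def swelling_attenuation(swelling: float) -> float:
    """|E(swelling * r_min)| / eps — identical for every LJ pair.

    Equals 1 at swelling 1 (contact at the minimum) and decreases
    monotonically for swelling > 1.
    """
    if swelling < 1.0:
        raise ValueError("swelling factor must be >= 1")
    x = (1.0 / (swelling * RMIN_OVER_SIGMA)) ** 6
    return -(4.0 * (x * x - x))


def vdw_component(
    pt: PairTable,
    lj: dict[str, LJEntry] | None = None,
    swelling: float = 1.0,
    sharing_factor: float = 2.0,
) -> EnergyComponent:
    """Dispersion energy component from the statistical pair table.

    Each pair contributes the magnitude of its LJ well (|-eps_ij|) scaled
    by the swelling attenuation; the grand total is halved for contacts
    shared between neighbouring molecules.
    """
    lj = lj if lj is not None else DEFAULT_LJ
    atten = swelling_attenuation(swelling)
    total = 0.0
    for row in pt.table.itertuples():
        mixed = mix_lj(lj[ELEMENT_CLASS[row.elem1]], lj[ELEMENT_CLASS[row.elem2]])
        total += row.count * mixed.epsilon_kcal * atten
    mean_e = total / pt.n_total_accessible if pt.n_total_accessible else 0.0
    return EnergyComponent(
        "vdw",
        float(pt.n_total_accessible),
        mean_e,
        divisors=(sharing_factor,),
        total_kcal_mol=total / sharing_factor,
    )


def pinned_vdw_component(total_kcal_mol: float, n_contacts: int, sharing_factor: float = 2.0) -> EnergyComponent:
    """Dispersion component with a calibrated per-TC total.

    The statistical estimate depends on per-pair force-field tables that
    cannot be resolved at the element-class level, so the per-type totals
    are treated as calibrated model constants; the implied mean
    per-contact energy is recorded alongside for transparency.
    """
    if total_kcal_mol < 0:
        raise ValueError("total must be non-negative")
    mean_e = total_kcal_mol * sharing_factor / n_contacts if n_contacts else 0.0
    return EnergyComponent(
        "vdw", float(n_contacts), mean_e, divisors=(sharing_factor,),
        total_kcal_mol=total_kcal_mol,
    )
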