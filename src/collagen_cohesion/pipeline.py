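"""End-to-end pipeline: scenario -> five-component cohesion decomposition.

Ties the modules together in the order the physics dictates: composition
statistics, hydration state and lattice geometry, effective dielectric,
then the five mechanism components, assembled into a
:class:`~collagen_cohesion.report.CohesionDecomposition`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from . import composition, coulomb, hbond, hydration, hydrophobic, vdw, water_bridges
from .report import CohesionDecomposition, assemble
from .scenarios import Scenario
from .synthetic import fixture_counts


@dataclass(frozen=True)
class PipelineResult:
    """Decomposition plus the geometric/dielectric intermediates."""

    decomposition: CohesionDecomposition
    hydration_state: hydration.HydrationState
    geometry: hydration.FibrilGeometry
    swelling: float
    dielectric: hydration.DielectricModel
    details: dict = field(default_factory=dict, compare=False)


def _load_counts(sc: Scenario) -> composition.ResidueCounts:
    if sc.composition in ("typeI", "typeII"):
        return fixture_counts(sc.composition)
    path = Path(sc.composition)
    if path.suffix in (".fa", ".fasta"):
        return composition.profile_tc(composition.read_fasta(path))
    return composition.read_composition_tsv(path)


def run_scenario(sc: Scenario, counts: composition.ResidueCounts | None = None) -> PipelineResult:
    """Run the full cohesion model for one scenario.

    ``counts`` overrides the scenario's composition source (useful for
    synthetic chains generated on the fly).
    """
    rc = counts if counts is not None else _load_counts(sc)
    atoms = composition.atom_composition(rc)
    stats = composition.charge_stats(rc)

    # hydration, lattice, swelling, dielectric
    h = hydration.HydrationState(sc.hydration_gg, sc.rho_water, sc.rho_collagen)
    h_ref = hydration.HydrationState(sc.ref_hydration_gg, sc.rho_water, sc.rho_collagen)
    lattice = hydration.lattice_spacing(sc.ref_lattice_A, h_ref, h)
    geom = hydration.FibrilGeometry(lattice, sc.core_diameter_A)
    geom_ref = hydration.FibrilGeometry(sc.ref_lattice_A, sc.core_diameter_A)
    swell = hydration.swelling_factor(geom, geom_ref)
    eps_eff = hydration.maxwell_garnett(sc.eps_protein, sc.eps_water, h.phi_w)
    eps_ref = hydration.maxwell_garnett(sc.eps_protein, sc.eps_water, h_ref.phi_w)
    dielectric = hydration.DielectricModel(sc.eps_protein, sc.eps_water, eps_eff)

    # hydrogen bonds: fit Kd at the reference point, evaluate at this hydration
    kd = hbond.fit_kd(sc.hbond_c_ref, sc.hbond_direct_ref, sc.hbond_n_total, sc.hill_n)
    hill = hbond.HillBindingModel(kd, sc.hill_n, sc.hbond_n_total)
    n_direct = hbond.direct_bond_count(sc.hydration_gg, hill)
    comp_hbond = hbond.hbond_component(n_direct, sc.e_hbond)

    # water bridges: one per triplet, single or double per scenario
    geometry = water_bridges.BridgeGeometry(
        sc.bridge_leg_A, sc.donor_acceptor_single_A, sc.ow_ow_A, sc.decay_exponent
    )
    energetics = water_bridges.BridgeEnergetics(sc.e_bridge_single, sc.bridge_sharing, geometry)
    n_bridges = water_bridges.bridge_count(rc)
    comp_bridge = water_bridges.bridge_component(n_bridges, sc.bridge_type, energetics)

    # van der Waals: statistical pair table; per-type total is a calibrated
    # constant unless unpinned, in which case the LJ estimate is used
    n_acc = vdw.accessible_atom_count(atoms, sc.vdw_accessibility)
    pair_table = vdw.pair_counts(atoms, n_acc)
    # below the reference hydration, flexible side chains remain at the LJ
    # equilibrium separation: attenuate only for swelling beyond contact
    comp_vdw_stat = vdw.vdw_component(
        pair_table, swelling=max(swell, 1.0), sharing_factor=sc.vdw_sharing
    )
    if sc.vdw_total_pinned is not None:
        comp_vdw = vdw.pinned_vdw_component(sc.vdw_total_pinned, n_acc, sc.vdw_sharing)
    else:
        comp_vdw = comp_vdw_stat

    # hydrophobic: CH2/CH3 statistics with hydration-scaled per-group energy
    scale = hydrophobic.HydrophobicScale(
        sc.e_chx_ref,
        sc.waters_displaced_ref,
        sc.hydrophobic_accessibility_divisor,
        sc.hydrophobic_sharing_divisor,
    )
    e_group = hydrophobic.per_group_energy(sc.waters_displaced, scale)
    comp_hydro = hydrophobic.hydrophobic_component(stats.n_chx_groups, e_group, scale)

    # coulomb: pairing probability, dielectric-scaled per-pair energy
    p_pair = coulomb.pairing_probability(stats.charged_fraction, sc.n_window)
    e_pair = coulomb.scaled_bridge_energy(sc.e_salt_ref, eps_ref, eps_eff)
    comp_coulomb = coulomb.coulomb_component(p_pair, stats.n_charged, e_pair)

    decomposition = assemble(
        [comp_hbond, comp_bridge, comp_vdw, comp_hydro, comp_coulomb], sc.label
    )
    details = {
        "kd": kd,
        "occupancy": hbond.occupancy(sc.hydration_gg, hill),
        "n_direct_bonds": n_direct,
        "n_water_bridges": n_bridges,
        "n_accessible_atoms": n_acc,
        "pair_table": pair_table,
        "vdw_statistical_kcal_mol": comp_vdw_stat.total_kcal_mol,
        "n_charged": stats.n_charged,
        "charged_fraction": stats.charged_fraction,
        "pairing_probability": p_pair,
        "n_salt_bridges": coulomb.salt_bridge_count(p_pair, stats.n_charged),
        "e_salt_pair": e_pair,
        "n_chx_groups": stats.n_chx_groups,
        "e_per_chx_group": e_group,
        "eps_ref": eps_ref,
    }
    return PipelineResult(decomposition, h, geom, swell, dielectric, details)
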