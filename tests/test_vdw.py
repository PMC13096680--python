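"""Contact statistics, Lennard-Jones energetics, and swelling attenuation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from collagen_cohesion.composition import ResidueCounts, atom_composition
from collagen_cohesion.vdw import (
    DEFAULT_LJ,
    RMIN_OVER_SIGMA,
    LJEntry,
    accessible_atom_count,
    lj_energy,
    mix_lj,
    pair_counts,
    pair_probability,
    swelling_attenuation,
    vdw_component,
)


def random_frequencies(draw):
    weights = draw(
        st.lists(st.floats(0.01, 1.0), min_size=5, max_size=5)
    )
    total = sum(weights)
    return [w / total for w in weights]


class TestPairStatistics:
    def test_published_co_probability(self):
        assert pair_probability(0.2922, 0.0395, same=False) == pytest.approx(0.0231, abs=5e-5)

    def test_self_pair_is_squared_frequency(self):
        assert pair_probability(0.3, 0.3, same=True) == pytest.approx(0.09)

    def test_zero_frequency(self):
        assert pair_probability(0.0, 0.5, same=False) == 0.0

    def test_type_i_co_contacts(self, type_i):
        n_acc = accessible_atom_count(type_i.atoms)
        table = pair_counts(type_i.atoms, n_acc).table
        co = table.loc[table["pair"] == "C-O", "count"].item()
        assert co == 238

    def test_accessibility_scaling(self, type_i):
        full = accessible_atom_count(type_i.atoms, 1.0)
        assert full == type_i.atoms.total_side_chain_atoms
        assert accessible_atom_count(type_i.atoms, 0.5) == pytest.approx(full / 2, abs=1)

    def test_single_element_composition(self):
        ac = atom_composition(ResidueCounts({"A": 10}))  # C and H only
        pt = pair_counts(ac, 100)
        assert pt.table["probability"].sum() == pytest.approx(1.0, abs=1e-9)

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_probabilities_normalise_for_any_frequencies(self, data):
        freqs = random_frequencies(data.draw)
        total = 0.0
        for i in range(5):
            for j in range(i, 5):
                total += pair_probability(freqs[i], freqs[j], same=i == j)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_counts_sum_to_accessible_total(self, type_i, type_ii):
        for prof in (type_i, type_ii):
            n_acc = accessible_atom_count(prof.atoms)
            pt = pair_counts(prof.atoms, n_acc)
            assert abs(pt.table["count"].sum() - n_acc) <= len(pt.table)

    def test_equal_frequency_self_cross_ratio(self):
        # two equal frequencies: self:self:cross = 1:1:2 from (1/2 + 1/2)^2
        p_self = pair_probability(0.5, 0.5, same=True)
        p_cross = pair_probability(0.5, 0.5, same=False)
        assert p_cross == pytest.approx(2 * p_self)


class TestLennardJones:
    def test_mixing_rules(self):
        mixed = mix_lj(LJEntry(3.0, 0.1), LJEntry(4.0, 0.4))
        assert mixed.sigma_A == pytest.approx(3.5)
        assert mixed.epsilon_kcal == pytest.approx(0.2)

    def test_mixing_idempotent_and_symmetric(self):
        a, b = LJEntry(3.2, 0.12), LJEntry(2.4, 0.05)
        assert mix_lj(a, a) == a
        assert mix_lj(a, b) == mix_lj(b, a)

    def test_minimum_depth_is_minus_epsilon(self):
        sigma, eps = 3.5, 0.11
        assert lj_energy(RMIN_OVER_SIGMA * sigma, sigma, eps) == pytest.approx(-eps)

    def test_zero_at_sigma(self):
        assert lj_energy(3.5, 3.5, 0.11) == pytest.approx(0.0, abs=1e-12)

    def test_attenuation_at_1_4_rmin(self):
        # analytic: 4[(1/1.4)^12 x 2^-2 ... ] = 0.2480 of the well depth
        assert swelling_attenuation(1.4) == pytest.approx(0.2481, abs=5e-4)

    def test_attenuation_identity_at_contact(self):
        assert swelling_attenuation(1.0) == pytest.approx(1.0)

    def test_attenuation_uniform_across_pairs(self):
        # geometric attenuation in sigma-reduced units is pair independent
        s = 1.37
        for entry in DEFAULT_LJ.values():
            r = s * RMIN_OVER_SIGMA * entry.sigma_A
            ratio = -lj_energy(r, entry.sigma_A, entry.epsilon_kcal) / entry.epsilon_kcal
            assert ratio == pytest.approx(swelling_attenuation(s), abs=1e-9)


class TestComponent:
    def test_swelling_reduces_energy_monotonically(self, type_i):
        n_acc = accessible_atom_count(type_i.atoms)
        pt = pair_counts(type_i.atoms, n_acc)
        totals = [vdw_component(pt, swelling=s).total_kcal_mol for s in (1.0, 1.2, 1.4, 1.8)]
        assert all(a > b > 0 for a, b in zip(totals, totals[1:]))

    def test_linear_in_counts(self, type_i):
        n_acc = accessible_atom_count(type_i.atoms)
        one = vdw_component(pair_counts(type_i.atoms, n_acc)).total_kcal_mol
        two = vdw_component(pair_counts(type_i.atoms, 2 * n_acc)).total_kcal_mol
        assert two == pytest.approx(2 * one, rel=0.01)

    def test_swelling_ratio_is_pure_attenuation(self, type_i):
        n_acc = accessible_atom_count(type_i.atoms)
        pt = pair_counts(type_i.atoms, n_acc)
        base = vdw_component(pt, swelling=1.0).total_kcal_mol
        swollen = vdw_component(pt, swelling=1.4).total_kcal_mol
        assert swollen / base == pytest.approx(swelling_attenuation(1.4), abs=1e-9)

    def test_empty_composition(self):
        ac = atom_composition(ResidueCounts({}))
        pt = pair_counts(ac, 0)
        assert vdw_component(pt).total_kcal_mol == 0.0
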