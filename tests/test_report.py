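"""Decomposition assembly, cross-type comparison, and serialization."""

import pytest

from collagen_cohesion.report import (
    MECHANISMS,
    BuehlerReference,
    EnergyComponent,
    assemble,
    buehler_reference,
    compare,
    read_report,
    write_report,
)


def make_components(totals):
    return [
        EnergyComponent(m, 1.0, t, total_kcal_mol=t) for m, t in zip(MECHANISMS, totals)
    ]


TYPE_I_TOTALS = (1035.0, 248.0, 414.0, 726.0, 622.0)
TYPE_II_TOTALS = (426.0, 72.0, 125.0, 1142.0, 443.0)


class TestAssemble:
    def test_type_i_total_and_shares(self):
        d = assemble(make_components(TYPE_I_TOTALS), "typeI")
        assert d.total_kcal_mol == pytest.approx(3045, abs=1)
        shares = {m: round(100 * f) for m, f in d.fractions.items()}
        assert shares == {
            "hbond": 34, "water_bridge": 8, "vdw": 14, "hydrophobic": 24, "coulomb": 20,
        }

    def test_type_ii_total_and_hydrophobic_share(self):
        d = assemble(make_components(TYPE_II_TOTALS), "typeII")
        assert d.total_kcal_mol == pytest.approx(2208, abs=1)
        assert round(100 * d.fractions["hydrophobic"]) == 52

    def test_fractions_sum_to_one(self):
        d = assemble(make_components(TYPE_I_TOTALS), "typeI")
        assert sum(d.fractions.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(round(100 * f) for f in d.fractions.values()) in (99, 100, 101)

    def test_duplicate_mechanism_rejected(self):
        comps = make_components(TYPE_I_TOTALS)
        comps[1] = EnergyComponent("hbond", 1.0, 10.0)
        with pytest.raises(ValueError, match="duplicate|missing"):
            assemble(comps, "x")

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            assemble(make_components((0.0,) * 5), "x")


class TestCompare:
    def test_cross_type_reduction(self):
        d1 = assemble(make_components(TYPE_I_TOTALS), "typeI")
        d2 = assemble(make_components(TYPE_II_TOTALS), "typeII")
        rec = compare(d1, d2)
        assert rec["reduction"] == pytest.approx(0.275, abs=0.005)
        assert rec["delta_by_mechanism"]["hbond"] == pytest.approx(609.0)

    def test_identity(self):
        d = assemble(make_components(TYPE_I_TOTALS), "typeI")
        rec = compare(d, d)
        assert rec["reduction"] == 0.0
        assert all(v == 0.0 for v in rec["delta_by_mechanism"].values())

    def test_antisymmetric_deltas(self):
        d1 = assemble(make_components(TYPE_I_TOTALS), "typeI")
        d2 = assemble(make_components(TYPE_II_TOTALS), "typeII")
        fwd, rev = compare(d1, d2), compare(d2, d1)
        for m in MECHANISMS:
            assert fwd["delta_by_mechanism"][m] == -rev["delta_by_mechanism"][m]
        assert fwd["delta_total"] == -rev["delta_total"]


class TestBuehlerReference:
    def test_bead_spring_energy_scale(self):
        assert buehler_reference(BuehlerReference()) == pytest.approx(3911, abs=5)

    def test_zero_gap_factor(self):
        assert buehler_reference(BuehlerReference(f_gap=0.0)) == 0.0

    def test_linear_in_bead_count(self):
        one = buehler_reference(BuehlerReference(n_beads=218))
        two = buehler_reference(BuehlerReference(n_beads=436))
        assert two == pytest.approx(2 * one)


class TestSerialization:
    def test_json_round_trip(self, tmp_path):
        d = assemble(make_components(TYPE_I_TOTALS), "typeI")
        p = write_report(d, tmp_path / "r.json")
        back = read_report(p)
        assert back.fibril_type == d.fibril_type
        assert back.total_kcal_mol == pytest.approx(d.total_kcal_mol, abs=0.1)
        for m in MECHANISMS:
            assert back.components[m].total_kcal_mol == pytest.approx(
                d.components[m].total_kcal_mol, abs=0.1
            )

    def test_tsv_has_five_mechanisms_plus_total(self, tmp_path):
        d = assemble(make_components(TYPE_II_TOTALS), "typeII")
        p = write_report(d, tmp_path / "r.tsv", format="tsv")
        lines = p.read_text().strip().splitlines()
        assert len(lines) == 1 + 5 + 1
        assert lines[-1].startswith("total")

    def test_deterministic_output(self, tmp_path):
        d = assemble(make_components(TYPE_I_TOTALS), "typeI")
        a = write_report(d, tmp_path / "a.json").read_text()
        b = write_report(d, tmp_path / "b.json").read_text()
        assert a == b

    def test_unknown_format_rejected(self, tmp_path):
        d = assemble(make_components(TYPE_I_TOTALS), "typeI")
        with pytest.raises(ValueError):
            write_report(d, tmp_path / "r.xml", format="xml")
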