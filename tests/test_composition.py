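"""Residue parsing, side-chain formulas, and per-TC statistics."""

import pytest

from collagen_cohesion import composition as comp
from collagen_cohesion.composition import (
    BACKBONE_FORMULA,
    ELEMENTS,
    FULL_FORMULAS,
    ChainSequence,
    ResidueCounts,
    SequenceError,
    atom_composition,
    charge_stats,
    chx_stats,
    profile_tc,
    read_composition_tsv,
    read_fasta,
    sidechain_formula,
)


class TestFasta:
    def test_minimal_record(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nGPA\n")
        chains = read_fasta(p)
        assert len(chains) == 1 and chains[0].residues == "GPA"

    def test_multi_record_order_and_upcasing(self, tmp_path):
        p = tmp_path / "m.fa"
        p.write_text(">c1\ngpagpa\n>c2\nGAP\n>c3\nGPK\n")
        chains = read_fasta(p)
        assert [c.id for c in chains] == ["c1", "c2", "c3"]
        assert chains[0].residues == "GPAGPA"

    def test_illegal_residue_reports_position(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text(">x\nGPB\n")
        with pytest.raises(SequenceError, match="position 3"):
            read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        with pytest.raises(SequenceError):
            read_fasta(p)


class TestSidechainFormula:
    def test_arginine_is_C4H10N3(self):
        assert sidechain_formula("R") == {"C": 4, "H": 10, "O": 0, "N": 3, "S": 0}

    def test_glycine_keeps_one_hydrogen(self):
        assert sidechain_formula("G") == {"C": 0, "H": 1, "O": 0, "N": 0, "S": 0}

    def test_alanine_is_CH3(self):
        side = sidechain_formula("A")
        assert (side["C"], side["H"]) == (1, 3)

    @pytest.mark.parametrize("residue", sorted(FULL_FORMULAS))
    def test_backbone_plus_side_chain_conserves_atoms(self, residue):
        side = sidechain_formula(residue)
        for el in ELEMENTS:
            assert side[el] + BACKBONE_FORMULA[el] == FULL_FORMULAS[residue][el]

    def test_unknown_code_rejected(self):
        with pytest.raises(SequenceError):
            sidechain_formula("B")


class TestProfile:
    def test_homotrimer_multiplicity(self):
        rc = profile_tc([ChainSequence("a", "GPAGPA", multiplicity=3)])
        assert rc.n_residues == 18 and rc.n_triplets == 6

    def test_zero_chains_rejected(self):
        with pytest.raises(ValueError):
            profile_tc([])

    def test_additivity(self):
        c1 = ChainSequence("a", "GPAGPA")
        c2 = ChainSequence("b", "GKRGDE")
        merged = profile_tc([c1, c2])
        summed = profile_tc([c1]) + profile_tc([c2])
        assert merged.counts == summed.counts

    def test_triplet_fraction(self):
        assert ChainSequence("a", "GPAGPA").triplet_fraction() == 1.0
        assert ChainSequence("a", "PPAGPA").triplet_fraction() == 0.5

    def test_tsv_round_trip(self, tmp_path, type_i):
        from collagen_cohesion.synthetic import write_composition_tsv

        p = write_composition_tsv(type_i.residue_counts, tmp_path / "t.tsv")
        assert read_composition_tsv(p).counts == type_i.residue_counts.counts


class TestAtomComposition:
    def test_arginine_block_totals(self):
        rc = ResidueCounts({"R": 165})
        ac = atom_composition(rc)
        assert ac.side_chain_atoms["C"] == 660
        assert ac.side_chain_atoms["H"] == 1650
        assert ac.side_chain_atoms["N"] == 495

    def test_all_gly_is_pure_hydrogen(self):
        ac = atom_composition(ResidueCounts({"G": 30}))
        assert ac.frequencies["H"] == 1.0

    def test_frequencies_sum_to_one(self, type_i, type_ii):
        for prof in (type_i, type_ii):
            assert abs(sum(prof.atoms.frequencies.values()) - 1.0) < 1e-12


class TestFixtureAnchors:
    """The frozen fixtures must satisfy all published composition statistics."""

    def test_type_i_residue_and_triplet_counts(self, type_i):
        assert type_i.residue_counts.n_residues == 3233
        assert type_i.residue_counts.n_triplets == 1078

    def test_type_i_arginine_count(self, type_i):
        assert type_i.residue_counts.counts["R"] == 165

    def test_type_i_charged_residues(self, type_i):
        assert type_i.stats.n_charged == 522
        assert type_i.stats.charged_fraction == pytest.approx(0.161, abs=5e-4)

    def test_type_i_sidechain_element_frequencies(self, type_i):
        assert type_i.atoms.frequencies["C"] == pytest.approx(0.2922, abs=2e-4)
        assert type_i.atoms.frequencies["O"] == pytest.approx(0.0395, abs=2e-4)

    def test_type_i_chx_groups(self, type_i):
        assert type_i.stats.n_chx_groups == 3073

    def test_type_ii_residue_and_triplet_counts(self, type_ii):
        assert type_ii.residue_counts.n_residues == 3648
        assert type_ii.residue_counts.n_triplets == 1216

    def test_type_ii_charged_fraction(self, type_ii):
        assert type_ii.stats.n_charged == 551
        assert type_ii.stats.charged_fraction == pytest.approx(0.151, abs=5e-4)

    def test_type_ii_hydrophobic_tallies(self, type_ii):
        assert type_ii.stats.n_hydrophobic_residues == 1683
        assert type_ii.stats.n_chx_groups == 4152


class TestClassStats:
    def test_neutral_chain_has_no_charge(self):
        stats = charge_stats(ResidueCounts({"G": 6, "P": 3, "A": 3}))
        assert stats.n_charged == 0 and stats.charged_fraction == 0.0

    def test_single_alanine_one_group(self):
        stats = chx_stats(ResidueCounts({"A": 1}))
        assert stats.n_hydrophobic_residues == 1 and stats.n_chx_groups == 1

    def test_all_gly_has_no_groups(self):
        stats = chx_stats(ResidueCounts({"G": 9}))
        assert stats.n_hydrophobic_residues == 0 and stats.n_chx_groups == 0

    def test_every_counted_residue_carries_a_group(self, type_i, type_ii):
        for prof in (type_i, type_ii):
            assert prof.stats.n_chx_groups >= prof.stats.n_hydrophobic_residues

    def test_spec_group_counts(self):
        assert [comp.CHX_GROUPS[r] for r in "ALKRP"] == [1, 3, 4, 3, 3]
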