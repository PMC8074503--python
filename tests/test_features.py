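"""Feature-encoder tests, cross-checked against independent oracles where
available (Biopython's ProtParam for GRAVY / instability / molecular weight,
a fine-grid charge scan for the isoelectric point)."""

import numpy as np
import pytest
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from hypothesis import given
from hypothesis import strategies as st

from circpred.descriptors import DEFAULT_TABLES
from circpred.features import (
    FEATURE_NAMES,
    N_FEATURES,
    aac,
    encode,
    gravy,
    instability_index,
    isoelectric_point,
    molecular_weight,
    net_charge,
    scale_mean,
    transitional,
)
from circpred.sequence_io import CANONICAL_RESIDUES, ProteinRecord

sequences = st.text(alphabet=CANONICAL_RESIDUES, min_size=2, max_size=120)


def rec(seq: str) -> ProteinRecord:
    return ProteinRecord(id="t", sequence=seq)


class TestAAC:
    def test_homopolymer(self):
        v = aac(rec("AAAA"))
        assert v[0] == 1.0 and v[1:].sum() == 0.0

    def test_uniform_sequence(self):
        v = aac(rec(CANONICAL_RESIDUES))
        assert np.allclose(v, 0.05)

    def test_hand_counted(self):
        v = aac(rec("AAC"))
        expected = np.zeros(20)
        expected[0], expected[1] = 2 / 3, 1 / 3
        assert np.allclose(v, expected)

    @given(seq=sequences)
    def test_simplex(self, seq):
        assert abs(aac(rec(seq)).sum() - 1.0) < 1e-9


class TestScaleMean:
    def test_homopolymer_equals_table_row(self):
        v = scale_mean(rec("GGGG"), DEFAULT_TABLES.protfp)
        assert np.allclose(v, DEFAULT_TABLES.protfp["G"])

    def test_two_residue_average(self):
        v = scale_mean(rec("AG"), DEFAULT_TABLES.fasgai)
        expected = (
            np.array(DEFAULT_TABLES.fasgai["A"]) + np.array(DEFAULT_TABLES.fasgai["G"])
        ) / 2
        assert np.allclose(v, expected)

    @given(seq=sequences)
    def test_permutation_invariant(self, seq):
        shuffled = "".join(sorted(seq))
        assert np.allclose(
            scale_mean(rec(seq), DEFAULT_TABLES.cruciani),
            scale_mean(rec(shuffled), DEFAULT_TABLES.cruciani),
        )


class TestTransitional:
    def test_has_21_entries(self):
        assert transitional(rec("ACDEF")).shape == (21,)

    def test_homopolymer_single_self_pair_per_block(self):
        v = transitional(rec("AAAAAA"))
        for block in (v[:9], v[9:18], v[18:]):
            assert np.isclose(block.max(), 1.0)
            assert np.isclose(block.sum(), 1.0)
            assert (block > 0).sum() == 1

    def test_two_residue_cross_class_pair(self):
        # R is polar, L is hydrophobic: one ordered polar->hydrophobic transition
        v = transitional(rec("RL"))
        names = [n for n in FEATURE_NAMES if n.startswith("trans_hyd")]
        block = dict(zip(names, v[:9]))
        assert block["trans_hyd_polar_hydrophobic"] == 1.0
        assert sum(val for key, val in block.items() if key != "trans_hyd_polar_hydrophobic") == 0.0

    def test_order_sensitivity(self):
        assert not np.allclose(transitional(rec("RLRLRL")), transitional(rec("RRRLLL")))

    def test_length_one_rejected(self):
        with pytest.raises(ValueError):
            transitional(rec("A"))

    @given(seq=sequences)
    def test_each_block_is_a_simplex(self, seq):
        v = transitional(rec(seq))
        assert v.shape == (21,)
        assert np.all((v >= 0) & (v <= 1))
        for block in (v[:9], v[9:18], v[18:]):
            assert abs(block.sum() - 1.0) < 1e-9


class TestPhysicoChemical:
    def test_gravy_homopolymer(self):
        assert gravy(rec("AAAA")) == DEFAULT_TABLES.hydrophobicity_scale["A"]

    def test_gravy_matches_biopython(self):
        seq = "MKVLAWTYRHDESGNQCIFP"
        assert gravy(rec(seq)) == pytest.approx(ProteinAnalysis(seq).gravy(), abs=1e-9)

    def test_instability_dipeptide(self):
        expected = 10 / 2 * DEFAULT_TABLES.diwv["G"]["G"]
        assert instability_index(rec("GG")) == pytest.approx(expected)

    def test_instability_matches_biopython(self):
        seq = "MKVLAWTYRHDESGNQCIFPMKVLAW"
        assert instability_index(rec(seq)) == pytest.approx(
            ProteinAnalysis(seq).instability_index(), abs=1e-6
        )

    def test_instability_single_residue_rejected(self):
        with pytest.raises(ValueError):
            instability_index(rec("A"))

    def test_molecular_weight_matches_biopython(self):
        from Bio.SeqUtils import molecular_weight as bio_mw

        seq = "MKVLAWTYRHDESGNQCIFP"
        assert molecular_weight(rec(seq)) == pytest.approx(
            bio_mw(seq, seq_type="protein"), abs=0.05
        )

    @given(s1=sequences, s2=sequences)
    def test_molecular_weight_additivity(self, s1, s2):
        combined = molecular_weight(rec(s1 + s2))
        parts = molecular_weight(rec(s1)) + molecular_weight(rec(s2))
        assert combined == pytest.approx(parts - DEFAULT_TABLES.water_mass, abs=1e-6)

    @pytest.mark.parametrize("seq", ["G", "KKKKKK", "DDDDDD", "MKVLAWTYRHDESGNQCIFP"])
    def test_isoelectric_point_matches_grid_scan(self, seq):
        # independent oracle: fine scan of the same charge function
        grid = np.arange(0.0, 14.0, 1e-4)
        charges = np.array([net_charge(seq, ph) for ph in grid])
        crossing = grid[np.argmax(charges < 0)]
        assert isoelectric_point(rec(seq)) == pytest.approx(crossing, abs=1e-3)

    def test_isoelectric_point_ordering(self):
        # a lysine-rich peptide is more basic than an aspartate-rich one
        assert isoelectric_point(rec("KKKKKK")) > isoelectric_point(rec("DDDDDD"))


class TestEncode:
    def test_layout_is_62_with_documented_blocks(self):
        fv = encode(rec("MKVLAWTYRHDESGNQCIFP"))
        assert len(fv.values) == N_FEATURES == 62
        assert len(FEATURE_NAMES) == 62
        blocks = {
            "aac_": 20,
            "protfp_": 8,
            "fasgai_": 6,
            "cruciani_": 3,
            "trans_": 21,
        }
        for prefix, count in blocks.items():
            assert sum(n.startswith(prefix) for n in FEATURE_NAMES) == count
        assert FEATURE_NAMES[-4:] == (
            "gravy",
            "instability_index",
            "molecular_weight",
            "isoelectric_point",
        )

    def test_deterministic(self):
        r = rec("MKVLAWTYRHDESGNQCIFP")
        assert np.array_equal(encode(r).values, encode(r).values)

    def test_composition_blocks_permutation_invariant_transitions_not(self):
        seq = "MKVLAWTYRHDESGNQCIFP" * 2
        shuffled = seq[::2] + seq[1::2]
        a, b = encode(rec(seq)).values, encode(rec(shuffled)).values
        assert np.allclose(a[:37], b[:37])  # composition + scale means
        assert not np.allclose(a[37:58], b[37:58])  # transitions differ

    @given(seq=sequences)
    def test_total_and_finite(self, seq):
        v = encode(rec(seq)).values
        assert v.shape == (62,)
        assert np.all(np.isfinite(v))

    def test_length_one_rejected(self):
        with pytest.raises(ValueError):
            encode(rec("A"))
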