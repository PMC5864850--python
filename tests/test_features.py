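import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import (
    ALPHABET,
    oracle_aac,
    oracle_atc,
    oracle_ctd,
    oracle_dpc,
    oracle_pcp,
    random_protein,
)
from pvpsvm.features import (
    BLOCKS,
    N_FEATURES,
    compute_aac,
    compute_atc,
    compute_ctd,
    compute_dpc,
    compute_pcp,
    encode,
    encode_set,
    feature_names,
)
from pvpsvm.properties import CTD_PROPERTIES, PCP_CLASSES
from pvpsvm.seq_io import LabeledSequenceSet, ProteinSequence

protein_strategy = st.text(alphabet=ALPHABET, min_size=2, max_size=80)


def _seq(residues):
    return ProteinSequence(id="t", residues=residues)


class TestLayout:
    def test_block_sizes_and_total(self):
        sizes = {k: s.stop - s.start for k, s in BLOCKS.items()}
        assert sizes == {"AAC": 20, "ATC": 5, "CTD": 147, "DPC": 400, "PCP": 11}
        assert N_FEATURES == 583

    def test_names_unique_and_ordered_by_block(self):
        names = feature_names()
        assert len(names) == 583 and len(set(names)) == 583
        for block, sl in BLOCKS.items():
            assert all(n.startswith(block) for n in names[sl])


class TestAAC:
    def test_homopolymer(self):
        v = compute_aac(_seq("AAAA"))
        assert v[0] == 1.0 and v[1:].sum() == 0.0

    def test_uniform(self):
        v = compute_aac(_seq(ALPHABET))
        np.testing.assert_allclose(v, 0.05)

    def test_matches_counting_oracle(self, rng):
        s = random_protein(rng, 200)
        np.testing.assert_allclose(compute_aac(_seq(s)), oracle_aac(s), atol=1e-12)


class TestDPC:
    def test_homopolymer(self):
        v = compute_dpc(_seq("AAA"))
        assert v[0] == 1.0 and v[1:].sum() == 0.0

    def test_two_windows(self):
        v = compute_dpc(_seq("ACA"))
        names = feature_names()
        d = dict(zip(names[BLOCKS["DPC"]], v))
        assert d["DPC_AC"] == 0.5 and d["DPC_CA"] == 0.5
        assert sum(x for x in v) == 1.0

    def test_length_one_is_error(self):
        with pytest.raises(ValueError):
            compute_dpc(_seq("A"))

    def test_matches_sliding_window_oracle(self, rng):
        s = random_protein(rng, 200)
        np.testing.assert_allclose(compute_dpc(_seq(s)), oracle_dpc(s), atol=1e-12)


class TestATC:
    def test_sums_to_one(self, rng):
        v = compute_atc(_seq(random_protein(rng, 50)))
        assert abs(v.sum() - 1.0) < 1e-12

    def test_no_sulfur_without_cys_met(self):
        v = compute_atc(_seq("AGPLKR"))
        assert v[4] == 0.0

    def test_glycine_pinned_values(self):
        # G residue C2H3NO plus terminal water: C2 H5 N1 O2 = 10 atoms
        v = compute_atc(_seq("G"))
        np.testing.assert_allclose(v, [2 / 10, 5 / 10, 1 / 10, 2 / 10, 0.0], atol=1e-12)

    def test_diglycine_pinned_values(self):
        # GG: C4 H8 N2 O3 = 17 atoms (one terminal water for the whole chain)
        v = compute_atc(_seq("GG"))
        np.testing.assert_allclose(v, [4 / 17, 8 / 17, 2 / 17, 3 / 17, 0.0], atol=1e-12)

    def test_matches_formula_summation_oracle(self, rng):
        s = random_protein(rng, 200)
        np.testing.assert_allclose(compute_atc(_seq(s)), oracle_atc(s), atol=1e-12)


class TestCTD:
    def test_composition_triples_sum_to_one(self, rng):
        v = compute_ctd(_seq(random_protein(rng, 120)))
        for p in range(7):
            assert abs(v[21 * p : 21 * p + 3].sum() - 1.0) < 1e-12

    def test_homopolymer_8mer(self, tables):
        v = compute_ctd(_seq("AAAAAAAA"))
        for p, prop in enumerate(CTD_PROPERTIES):
            groups = tables.ctd_groups[prop]
            g = next(i for i in range(3) if "A" in groups[i])
            block = v[21 * p : 21 * (p + 1)]
            comp, trans, dist = block[:3], block[3:6], block[6:]
            assert comp[g] == 1.0 and comp.sum() == 1.0
            assert trans.sum() == 0.0
            np.testing.assert_allclose(
                dist[5 * g : 5 * g + 5], [1 / 8, 2 / 8, 4 / 8, 6 / 8, 8 / 8]
            )
            for other in range(3):
                if other != g:
                    assert dist[5 * other : 5 * other + 5].sum() == 0.0

    def test_matches_bruteforce_oracle(self, rng, tables):
        s = random_protein(rng, 200)
        expected = oracle_ctd(s, tables.ctd_groups, CTD_PROPERTIES)
        np.testing.assert_allclose(compute_ctd(_seq(s)), expected, atol=1e-12)


class TestPCP:
    def test_polylysine_charge_classes(self):
        names = feature_names()
        d = dict(zip(names[BLOCKS["PCP"]], compute_pcp(_seq("KKKK"))))
        assert d["PCP_positively_charged"] == 1.0
        assert d["PCP_negatively_charged"] == 0.0

    def test_polyglycine_mass_lower_bound(self):
        # glycine is the lightest residue: rescaled mean mass hits 0
        assert compute_pcp(_seq("GGGG"))[-1] == 0.0

    def test_matches_membership_oracle(self, rng, tables):
        s = random_protein(rng, 200)
        expected = oracle_pcp(s, tables.pcp_classes, PCP_CLASSES, tables.residue_masses)
        np.testing.assert_allclose(compute_pcp(_seq(s)), expected, atol=1e-12)


class TestEncode:
    def test_length_583_and_unit_interval(self, rng):
        v = encode(_seq(random_protein(rng, 75)))
        assert v.shape == (583,)
        assert v.min() >= 0.0 and v.max() <= 1.0

    def test_deterministic(self, rng):
        s = _seq(random_protein(rng, 40))
        np.testing.assert_array_equal(encode(s), encode(s))

    def test_blocks_equal_standalone_encoders(self, rng, tables):
        s = _seq(random_protein(rng, 60))
        v = encode(s)
        np.testing.assert_array_equal(v[BLOCKS["AAC"]], compute_aac(s))
        np.testing.assert_array_equal(v[BLOCKS["ATC"]], compute_atc(s, tables))
        np.testing.assert_array_equal(v[BLOCKS["CTD"]], compute_ctd(s, tables))
        np.testing.assert_array_equal(v[BLOCKS["DPC"]], compute_dpc(s))
        np.testing.assert_array_equal(v[BLOCKS["PCP"]], compute_pcp(s, tables))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(residues=protein_strategy, perm_seed=st.integers(0, 2**31 - 1))
    def test_permutation_invariance_of_composition_blocks(self, residues, perm_seed):
        """AAC, ATC and the PCP class fractions ignore residue order."""
        rng = np.random.default_rng(perm_seed)
        shuffled = "".join(rng.permutation(list(residues)))
        a, b = encode(_seq(residues)), encode(_seq(shuffled))
        np.testing.assert_allclose(a[BLOCKS["AAC"]], b[BLOCKS["AAC"]], atol=1e-12)
        np.testing.assert_allclose(a[BLOCKS["ATC"]], b[BLOCKS["ATC"]], atol=1e-12)
        np.testing.assert_allclose(a[BLOCKS["PCP"]], b[BLOCKS["PCP"]], atol=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(residues=protein_strategy)
    def test_normalization_invariants(self, residues):
        v = encode(_seq(residues))
        assert abs(v[BLOCKS["AAC"]].sum() - 1.0) < 1e-9
        assert abs(v[BLOCKS["ATC"]].sum() - 1.0) < 1e-9
        assert abs(v[BLOCKS["DPC"]].sum() - 1.0) < 1e-9
        assert v.min() >= -1e-15 and v.max() <= 1 + 1e-15


class TestEncodeSet:
    def test_shape_order_and_labels(self, small_dataset):
        X, y = encode_set(small_dataset)
        assert X.shape == (len(small_dataset), 583)
        assert list(y) == [1] * len(small_dataset.positives) + [0] * len(
            small_dataset.negatives
        )

    def test_rows_equal_per_sequence_encode(self, small_dataset):
        X, _ = encode_set(small_dataset)
        for i, s in enumerate(small_dataset.sequences[:5]):
            np.testing.assert_array_equal(X[i], encode(s))

    def test_empty_negatives_gives_all_ones_labels(self):
        ds = LabeledSequenceSet(
            positives=(ProteinSequence("p1", "MKVL"), ProteinSequence("p2", "ACDE")),
            negatives=(),
        )
        _, y = encode_set(ds)
        assert list(y) == [1, 1]

    def test_error_names_offending_sequence(self):
        ds = LabeledSequenceSet(
            positives=(ProteinSequence("tooshort", "M"),), negatives=()
        )
        with pytest.raises(ValueError, match="tooshort"):
            encode_set(ds)
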