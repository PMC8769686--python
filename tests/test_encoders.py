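"""Encoder contracts: dimensions, worked examples, brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from kacestack.encoders import (EncodingConfig, EncodingError, HYBRID_ORDER,
                                KNNReference, encode_aac, encode_aai,
                                encode_bina, encode_blosum62, encode_cksaagp,
                                encode_ctf, encode_dpc, encode_gdpc,
                                encode_gtpc, encode_hybrid, encode_knn,
                                encode_nrf, encode_zscale, knn_distances)
from kacestack.fragments import FragmentDataset, PeptideFragment
from kacestack.resources import ALPHABET, STANDARD_RESIDUES

K21 = "K" * 21
A_FLANKS = "A" * 10 + "K" + "A" * 10
W_FLANKS = "W" * 10 + "K" + "W" * 10

fragment_strategy = st.builds(
    lambda left, right: left + "K" + right,
    st.text(st.sampled_from(ALPHABET), min_size=10, max_size=10),
    st.text(st.sampled_from(ALPHABET), min_size=10, max_size=10),
)

ENCODER_DIMS = [
    (encode_aai, 525), (encode_aac, 21), (encode_dpc, 441),
    (encode_cksaagp, 150), (encode_ctf, 343), (encode_zscale, 105),
    (encode_bina, 441), (encode_blosum62, 420), (encode_gtpc, 125),
    (encode_gdpc, 25), (encode_nrf, 20),
]


@pytest.mark.parametrize("encoder,dim", ENCODER_DIMS,
                         ids=[e.__name__ for e, _ in ENCODER_DIMS])
def test_block_dimension(encoder, dim, small_dataset):
    block = encoder(small_dataset)
    assert block.n_features == dim
    assert block.matrix.shape == (len(small_dataset), dim)
    assert len(block.feature_names) == dim


def test_unknown_symbol_rejected():
    with pytest.raises(EncodingError, match="alphabet"):
        encode_aac(["A" * 10 + "K" + "A" * 9 + "*"])


class TestNRF:
    def test_all_alanine_flanks_map_to_zero(self):
        block = encode_nrf([A_FLANKS])
        assert np.all(block.matrix == 0.0)
        assert block.n_features == 20  # center excluded

    def test_rank_values_enumerate_two_point_zero_grid(self):
        # one fragment per symbol in the flank position right before K
        frags = ["A" * 9 + c + "K" + "A" * 10 for c in ALPHABET]
        col = encode_nrf(frags).matrix[:, 9]
        assert sorted(np.round(col, 10)) == pytest.approx(
            [0.1 * i for i in range(21)]
        )


class TestBINA:
    def test_one_hot_positions(self):
        block = encode_bina(["A" * 10 + "K" + "O" * 10])
        row = block.matrix[0]
        assert row[0] == 1.0                       # 'A' at first alphabet slot
        assert row[20 * 21 + 20] == 1.0            # 'O' at the last slot
        assert row.sum() == 21.0

    @given(fragment_strategy)
    def test_row_sums_equal_window(self, frag):
        assert encode_bina([frag]).matrix.sum() == 21.0


class TestCompositionExamples:
    def test_aac_homopolymer(self):
        block = encode_aac([K21])
        k_col = ALPHABET.index("K")
        assert block.matrix[0, k_col] == 1.0
        assert block.matrix[0].sum() == pytest.approx(1.0)

    def test_aac_hand_count(self):
        frag = "A" * 10 + "K" + "G" * 10
        block = encode_aac([frag])
        assert block.matrix[0, ALPHABET.index("A")] == pytest.approx(10 / 21)

    def test_dpc_homopolymer(self):
        block = encode_dpc([K21])
        kk = ALPHABET.index("K") * 21 + ALPHABET.index("K")
        assert block.matrix[0, kk] == 1.0

    def test_dpc_alternating_pattern(self):
        frag = "AK" * 10 + "K"  # dipeptides: 10x AK, 9x KA, 1x KK
        block = encode_dpc([frag])
        ak = ALPHABET.index("A") * 21 + ALPHABET.index("K")
        assert block.matrix[0, ak] == pytest.approx(10 / 20)

    def test_ctf_homopolymer_k_is_class5_triad(self):
        block = encode_ctf([K21])
        names = dict(zip(block.feature_names, block.matrix[0]))
        assert names["CTF:c5c5c5"] == 1.0

    def test_ctf_dummy_in_first_class(self):
        frag = "O" * 10 + "K" + "O" * 10
        block = encode_ctf([frag])
        names = dict(zip(block.feature_names, block.matrix[0]))
        assert names["CTF:c1c1c1"] == pytest.approx(16 / 19)

    def test_gdpc_positive_group_homopolymer(self):
        block = encode_gdpc([K21])  # K is positively charged
        names = dict(zip(block.feature_names, block.matrix[0]))
        assert names["GDPC:pos.pos"] == 1.0

    def test_gtpc_homopolymer_single_column(self):
        row = encode_gtpc([K21]).matrix[0]
        assert row.max() == 1.0 and row.sum() == pytest.approx(1.0)

    def test_cksaagp_homopolymer_every_gap(self):
        block = encode_cksaagp([K21])
        for k in range(6):
            names = dict(zip(block.feature_names, block.matrix[0]))
            assert names[f"CKSAAGP:k{k}:pos.pos"] == 1.0

    @given(fragment_strategy)
    def test_composition_blocks_are_distributions(self, frag):
        for enc in (encode_aac, encode_dpc, encode_ctf, encode_gdpc,
                    encode_gtpc):
            row = enc([frag]).matrix[0]
            assert row.min() >= 0
            assert row.sum() == pytest.approx(1.0)
        ck = encode_cksaagp([frag]).matrix[0]
        for k in range(6):
            assert ck[k * 25:(k + 1) * 25].sum() == pytest.approx(1.0)


class TestTableEncoders:
    def test_aai_constant_fragment_returns_k_values(self):
        cfg = EncodingConfig()
        block = encode_aai([K21], cfg)
        expected = cfg.aai_table["K"].to_numpy()
        assert block.matrix[0] == pytest.approx(expected)

    def test_aai_ignores_dummy_positions(self):
        cfg = EncodingConfig()
        padded = encode_aai(["O" * 10 + "K" + "O" * 10], cfg).matrix[0]
        assert padded == pytest.approx(cfg.aai_table["K"].to_numpy())

    def test_zscale_dummy_contributes_zeros(self):
        row = encode_zscale(["O" * 10 + "K" + "O" * 10]).matrix[0]
        assert np.all(row[:50] == 0.0) and np.all(row[55:] == 0.0)

    def test_zscale_constant_fragment_repeats_vector(self):
        cfg = EncodingConfig()
        row = encode_zscale([W_FLANKS], cfg).matrix[0]
        w = cfg.zscale_table.loc["W"].to_numpy()
        assert row[:5] == pytest.approx(w)
        assert row[-5:] == pytest.approx(w)

    def test_blosum_w_diagonal_is_matrix_max(self):
        block = encode_blosum62([W_FLANKS])
        names = dict(zip(block.feature_names, block.matrix[0]))
        assert names["BLOS:p-10:W"] == 11.0

    def test_blosum_dummy_row_is_zero(self):
        row = encode_blosum62(["O" * 10 + "K" + "O" * 10]).matrix[0]
        assert np.all(row[:200] == 0.0)


class TestHybrid:
    def test_dimension_and_block_partition(self, small_hybrid):
        assert small_hybrid.n_features == 2616
        sizes = [small_hybrid.block_slices[t].stop
                 - small_hybrid.block_slices[t].start for t in HYBRID_ORDER]
        assert sizes == [525, 21, 441, 150, 343, 105, 441, 420, 125, 25, 20]
        prefixes = [n.split(":")[0] for n in small_hybrid.feature_names]
        for tag in HYBRID_ORDER:
            sl = small_hybrid.block_slices[tag]
            assert all(p == ("BLOS" if tag == "BLOS" else tag)
                       for p in prefixes[sl])

    def test_single_fragment_single_row(self):
        assert encode_hybrid([A_FLANKS]).matrix.shape == (1, 2616)

    def test_permutation_equivariance(self, small_dataset):
        fwd = encode_hybrid(small_dataset).matrix
        rev = encode_hybrid(list(reversed(small_dataset.sequences))).matrix
        assert np.array_equal(fwd[::-1], rev)

    def test_tag_subset_keeps_hybrid_order(self, small_dataset):
        block = encode_hybrid(small_dataset, tags=("NRF", "Zscale"))
        assert list(block.block_slices) == ["Zscale", "NRF"]
        assert block.n_features == 125


class TestToyAlphabetOracle:
    """Composition encoders vs brute-force window enumeration, length 5."""

    cfg = EncodingConfig(
        window=5, alphabet="ABK",
        ctf_classes=("AB", "K"), group5={"g1": "A", "g2": "BK"},
        cksaagp_k_max=2,
    )

    frags = ["ABKBA", "KKKKK", "ABKAB", "BBKAA", "AAKAA"]

    @staticmethod
    def brute_kmers(seq, alphabet, k):
        counts = {"".join(p): 0 for p in itertools.product(alphabet, repeat=k)}
        for i in range(len(seq) - k + 1):
            counts[seq[i:i + k]] += 1
        total = len(seq) - k + 1
        return np.array([counts[c] / total for c in sorted(counts)])

    def brute_grouped(self, seq, partition, k):
        gseq = "".join(
            str(next(i for i, g in enumerate(partition) if c in g))
            for c in seq
        )
        return self.brute_kmers(gseq, "01"[:len(partition)], k)

    def test_aac_matches_bruteforce(self):
        got = encode_aac(self.frags, self.cfg).matrix
        want = np.array([self.brute_kmers(f, "AB K".replace(" ", ""), 1)
                         for f in self.frags])
        # canonical order "ABK" is already sorted
        assert got == pytest.approx(want)

    def test_dpc_matches_bruteforce(self):
        got = encode_dpc(self.frags, self.cfg).matrix
        want = np.array([self.brute_kmers(f, "ABK", 2) for f in self.frags])
        assert got == pytest.approx(want)

    def test_ctf_matches_bruteforce(self):
        got = encode_ctf(self.frags, self.cfg).matrix
        want = np.array(
            [self.brute_grouped(f, self.cfg.ctf_classes, 3)
             for f in self.frags]
        )
        assert got == pytest.approx(want)

    def test_gdpc_gtpc_match_bruteforce(self):
        groups = tuple(self.cfg.group5.values())
        got2 = encode_gdpc(self.frags, self.cfg).matrix
        got3 = encode_gtpc(self.frags, self.cfg).matrix
        want2 = np.array([self.brute_grouped(f, groups, 2) for f in self.frags])
        want3 = np.array([self.brute_grouped(f, groups, 3) for f in self.frags])
        assert got2 == pytest.approx(want2)
        assert got3 == pytest.approx(want3)

    def test_cksaagp_matches_bruteforce(self):
        groups = tuple(self.cfg.group5.values())
        got = encode_cksaagp(self.frags, self.cfg).matrix
        for fi, seq in enumerate(self.frags):
            gseq = [0 if c in groups[0] else 1 for c in seq]
            for k in range(3):
                pairs = [(gseq[i], gseq[i + k + 1])
                         for i in range(len(seq) - k - 1)]
                want = np.zeros(4)
                for a, b in pairs:
                    want[a * 2 + b] += 1 / len(pairs)
                assert got[fi, k * 4:(k + 1) * 4] == pytest.approx(want)


@pytest.fixture(scope="module")
def pool():
    from kacestack.simulate import SyntheticDatasetSpec, generate_dataset

    return generate_dataset(SyntheticDatasetSpec(70, 70, seed=5))


class TestKNN:
    def test_default_x_set_gives_seven_columns(self, pool):
        block = encode_knn(pool, KNNReference(pool))
        assert block.n_features == 7
        assert block.feature_names[0] == "KNN:X2"
        assert block.matrix.min() >= 0 and block.matrix.max() <= 1

    def test_self_distance_of_tryptophan_flanks(self, pool):
        # Sim(W,W) = (11+4)/15 = 1 at the 20 W positions; Sim(K,K) = 9/15
        ds = FragmentDataset([PeptideFragment(W_FLANKS)], np.array([0]))
        D = knn_distances([W_FLANKS], KNNReference(ds, (1,)))
        expected = 1 - (20 * 1.0 + 9 / 15) / 21
        assert D[0, 0] == pytest.approx(expected)

    def test_relabeling_own_match_lowers_positive_fraction(self):
        frags = [PeptideFragment(W_FLANKS), PeptideFragment(A_FLANKS),
                 PeptideFragment("G" * 10 + "K" + "G" * 10)]
        pos = FragmentDataset(frags, np.array([1, 0, 1]))
        neg = FragmentDataset(frags, np.array([0, 0, 1]))
        f_pos = encode_knn([W_FLANKS], KNNReference(pos, (2,))).matrix[0, 0]
        f_neg = encode_knn([W_FLANKS], KNNReference(neg, (2,))).matrix[0, 0]
        assert f_pos >= f_neg

    def test_ties_broken_by_pool_order(self):
        twin = [PeptideFragment(A_FLANKS), PeptideFragment(A_FLANKS)]
        ref = FragmentDataset(twin, np.array([1, 0]))
        block = encode_knn([A_FLANKS], KNNReference(ref, (1,)))
        assert block.matrix[0, 0] == 1.0  # first pool entry wins the tie

    def test_leave_one_out_excludes_self(self):
        frags = [PeptideFragment(W_FLANKS), PeptideFragment(A_FLANKS)]
        ds = FragmentDataset(frags, np.array([1, 0]))
        naive = encode_knn(ds, KNNReference(ds, (1,)))
        loo = encode_knn(ds, KNNReference(ds, (1,)), leave_one_out=True)
        assert np.array_equal(naive.matrix[:, 0], [1.0, 0.0])  # self nearest
        assert np.array_equal(loo.matrix[:, 0], [0.0, 1.0])    # other one

    def test_x_exceeding_pool_rejected(self, pool):
        with pytest.raises(EncodingError, match="exceeds pool"):
            KNNReference(pool, (2, 4, 1000))

    def test_empty_pool_rejected(self):
        with pytest.raises(EncodingError, match="empty"):
            KNNReference(FragmentDataset([], np.zeros(0, int)))
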