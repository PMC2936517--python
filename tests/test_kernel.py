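"""Di-mismatch kernel: scores, feature spaces, feature maps, Gram matrices,
and the fast-scan contribution table."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dimismatch import (
    DiMismatchParams,
    FeatureSpace,
    KmerContributionTable,
    build_feature_space,
    di_mismatch_score,
    feature_map,
    feature_matrix,
    kernel_matrix,
    matching_dinucleotides,
    reverse_complement,
)
from conftest import random_seq

SUB = {"A": "C", "C": "G", "G": "T", "T": "A"}


def mutate(s, positions_1based):
    out = list(s)
    for p in positions_1based:
        out[p - 1] = SUB[out[p - 1]]
    return "".join(out)


P13 = DiMismatchParams(13, 5, "single")
A13 = "ACGTACGTACGTA"


class TestDiMismatchScore:
    def test_identical_13mers_score_12(self):
        assert di_mismatch_score(A13, A13, P13) == 12

    def test_four_consecutive_interior_mismatches(self):
        """Four consecutive substitutions disrupt only five of the twelve
        overlapping dinucleotides, so the score stays above threshold."""
        b = mutate(A13, [5, 6, 7, 8])
        assert 12 - matching_dinucleotides(A13, b) == 5
        assert di_mismatch_score(A13, b, P13) == 7

    def test_four_scattered_mismatches_fall_below_threshold(self):
        """Substitutions at positions 1, 5, 9, 13 disrupt six dinucleotides;
        6 matching < threshold 7, so the thresholded score is zero."""
        b = mutate(A13, [1, 5, 9, 13])
        assert 12 - matching_dinucleotides(A13, b) == 6
        assert di_mismatch_score(A13, b, P13) == 0

    def test_small_example_with_threshold(self):
        p = DiMismatchParams(4, 1, "single")
        assert di_mismatch_score("ACGT", "ACGA", p) == 2

    def test_both_strand_mode_takes_reverse_complement_max(self):
        p = DiMismatchParams(4, 1, "both")
        # revcomp(ACGT) == ACGT: self-complementary
        assert di_mismatch_score("ACGT", "ACGT", p) == 3
        ps = DiMismatchParams(6, 5, "both")
        # AAAAAA vs TTTTTT share nothing forward but match via the reverse
        # complement; single-strand scoring sees zero matching dinucleotides
        assert di_mismatch_score("AAAAAA", "TTTTTT", ps) == 5
        assert di_mismatch_score("AAAAAA", "TTTTTT", DiMismatchParams(6, 5, "single")) == 0

    @pytest.mark.parametrize(
        "a,b",
        [("ACGT", "ACG"), ("ACNT", "ACGT"), ("ACGT", "ACXT")],
    )
    def test_invalid_inputs_raise(self, a, b):
        with pytest.raises(ValueError):
            di_mismatch_score(a, b, DiMismatchParams(4, 1, "single"))

    def test_params_validation(self):
        with pytest.raises(ValueError):
            DiMismatchParams(1, 0)
        with pytest.raises(ValueError):
            DiMismatchParams(5, 5)
        with pytest.raises(ValueError):
            DiMismatchParams(13, 6).require_training_valid()
        DiMismatchParams(13, 5).require_training_valid()
        assert DiMismatchParams(13, 5).min_matching_dinucs == 7

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 2**32 - 1), st.integers(2, 13), st.sampled_from(["single", "both"]))
    def test_score_symmetry(self, seed, k, strand):
        rng = np.random.default_rng(seed)
        a, b = random_seq(rng, k), random_seq(rng, k)
        p = DiMismatchParams(k, rng.integers(0, k), strand)
        assert di_mismatch_score(a, b, p) == di_mismatch_score(b, a, p)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2**32 - 1))
    def test_extra_mismatch_never_raises_match_count(self, seed):
        rng = np.random.default_rng(seed)
        a = random_seq(rng, 13)
        b = a
        prev = matching_dinucleotides(a, b)
        for pos in rng.permutation(13)[:6]:
            b = mutate(b, [pos + 1])
            cur = matching_dinucleotides(a, b)
            assert cur <= prev
            prev = cur


class TestFeatureSpace:
    def test_all_distinct_windows(self, rng):
        while True:
            s = random_seq(rng, 36)
            wins = {s[i : i + 13] for i in range(24)}
            if len(wins) == 24:
                break
        assert len(build_feature_space([s], P13)) == 24

    def test_repeated_kmer_collapses(self):
        sp = build_feature_space(["AAAAA"], DiMismatchParams(4, 1, "single"))
        assert sp.features == ("AAAA",)

    def test_canonical_strand_collapse(self):
        p = DiMismatchParams(4, 1, "both")
        sp = build_feature_space(["ACGT", reverse_complement("ACGT")], p)
        assert len(sp) == 1

    def test_no_feature_is_revcomp_of_another(self, rng):
        p = DiMismatchParams(5, 1, "both")
        sp = build_feature_space([random_seq(rng, 50) for _ in range(5)], p)
        feats = set(sp.features)
        for f in feats:
            rc = reverse_complement(f)
            assert rc == f or rc not in feats

    def test_errors(self):
        with pytest.raises(ValueError):
            build_feature_space([], P13)
        with pytest.raises(ValueError):
            build_feature_space(["ACGT"], P13)  # shorter than k

    def test_plain_text_round_trip(self, tmp_path):
        sp = build_feature_space(["ACGTACGTAC"], DiMismatchParams(4, 1, "single"))
        path = tmp_path / "space.txt"
        sp.save(path, DiMismatchParams(4, 1, "single"))
        sp2 = FeatureSpace.load(path)
        assert sp2.features == sp.features and sp2.k == sp.k


def naive_feature_map(seq, space, params):
    """Independent oracle: explicit double loop over windows and features."""
    v = np.zeros(len(space))
    for j, f in enumerate(space.features):
        for i in range(len(seq) - params.k + 1):
            w = seq[i : i + params.k]
            if set(w) <= set("ACGT"):
                v[j] += di_mismatch_score(w, f, params)
    return v


class TestFeatureMap:
    def test_self_feature_entry(self):
        p = DiMismatchParams(6, 1, "single")
        f = "ACGTAC"
        sp = FeatureSpace((f,), 6)
        assert feature_map(f, sp, p)[0] == 5  # d(f, f) = k-1

    def test_matches_naive_oracle(self, rng):
        for _ in range(10):
            k = int(rng.integers(4, 8))
            p = DiMismatchParams(k, int(rng.integers(0, k)), rng.choice(["single", "both"]))
            seqs = [random_seq(rng, 30) for _ in range(4)]
            sp = build_feature_space(seqs[:2], p)
            X = feature_matrix(seqs, sp, p)
            for i, s in enumerate(seqs):
                np.testing.assert_allclose(X[i], naive_feature_map(s, sp, p), atol=1e-9)

    def test_far_sequence_maps_to_zero(self):
        p = DiMismatchParams(8, 0, "single")  # threshold 7: near-exact match needed
        sp = FeatureSpace(("AAAAAAAA",), 8)
        assert feature_map("CGCGCGCGCGCG", sp, p).sum() == 0

    def test_ambiguous_bases_contribute_zero(self):
        p = DiMismatchParams(4, 3, "single")  # threshold 0: everything counts
        sp = FeatureSpace(("ACGT",), 4)
        with_n = feature_map("ACGTNACGT", sp, p)
        plain = feature_map("ACGT", sp, p)
        # windows touching N contribute nothing: total is twice one clean match
        assert with_n[0] == 2 * plain[0]

    def test_sequence_shorter_than_k_raises(self):
        sp = FeatureSpace(("ACGT",), 4)
        with pytest.raises(ValueError):
            feature_map("ACG", sp, DiMismatchParams(4, 1, "single"))


class TestKernelMatrix:
    def test_gram_matrix_is_psd_and_symmetric(self, rng):
        p = DiMismatchParams(6, 2, "both")
        seqs = [random_seq(rng, 36) for _ in range(10)]
        sp = build_feature_space(seqs, p)
        K = kernel_matrix(seqs, seqs, sp, p)
        np.testing.assert_allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-8 * np.trace(K)

    def test_singleton_is_squared_norm(self, rng):
        p = DiMismatchParams(5, 1, "single")
        s = random_seq(rng, 20)
        sp = build_feature_space([s], p)
        K = kernel_matrix([s], [s], sp, p)
        v = feature_map(s, sp, p)
        np.testing.assert_allclose(K, [[v @ v]])

    def test_equals_explicit_dot_products(self, rng):
        p = DiMismatchParams(6, 1, "both")
        X = [random_seq(rng, 36) for _ in range(5)]
        Y = [random_seq(rng, 36) for _ in range(3)]
        sp = build_feature_space(X, p)
        K = kernel_matrix(X, Y, sp, p)
        FX = np.stack([naive_feature_map(s, sp, p) for s in X])
        FY = np.stack([naive_feature_map(s, sp, p) for s in Y])
        np.testing.assert_allclose(K, FX @ FY.T, atol=1e-9)


class TestContributionTable:
    def test_single_feature_contribution(self):
        p = DiMismatchParams(6, 1, "single")
        f = "ACGTAC"
        sp = FeatureSpace((f,), 6)
        table = KmerContributionTable(sp, np.array([1.0]), 0.0, p)
        assert table.contribution(f) == 5

    def test_zero_weights_give_bias(self, rng):
        p = DiMismatchParams(6, 1, "single")
        sp = build_feature_space([random_seq(rng, 30)], p)
        table = KmerContributionTable(sp, np.zeros(len(sp)), 1.5, p)
        assert table.score_sequence(random_seq(rng, 50)) == pytest.approx(1.5)

    def test_hash_path_equals_explicit_prediction(self, rng):
        p = DiMismatchParams(6, 2, "both")
        train = [random_seq(rng, 36) for _ in range(5)]
        sp = build_feature_space(train, p)
        w = rng.normal(size=len(sp))
        bias = 0.7
        table = KmerContributionTable(sp, w, bias, p)
        for _ in range(3):
            s = random_seq(rng, 200)
            explicit = feature_map(s, sp, p) @ w + bias
            assert table.score_sequence(s) == pytest.approx(explicit, abs=1e-9)
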