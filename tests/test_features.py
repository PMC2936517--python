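"""Feature embedding, clustering, representatives, PSSM expansion, and
subset retraining."""

import numpy as np
import pytest
from sklearn.metrics import rand_score

from dimismatch import (
    DiMismatchParams,
    Probe,
    TrainingConfig,
    TrainingSample,
    alignment_score_vectors,
    build_feature_space,
    cluster_model_features,
    expand_feature_to_pssm,
    retrain_on_feature_subset,
    reverse_complement,
    select_cluster_representative,
)
from dimismatch.features import _best_alignment, consensus_agreement
from dimismatch.baselines import make_motif_pssm
from conftest import random_seq


def mutated(rng, s, n_mut):
    out = list(s)
    for pos in rng.choice(len(s), n_mut, replace=False):
        out[pos] = rng.choice([b for b in "ACGT" if b != out[pos]])
    return "".join(out)


class TestAlignmentVectors:
    def test_exact_occurrence_scores_k(self, rng):
        kmer = "ACGTTGCAC"
        seq = random_seq(rng, 10) + kmer + random_seq(rng, 10)
        emb = alignment_score_vectors([kmer], [seq], strand_mode="single")
        assert emb.vectors[0, 0] == len(kmer)

    def test_hand_counted_toy(self):
        # kmer ACGT vs sequence AAGTCC: offsets give matches 2 (A.GT at 0:
        # A=A, C!=A, G=G, T=T -> 3), check by hand:
        # off 0: ACGT vs AAGT -> A=A, C!=A, G=G, T=T = 3
        # off 1: ACGT vs AGTC -> 1 ; off 2: ACGT vs GTCC -> 1
        emb = alignment_score_vectors(["ACGT"], ["AAGTCC"], strand_mode="single")
        assert emb.vectors[0, 0] == 3

    def test_both_strands_take_reverse_complement(self):
        kmer = "AAAA"
        seq = "TTTTGG"
        single = alignment_score_vectors([kmer], [seq], strand_mode="single").vectors[0, 0]
        both = alignment_score_vectors([kmer], [seq], strand_mode="both").vectors[0, 0]
        assert single < 4 and both == 4

    def test_identical_kmers_identical_vectors(self, rng):
        seqs = [random_seq(rng, 30) for _ in range(5)]
        emb = alignment_score_vectors(["ACGTACGTA", "ACGTACGTA"], seqs)
        np.testing.assert_array_equal(emb.vectors[0], emb.vectors[1])

    def test_column_permutation_equivariance(self, rng):
        kmers = [random_seq(rng, 7) for _ in range(4)]
        seqs = [random_seq(rng, 25) for _ in range(6)]
        emb = alignment_score_vectors(kmers, seqs)
        emb_rev = alignment_score_vectors(kmers, seqs[::-1])
        np.testing.assert_array_equal(emb.vectors[:, ::-1], emb_rev.vectors)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            alignment_score_vectors([], ["ACGTACGT"])
        with pytest.raises(ValueError):
            alignment_score_vectors(["ACGT"], [])


def two_group_embedding(rng, n_per_group=30, n_seqs=40):
    """k-mers that are noisy copies of two dissimilar consensi, embedded
    against sequences that each contain one of the motifs."""
    c1, c2 = "AAACGTACGTAAA", "GGGTTAATTGGGG"
    kmers = [mutated(rng, c1, 2) for _ in range(n_per_group)] + [
        mutated(rng, c2, 2) for _ in range(n_per_group)
    ]
    seqs = []
    for i in range(n_seqs):
        motif = c1 if i % 2 == 0 else c2
        seqs.append(random_seq(rng, 6) + motif + random_seq(rng, 6))
    weights = rng.uniform(0.1, 1.0, size=len(kmers))
    emb = alignment_score_vectors(kmers, seqs, weights=weights)
    truth = np.r_[np.zeros(n_per_group), np.ones(n_per_group)]
    return emb, truth


class TestClustering:
    def test_recovers_planted_groups(self, rng):
        emb, truth = two_group_embedding(rng)
        report = cluster_model_features(emb, seed=0)
        labels = np.array([report.assignment[u] for u in emb.kmers])
        assert rand_score(truth, labels) >= 0.95

    def test_seeded_determinism(self, rng):
        emb, _ = two_group_embedding(rng)
        r1 = cluster_model_features(emb, seed=3)
        r2 = cluster_model_features(emb, seed=3)
        assert r1.assignment == r2.assignment
        np.testing.assert_allclose(r1.table[["x", "y"]], r2.table[["x", "y"]])

    def test_small_clusters_fully_kept(self, rng):
        emb, _ = two_group_embedding(rng, n_per_group=10)
        report = cluster_model_features(emb, top_per_cluster=500, seed=0)
        assert len(report.table) == 20

    def test_top_per_cluster_cap(self, rng):
        emb, _ = two_group_embedding(rng, n_per_group=30)
        report = cluster_model_features(emb, top_per_cluster=5, seed=0)
        assert len(report.table) == 10

    def test_degenerate_vectors_rejected(self):
        emb = alignment_score_vectors(["AAAA", "AAAA", "AAAA", "AAAA"], ["AAAAAAAA"])
        with pytest.raises(ValueError, match="degenerate"):
            cluster_model_features(emb, seed=0)


class TestRepresentative:
    def test_equal_weights_pick_nearest_centroid(self, rng):
        emb, _ = two_group_embedding(rng)
        emb.weights = np.ones(len(emb.kmers))
        report = cluster_model_features(emb, seed=0)
        reps = select_cluster_representative(report, emb)
        index = {u: i for i, u in enumerate(emb.kmers)}
        for c, rep in reps.items():
            members = report.cluster_kmers(c)
            centroid = report.centroids[c]
            dists = {u: np.linalg.norm(emb.vectors[index[u]] - centroid) for u in members}
            assert dists[rep] == pytest.approx(min(dists.values()))

    def test_representative_in_top_weight_quartile_of_cluster(self, rng):
        emb, _ = two_group_embedding(rng)
        report = cluster_model_features(emb, seed=0)
        reps = select_cluster_representative(report, emb)
        for c, rep in reps.items():
            sub = report.table[report.table["cluster"] == c]
            cutoff = np.quantile(sub["weight"], 0.75)
            assert sub.set_index("kmer").loc[rep, "weight"] >= cutoff

    def test_stable_under_weight_rescaling(self, rng):
        emb, _ = two_group_embedding(rng)
        report = cluster_model_features(emb, seed=0)
        reps1 = select_cluster_representative(report, emb)
        emb.weights = emb.weights * 7.5
        report2 = cluster_model_features(emb, seed=0)
        reps2 = select_cluster_representative(report2, emb)
        assert reps1 == reps2


class TestExpansion:
    def test_exact_occurrences_give_consensus_pssm(self, rng):
        kmer = "ACGTTGCACGATT"
        seqs = [random_seq(rng, 8) + kmer + random_seq(rng, 8) for _ in range(60)]
        pssm = expand_feature_to_pssm(kmer, seqs, top_n=50, pseudocount=0.5)
        assert pssm.consensus == kmer
        # every column concentrated on the k-mer base
        for i, b in enumerate(kmer):
            assert pssm.matrix[i, "ACGT".index(b)] >= 50 / (50 + 4 * 0.5) - 1e-9

    def test_columns_sum_to_one(self, rng):
        seqs = [random_seq(rng, 30) for _ in range(55)]
        pssm = expand_feature_to_pssm("ACGTACGTACGTA", seqs, top_n=50)
        np.testing.assert_allclose(pssm.matrix.sum(axis=1), 1.0)

    def test_minus_strand_windows_oriented(self, rng):
        kmer = "AACCGGTTACGTA"
        rc = reverse_complement(kmer)
        seqs = [random_seq(rng, 5) + rc + random_seq(rng, 5) for _ in range(50)]
        pssm = expand_feature_to_pssm(kmer, seqs, top_n=50)
        assert pssm.consensus == kmer

    def test_too_few_sequences_rejected(self, rng):
        with pytest.raises(ValueError):
            expand_feature_to_pssm("ACGTACGTACGTA", [random_seq(rng, 20)], top_n=50)

    def test_consensus_agreement_helper(self):
        planted = make_motif_pssm("TGACGTCA")
        expanded = make_motif_pssm("GG" + "TGACGTCA" + "AAA")
        assert consensus_agreement(expanded, planted) == 1.0
        shuffled = make_motif_pssm("CCCCCCCCCCCCC")
        assert consensus_agreement(shuffled, planted) < 0.8


class TestRetraining:
    P9 = DiMismatchParams(9, 1, "single")

    def _sample(self, rng):
        motif = "GATTACAGA"
        pos = [Probe(f"p{i}", random_seq(rng, 4) + motif + random_seq(rng, 7), 2.0) for i in range(10)]
        neg = [Probe(f"n{i}", random_seq(rng, 20), 0.1) for i in range(10)]
        labels = np.r_[np.ones(10), np.zeros(10)]
        return TrainingSample(pos, neg, labels)

    def test_full_space_subset_matches_direct_training(self, rng):
        sample = self._sample(rng)
        cfg = TrainingConfig(params=self.P9, mode="regression")
        space = build_feature_space(sample.sequences, self.P9)
        m_sub = retrain_on_feature_subset(sample, list(space.features), cfg)
        from dimismatch.models import fit_in_space

        m_dir = fit_in_space(sample.sequences, sample.labels, space, cfg)
        seqs = [random_seq(rng, 25) for _ in range(4)]
        np.testing.assert_allclose(m_sub.predict(seqs), m_dir.predict(seqs), atol=1e-8)

    def test_empty_subset_rejected(self, rng):
        with pytest.raises(ValueError):
            retrain_on_feature_subset(self._sample(rng), [], TrainingConfig(params=self.P9))

    def test_informative_subset_beats_uninformative(self, rng):
        sample = self._sample(rng)
        cfg = TrainingConfig(params=self.P9, mode="regression")
        space = build_feature_space(sample.sequences, self.P9)
        motif_kmers = [f for f in space.features if _best_alignment("GATTACAGA", f + "", "single")[0] >= 8]
        junk_kmers = [f for f in space.features if f not in set(motif_kmers)][: len(motif_kmers)]
        m_motif = retrain_on_feature_subset(sample, motif_kmers, cfg)
        m_junk = retrain_on_feature_subset(sample, junk_kmers, cfg)
        test_pos = [random_seq(rng, 4) + "GATTACAGA" + random_seq(rng, 7) for _ in range(10)]
        test_neg = [random_seq(rng, 20) for _ in range(10)]
        gap_motif = np.mean(m_motif.predict(test_pos)) - np.mean(m_motif.predict(test_neg))
        gap_junk = np.mean(m_junk.predict(test_pos)) - np.mean(m_junk.predict(test_neg))
        assert gap_motif > gap_junk
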