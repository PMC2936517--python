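"""Model dissection: embed, cluster, and expand the k-mer features of a
trained model.

A trained SVR/SVM assigns a weight to each k-mer feature, but individual
k-mers are hard to read.  The procedure here makes the learned sequence
preferences visible:

1. Represent each k-mer by its vector of optimal ungapped alignment scores
   (number of matching positions) against the positive training sequences;
   sequence-similar k-mers that hit the same probes land on nearby vectors.
2. Cluster the vectors with 2-means.  When a model has learned two binding
   modes (e.g. a primary motif and a cofactor or secondary motif), they
   separate into the two clusters.
3. Keep the top-weighted k-mers per cluster, project them to 2D with PCA
   for plotting, and pick one representative per cluster (top weight
   quartile, nearest the cluster centroid).
4. Expand a representative k-mer into a PSSM from the best-aligned windows
   of the top positive training sequences.
5. Optionally retrain restricted to one cluster's k-mers, to test which
   cluster carries the predictive signal for a given label set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .baselines import PSSM
from .kernel import DiMismatchParams, FeatureSpace, reverse_complement
from .models import LinearSequenceModel, TrainingConfig, fit_in_space

__all__ = [
    "FeatureEmbedding",
    "ClusterReport",
    "alignment_score_vectors",
    "cluster_model_features",
    "select_cluster_representative",
    "expand_feature_to_pssm",
    "retrain_on_feature_subset",
    "consensus_agreement",
    "plot_clusters",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


def _nt_onehot(seqs: Sequence[str], length: int) -> np.ndarray:
    """(n, 4*length) float32 one-hot of fixed-length sequences (non-ACGT ->
    all-zero column block)."""
    out = np.zeros((len(seqs), 4 * length), dtype=np.float32)
    for i, s in enumerate(seqs):
        for j, ch in enumerate(s.upper()):
            b = _BASE_INDEX.get(ch)
            if b is not None:
                out[i, 4 * j + b] = 1.0
    return out


@dataclass
class FeatureEmbedding:
    """k-mers embedded as alignment-score vectors over positive training
    sequences, with their model weights."""

    kmers: list
    vectors: np.ndarray  # (n_kmers, n_positive_sequences), integer-valued
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if len(self.kmers) != self.vectors.shape[0] or len(self.kmers) != len(self.weights):
            raise ValueError("kmers, vectors and weights must align")


def alignment_score_vectors(
    kmers: Sequence[str],
    positive_sequences: Sequence[str],
    weights: Optional[Sequence[float]] = None,
    strand_mode: str = "both",
) -> FeatureEmbedding:
    """Optimal ungapped alignment score of every k-mer against every
    positive training sequence.

    The score is the maximum, over all offsets (and both strands when
    ``strand_mode='both'``), of the number of matching positions between
    the k-mer and the aligned k-length window; entries are integers in
    [0, k].
    """
    if not kmers or not positive_sequences:
        raise ValueError("kmers and positive_sequences must be non-empty")
    k = len(kmers[0])
    if any(len(u) != k for u in kmers):
        raise ValueError("all k-mers must have equal length")
    if any(len(s) < k for s in positive_sequences):
        raise ValueError(f"all sequences must be at least {k} nt")
    K = _nt_onehot(list(kmers), k)
    if strand_mode == "both":
        Krc = _nt_onehot([reverse_complement(u) for u in kmers], k)
        K = np.concatenate([K, Krc])
    vectors = np.empty((len(kmers), len(positive_sequences)))
    for j, seq in enumerate(positive_sequences):
        wins = [seq[i : i + k] for i in range(len(seq) - k + 1)]
        W = _nt_onehot(wins, k)
        scores = W @ K.T  # (n_windows, n_kmer_rows)
        best = scores.max(axis=0)
        if strand_mode == "both":
            best = np.maximum(best[: len(kmers)], best[len(kmers) :])
        vectors[:, j] = best
    w = np.zeros(len(kmers)) if weights is None else np.asarray(weights, dtype=np.float64)
    return FeatureEmbedding(list(kmers), vectors, w)


def embed_model_features(
    model: LinearSequenceModel, positive_sequences: Sequence[str]
) -> FeatureEmbedding:
    """Embedding of a trained model's feature k-mers carrying its weights."""
    return alignment_score_vectors(
        list(model.space.features),
        positive_sequences,
        weights=model.weights,
        strand_mode=model.config.params.strand_mode,
    )


@dataclass
class ClusterReport:
    """2-means clustering of model features with PCA projection.

    ``assignment`` maps every clustered k-mer to a cluster id (1-based);
    ``table`` holds the kept (top-weight) k-mers with cluster, weight, and
    2D PCA coordinates; ``representatives`` maps cluster id to its
    representative k-mer once selected.
    """

    assignment: Dict[str, int]
    table: pd.DataFrame
    centroids: Dict[int, np.ndarray]
    representatives: Dict[int, str] = field(default_factory=dict)
    expanded_pssms: Dict[int, PSSM] = field(default_factory=dict)

    def cluster_kmers(self, cluster: int, kept_only: bool = True) -> list:
        if kept_only:
            return self.table.loc[self.table["cluster"] == cluster, "kmer"].tolist()
        return [u for u, c in self.assignment.items() if c == cluster]


def cluster_model_features(
    embedding: FeatureEmbedding,
    top_per_cluster: int = 500,
    n_clusters: int = 2,
    seed: int = 0,
) -> ClusterReport:
    """k-means (k=2 by default) on alignment-score vectors.

    Per cluster the top ``top_per_cluster`` k-mers by model weight are
    kept (ties broken lexicographically); the kept union is projected to
    2D by PCA.  Cluster ids are relabeled 1..n by descending top member
    weight, so cluster 1 holds the strongest features.
    """
    V = embedding.vectors
    if V.shape[0] < 2 * n_clusters:
        raise ValueError(f"need at least {2 * n_clusters} k-mers to cluster")
    if np.allclose(V, V[0]):
        raise ValueError("degenerate clustering: all alignment vectors identical")
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    raw_labels = km.fit_predict(V)

    kmers = np.array(embedding.kmers)
    weights = embedding.weights
    # deterministic relabeling: cluster 1 = cluster with the largest member weight
    order = sorted(
        range(n_clusters),
        key=lambda c: (-weights[raw_labels == c].max(), min(kmers[raw_labels == c])),
    )
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = np.array([relabel[c] for c in raw_labels])

    keep_idx = []
    for c in range(1, n_clusters + 1):
        members = np.flatnonzero(labels == c)
        member_order = np.lexsort((kmers[members], -weights[members]))
        keep_idx.extend(members[member_order[:top_per_cluster]].tolist())
    keep_idx = np.array(sorted(keep_idx))

    proj = PCA(n_components=2, random_state=seed).fit_transform(V[keep_idx])
    table = pd.DataFrame(
        {
            "kmer": kmers[keep_idx],
            "cluster": labels[keep_idx],
            "weight": weights[keep_idx],
            "x": proj[:, 0],
            "y": proj[:, 1],
        }
    )
    centroids = {
        c: V[labels == c].mean(axis=0) for c in range(1, n_clusters + 1)
    }
    return ClusterReport(
        assignment=dict(zip(kmers.tolist(), labels.tolist())),
        table=table,
        centroids=centroids,
    )


def select_cluster_representative(
    report: ClusterReport, embedding: FeatureEmbedding
) -> Dict[int, str]:
    """One representative k-mer per cluster: among kept members in the top
    quartile of model weights, the one closest (Euclidean, on alignment
    vectors) to the cluster centroid; ties broken lexicographically."""
    index = {u: i for i, u in enumerate(embedding.kmers)}
    reps: Dict[int, str] = {}
    for c, centroid in report.centroids.items():
        sub = report.table[report.table["cluster"] == c]
        if sub.empty:
            continue
        cutoff = np.quantile(sub["weight"].to_numpy(), 0.75)
        elig = sub[sub["weight"] >= cutoff]
        best = None
        for _, row in elig.iterrows():
            v = embedding.vectors[index[row.kmer]]
            d = float(np.linalg.norm(v - centroid))
            key = (d, row.kmer)
            if best is None or key < best[0]:
                best = (key, row.kmer)
        reps[c] = best[1]
    report.representatives = reps
    return reps


def _best_alignment(kmer: str, sequence: str, strand_mode: str = "both"):
    """(score, offset, strand) of the optimal ungapped alignment of a k-mer
    within a sequence; strand '-' means the reverse complement of the k-mer
    matched the forward window."""
    k = len(kmer)
    candidates = [(kmer, "+")]
    if strand_mode == "both":
        candidates.append((reverse_complement(kmer), "-"))
    best = (-1, 0, "+")
    s = sequence.upper()
    for cand, strand in candidates:
        for off in range(len(s) - k + 1):
            score = sum(1 for a, b in zip(cand, s[off : off + k]) if a == b)
            if score > best[0]:
                best = (score, off, strand)
    return best


def expand_feature_to_pssm(
    kmer: str,
    positive_sequences: Sequence[str],
    top_n: int = 50,
    pseudocount: float = 0.5,
    strand_mode: str = "both",
    name: Optional[str] = None,
) -> PSSM:
    """Expand a k-mer feature into a PSSM from its best-matching windows.

    The ``top_n`` positive sequences with the highest optimal ungapped
    alignment score to the k-mer are selected; from each, the k-length
    window achieving that alignment is extracted (reverse-complemented when
    the k-mer matched on the minus strand) and the stack is converted to a
    position frequency matrix with a pseudocount.
    """
    if len(positive_sequences) < top_n:
        raise ValueError(f"need at least top_n={top_n} positive sequences")
    hits = []
    for j, seq in enumerate(positive_sequences):
        score, off, strand = _best_alignment(kmer, seq, strand_mode)
        hits.append((-score, j, off, strand))
    hits.sort()
    k = len(kmer)
    counts = np.zeros((k, 4), dtype=np.float64)
    for negscore, j, off, strand in hits[:top_n]:
        window = positive_sequences[j].upper()[off : off + k]
        if strand == "-":
            window = reverse_complement(window)
        for pos, ch in enumerate(window):
            b = _BASE_INDEX.get(ch)
            if b is not None:
                counts[pos, b] += 1.0
    probs = (counts + pseudocount) / (counts.sum(axis=1, keepdims=True) + 4 * pseudocount)
    return PSSM(probs, name=name or f"expanded_{kmer}")


def retrain_on_feature_subset(
    sample,
    cluster_kmers: Sequence[str],
    config: TrainingConfig,
) -> LinearSequenceModel:
    """Retrain restricting the feature space to the given k-mers.

    Used to ask which feature cluster carries the signal: retraining on
    the cluster matching the in vivo motif should preserve performance,
    retraining on the other cluster should lose it.
    """
    kmers = sorted(set(cluster_kmers))
    if not kmers:
        raise ValueError("empty feature subset")
    space = FeatureSpace(tuple(kmers), config.params.k)
    labels = (
        sample.labels if config.mode == "regression" else sample.class_labels
    )
    return fit_in_space(sample.sequences, labels, space, config)


def consensus_agreement(expanded: PSSM, planted: PSSM) -> float:
    """Fraction of planted-motif columns whose maximum-probability base
    agrees with the expanded PSSM's, maximized over alignment offsets and
    strands.  The expanded PSSM must be at least as wide as the planted
    one."""
    if expanded.width < planted.width:
        raise ValueError("expanded PSSM narrower than planted PSSM")
    best = 0.0
    for cand in (planted, planted.reverse_complement()):
        cons = cand.consensus
        exp_cons = expanded.consensus
        for off in range(expanded.width - cand.width + 1):
            agree = sum(
                1 for i, b in enumerate(cons) if exp_cons[off + i] == b
            ) / cand.width
            best = max(best, agree)
    return best


def plot_clusters(report: ClusterReport, path=None, ax=None):
    """Scatter the PCA projection: stars for cluster 1, circles for cluster
    2+, colored red (high weight) to blue (low weight)."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    markers = {1: "*", 2: "o", 3: "s", 4: "^"}
    t = report.table
    for c in sorted(t["cluster"].unique()):
        sub = t[t["cluster"] == c]
        ax.scatter(
            sub["x"],
            sub["y"],
            c=sub["weight"],
            cmap="coolwarm",
            marker=markers.get(int(c), "o"),
            label=f"cluster {c}",
            edgecolors="none",
            s=40,
        )
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend()
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
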