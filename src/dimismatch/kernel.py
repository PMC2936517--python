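"""Di-mismatch string kernel over DNA k-mers.

The di-mismatch kernel is a first-order Markov mismatch kernel: two k-mers
are compared in the alphabet of their k-1 overlapping dinucleotides, and the
similarity is the number of *matching* dinucleotides, zeroed when it falls
below a threshold of (k-1) - m matching dinucleotides (m = maximum tolerated
mismatching-dinucleotide count).  Because a single substituted nucleotide
disrupts two overlapping dinucleotides while a run of j consecutive
substitutions disrupts only j+1, the kernel inherently favors k-mers whose
mismatches are consecutive -- the mutation pattern typical of related
binding sites.

A sequence x is represented by the feature vector over a dictionary D of
k-mers (those occurring in training sequences):

    Phi(x)_f = sum over length-k windows s of x of  d(s, f)

where d is the thresholded di-mismatch score.  All operations here work in
this explicit feature space; `kernel_matrix` returns the induced Gram
matrix, and `KmerContributionTable` pre-computes per-window contributions of
a trained linear model so scanning a sequence of length L costs one table
lookup per window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DiMismatchParams",
    "FeatureSpace",
    "matching_dinucleotides",
    "di_mismatch_score",
    "build_feature_space",
    "feature_map",
    "feature_matrix",
    "kernel_matrix",
    "KmerContributionTable",
    "reverse_complement",
]

_BASES = "ACGT"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: dinucleotide class count used for one-hot encoding (4 x 4)
_NDINUC = 16


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes; non-ACGT characters become 255."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _check_kmer(s: str, k: int, name: str) -> None:
    if len(s) != k:
        raise ValueError(f"{name} {s!r} has length {len(s)}, expected k={k}")
    bad = set(s.upper()) - set(_BASES)
    if bad:
        raise ValueError(f"{name} {s!r} contains non-ACGT characters: {sorted(bad)}")


@dataclass(frozen=True)
class DiMismatchParams:
    """Hyperparameters of the di-mismatch kernel.

    Parameters
    ----------
    k : int
        k-mer length in nucleotides (k >= 2).
    m : int
        Maximum tolerated number of mismatching dinucleotides
        (0 <= m <= k-1).  The score threshold is ``(k-1) - m`` matching
        dinucleotides.
    strand_mode : {"both", "single"}
        Under ``"both"`` a k-mer is scored against a feature and its
        reverse complement and the maximum is taken; features are kept in
        canonical (lexicographically smaller strand) form.
    """

    k: int = 13
    m: int = 5
    strand_mode: str = "both"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        if not 0 <= self.m <= self.k - 1:
            raise ValueError(f"m must satisfy 0 <= m <= k-1, got m={self.m}, k={self.k}")
        if self.strand_mode not in ("single", "both"):
            raise ValueError(f"strand_mode must be 'single' or 'both', got {self.strand_mode!r}")

    @property
    def min_matching_dinucs(self) -> int:
        """Score threshold: (k-1) - m matching dinucleotides."""
        return self.k - 1 - self.m

    def require_training_valid(self) -> None:
        """PBM probes give good coverage of 8-mers, so model training
        requires k - m >= 8 (at least 8 matching characters)."""
        if self.k - self.m < 8:
            raise ValueError(
                f"training requires k - m >= 8 matching characters, got k={self.k}, m={self.m}"
            )

    def canonical(self, kmer: str) -> str:
        if self.strand_mode == "single":
            return kmer
        rc = reverse_complement(kmer)
        return min(kmer, rc)


def matching_dinucleotides(a: str, b: str) -> int:
    """Raw count of positions i (1..k-1) where the overlapping dinucleotides
    a[i:i+2] and b[i:i+2] agree.  No threshold applied."""
    if len(a) != len(b):
        raise ValueError(f"k-mer length mismatch: {a!r} vs {b!r}")
    _check_kmer(a, len(a), "k-mer")
    _check_kmer(b, len(b), "k-mer")
    ca, cb = _encode(a.upper()), _encode(b.upper())
    da = ca[:-1] * 4 + ca[1:]
    db = cb[:-1] * 4 + cb[1:]
    return int(np.count_nonzero(da == db))


def di_mismatch_score(a: str, b: str, params: DiMismatchParams) -> int:
    """Thresholded di-mismatch score between two k-mers.

    Returns the number of matching overlapping dinucleotides, or 0 if that
    count is below ``params.min_matching_dinucs``.  Under
    ``strand_mode='both'`` the maximum over ``b`` and its reverse complement
    is returned.
    """
    _check_kmer(a, params.k, "k-mer a")
    _check_kmer(b, params.k, "k-mer b")
    c = matching_dinucleotides(a, b)
    if params.strand_mode == "both":
        c = max(c, matching_dinucleotides(a, reverse_complement(b)))
    return c if c >= params.min_matching_dinucs else 0


@dataclass(frozen=True)
class FeatureSpace:
    """Ordered dictionary of k-mer features (lexicographic, unique,
    canonical by strand when built under strand_mode='both')."""

    features: tuple
    k: int

    index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "index", {f: i for i, f in enumerate(self.features)})
        if len(self.index) != len(self.features):
            raise ValueError("duplicate features in FeatureSpace")

    def __len__(self) -> int:
        return len(self.features)

    def subset(self, kmers: Iterable[str]) -> "FeatureSpace":
        """Restrict to the given k-mers (re-sorted lexicographically)."""
        kept = sorted(set(kmers))
        missing = [f for f in kept if f not in self.index]
        if missing:
            raise ValueError(f"k-mers not in feature space: {missing[:5]}")
        return FeatureSpace(tuple(kept), self.k)

    # -- plain-text serialization (one k-mer per line) --------------------
    def save(self, path, params: DiMismatchParams | None = None) -> None:
        with open(path, "w") as fh:
            if params is not None:
                fh.write(f"#k={params.k}\tm={params.m}\tstrand_mode={params.strand_mode}\n")
            else:
                fh.write(f"#k={self.k}\n")
            for f in self.features:
                fh.write(f + "\n")

    @classmethod
    def load(cls, path) -> "FeatureSpace":
        feats = []
        k = None
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    for tok in line[1:].split("\t"):
                        key, _, val = tok.partition("=")
                        if key == "k":
                            k = int(val)
                    continue
                feats.append(line)
        if not feats:
            raise ValueError(f"no features in {path}")
        if k is None:
            k = len(feats[0])
        return cls(tuple(sorted(set(feats))), k)


def build_feature_space(sequences: Sequence[str], params: DiMismatchParams) -> FeatureSpace:
    """Collect the distinct k-mers occurring as substrings of the input.

    Windows containing non-ACGT characters are skipped.  Under
    strand_mode='both' each k-mer is canonicalized to the lexicographically
    smaller of itself and its reverse complement.
    """
    if not sequences:
        raise ValueError("no sequences given")
    k = params.k
    seen: set[str] = set()
    for seq in sequences:
        s = seq.upper()
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if set(w) <= set(_BASES):
                seen.add(params.canonical(w))
    if not seen:
        raise ValueError(f"no valid length-{k} windows in input sequences")
    return FeatureSpace(tuple(sorted(seen)), k)


# ---------------------------------------------------------------------------
# Vectorized feature maps.
#
# The matching-dinucleotide count between two k-mers equals the inner product
# of their one-hot dinucleotide encodings (k-1 blocks of 16), so batched
# window-vs-feature counts reduce to a single matrix product, exact in
# float32 because every count is an integer <= k-1.
# ---------------------------------------------------------------------------


def _dinuc_codes(encoded: np.ndarray) -> np.ndarray:
    """Dinucleotide codes 0..15 of an encoded sequence; 16 marks codes
    touching a non-ACGT base."""
    a, b = encoded[:-1], encoded[1:]
    valid = (a < 4) & (b < 4)
    codes = np.where(valid, a.astype(np.int64) * 4 + b, _NDINUC)
    return codes


def _onehot(dinuc_rows: np.ndarray) -> np.ndarray:
    """(n, k-1) dinucleotide codes -> (n, 16*(k-1)) float32 one-hot.
    Code 16 (invalid) maps to an all-zero block."""
    n, p = dinuc_rows.shape
    out = np.zeros((n, p * _NDINUC), dtype=np.float32)
    rows = np.repeat(np.arange(n), p)
    cols = np.arange(p)[None, :] + np.zeros((n, 1), dtype=np.int64)
    flat = dinuc_rows.ravel()
    ok = flat < _NDINUC
    out[rows[ok], (cols.ravel()[ok] * _NDINUC + flat[ok])] = 1.0
    return out


def _encode_feature_blocks(space: FeatureSpace, params: DiMismatchParams):
    """One-hot blocks for the features and (if both strands) their reverse
    complements; cached on the FeatureSpace instance."""
    key = ("_onehot_cache", params.k, params.strand_mode)
    cache = getattr(space, "_onehot_cache", None)
    if cache is not None and cache[0] == key:
        return cache[1]
    fwd = np.ascontiguousarray(
        _onehot(np.stack([_dinuc_codes(_encode(f)) for f in space.features])).T
    )
    rc = None
    if params.strand_mode == "both":
        rc = np.ascontiguousarray(
            _onehot(
                np.stack([_dinuc_codes(_encode(reverse_complement(f))) for f in space.features])
            ).T
        )
    object.__setattr__(space, "_onehot_cache", (key, (fwd, rc)))
    return fwd, rc


def _window_dinucs(sequence: str, k: int):
    """All length-k window dinucleotide code rows of a sequence plus a
    validity mask (False where the window touches a non-ACGT base)."""
    s = _encode(sequence.upper())
    L = len(s)
    if L < k:
        raise ValueError(f"sequence of length {L} shorter than k={k}")
    codes = _dinuc_codes(s)  # length L-1
    win = np.lib.stride_tricks.sliding_window_view(codes, k - 1)
    valid = (win < _NDINUC).all(axis=1)
    return win, valid


try:
    from numba import njit as _njit

    @_njit(cache=True, fastmath=False)
    def _counts_loop(win, feat, feat_rc, use_rc, thr, out):  # pragma: no cover
        W, P = win.shape
        F = feat.shape[0]
        for i in range(W):
            for j in range(F):
                c = 0
                for p in range(P):
                    if win[i, p] == feat[j, p]:
                        c += 1
                if use_rc:
                    c2 = 0
                    for p in range(P):
                        if win[i, p] == feat_rc[j, p]:
                            c2 += 1
                    if c2 > c:
                        c = c2
                if c >= thr:
                    out[i, j] = c

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _encode_feature_codes(space: FeatureSpace, params: DiMismatchParams):
    """uint8 dinucleotide code rows for the features and (under both
    strands) their reverse complements; cached on the space."""
    key = ("_codes_cache", params.k, params.strand_mode)
    cache = getattr(space, "_codes_cache", None)
    if cache is not None and cache[0] == key:
        return cache[1]
    fwd = np.stack([_dinuc_codes(_encode(f)) for f in space.features]).astype(np.uint8)
    if params.strand_mode == "both":
        rc = np.stack(
            [_dinuc_codes(_encode(reverse_complement(f))) for f in space.features]
        ).astype(np.uint8)
    else:
        rc = fwd
    object.__setattr__(space, "_codes_cache", (key, (fwd, rc)))
    return fwd, rc


def _sparse_onehot(dinuc_rows: np.ndarray):
    """Sparse CSR one-hot of window dinucleotide codes (12 nonzeros of 192
    per row for k=13); invalid codes are simply absent."""
    from scipy import sparse

    n, p = dinuc_rows.shape
    flat = dinuc_rows.ravel()
    ok = flat < _NDINUC
    rows = np.repeat(np.arange(n), p)[ok]
    cols = (np.tile(np.arange(p), n)[ok] * _NDINUC + flat[ok])
    data = np.ones(ok.sum(), dtype=np.float32)
    return sparse.csr_matrix((data, (rows, cols)), shape=(n, p * _NDINUC))


def _window_counts(
    win: np.ndarray, valid: np.ndarray, space: FeatureSpace, params: DiMismatchParams
) -> np.ndarray:
    """(n_windows, n_features) thresholded di-mismatch scores."""
    if _HAVE_NUMBA:
        fwd, rc = _encode_feature_codes(space, params)
        counts = np.zeros((win.shape[0], fwd.shape[0]), dtype=np.float32)
        _counts_loop(
            win.astype(np.uint8),
            fwd,
            rc,
            params.strand_mode == "both",
            params.min_matching_dinucs,
            counts,
        )
    else:
        fwd_t, rc_t = _encode_feature_blocks(space, params)
        W = _sparse_onehot(win)
        counts = np.asarray(W @ fwd_t)
        if rc_t is not None:
            np.maximum(counts, np.asarray(W @ rc_t), out=counts)
        counts[counts < params.min_matching_dinucs] = 0.0
    if not valid.all():
        counts[~valid] = 0.0
    return counts


def feature_matrix(
    sequences: Sequence[str],
    space: FeatureSpace,
    params: DiMismatchParams,
    chunk: int = 4096,
) -> np.ndarray:
    """Stacked feature vectors: row i is Phi(sequences[i]) over the space.

    Feature entry f = sum over length-k windows s of the thresholded
    di-mismatch score d(s, f).  Windows containing non-ACGT characters
    contribute 0 to every feature.
    """
    if params.k != space.k:
        raise ValueError(f"params.k={params.k} does not match space.k={space.k}")
    n = len(sequences)
    out = np.zeros((n, len(space)), dtype=np.float64)
    wins, valids, owners = [], [], []
    buffered = 0

    def flush() -> None:
        nonlocal wins, valids, owners, buffered
        if not wins:
            return
        W = np.concatenate(wins)
        V = np.concatenate(valids)
        O = np.concatenate(owners)
        counts = _window_counts(W, V, space, params).astype(np.float64)
        # owners are sorted and contiguous within a chunk -> segment sums
        starts = np.flatnonzero(np.r_[True, O[1:] != O[:-1]])
        sums = np.add.reduceat(counts, starts, axis=0)
        out[O[starts]] += sums
        wins, valids, owners = [], [], []
        buffered = 0

    for i, seq in enumerate(sequences):
        w, v = _window_dinucs(seq, params.k)
        wins.append(w)
        valids.append(v)
        owners.append(np.full(len(w), i, dtype=np.int64))
        buffered += len(w)
        if buffered >= chunk:
            flush()
    flush()
    return out


def feature_map(sequence: str, space: FeatureSpace, params: DiMismatchParams) -> np.ndarray:
    """Di-mismatch feature vector of a single sequence (dense, length |space|)."""
    return feature_matrix([sequence], space, params)[0]


def kernel_matrix(
    X: Sequence[str],
    Y: Sequence[str],
    space: FeatureSpace,
    params: DiMismatchParams,
) -> np.ndarray:
    """Gram matrix of explicit di-mismatch feature vectors:
    K[i, j] = <Phi(X[i]), Phi(Y[j])>.  For X = Y the matrix is symmetric
    positive semi-definite."""
    FX = feature_matrix(X, space, params)
    FY = FX if Y is X else feature_matrix(Y, space, params)
    return FX @ FY.T


class KmerContributionTable:
    """Per-k-mer contributions of a linear model, for linear-time scanning.

    Every window k-mer u has contribution ``sum_f w_f * d(u, f)``; entries
    are computed on demand and memoized, so scoring a sequence of length L
    costs one lookup per each of its L-k+1 windows plus the bias once.
    """

    def __init__(self, space: FeatureSpace, weights: np.ndarray, bias: float, params: DiMismatchParams):
        if len(weights) != len(space):
            raise ValueError("weights length does not match feature space")
        self.space = space
        self.weights = np.asarray(weights, dtype=np.float64)
        self.bias = float(bias)
        self.params = params
        self._table: dict[str, float] = {}

    def contribution(self, kmer: str) -> float:
        """Contribution of one window k-mer (0.0 for windows with non-ACGT)."""
        val = self._table.get(kmer)
        if val is None:
            val = self._compute([kmer])[0]
            self._table[kmer] = val
        return val

    def _compute(self, kmers: list[str]) -> np.ndarray:
        k = self.params.k
        rows = []
        valid = []
        for u in kmers:
            enc = _encode(u.upper())
            if len(enc) != k:
                raise ValueError(f"window {u!r} has length {len(u)}, expected {k}")
            rows.append(_dinuc_codes(enc))
            valid.append(bool((enc < 4).all()))
        counts = _window_counts(np.stack(rows), np.asarray(valid), self.space, self.params)
        return counts.astype(np.float64) @ self.weights

    def window_contributions(self, sequence: str) -> np.ndarray:
        """Contributions of all length-k windows of a sequence (vectorized,
        cache-assisted)."""
        s = sequence.upper()
        k = self.params.k
        kmers = [s[i : i + k] for i in range(len(s) - k + 1)]
        out = np.empty(len(kmers))
        missing_idx = [i for i, u in enumerate(kmers) if u not in self._table]
        if missing_idx:
            vals = self._compute([kmers[i] for i in missing_idx])
            for j, i in enumerate(missing_idx):
                self._table[kmers[i]] = vals[j]
        for i, u in enumerate(kmers):
            out[i] = self._table[u]
        return out

    def score_sequence(self, sequence: str) -> float:
        """Model prediction via table lookups: window-sum + bias.  Matches
        the explicit feature-map prediction exactly (same integer counts)."""
        return float(self.window_contributions(sequence).sum() + self.bias)
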