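"""Support-vector models in the explicit di-mismatch feature space.

Two model classes follow the fit/results pattern:

* :class:`PBMRegression` -- epsilon-insensitive support-vector regression of
  normalized PBM probe intensities on di-mismatch k-mer features (the in
  vitro binding model).
* :class:`ChIPClassification` -- soft-margin linear SVM separating 60-bp
  ChIP-seq peak windows from flanking negatives (the in vivo model).

Both ``fit()`` methods return a :class:`LinearSequenceModel` results object
holding the primal weight per k-mer feature plus bias, diagnostics, and a
``summary()`` table.  Because the kernel is computed through an explicit
feature map, the trained model is a plain linear function of the feature
vector and can be scanned across genomic sequence in linear time via a
precomputed k-mer contribution table.

The epsilon tube width is fixed at 0.1 by default; C defaults to 1.0 and is
exposed.  The classification default kernel setting is (k, m) = (13, 5).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC, SVR

from .kernel import (
    DiMismatchParams,
    FeatureSpace,
    KmerContributionTable,
    build_feature_space,
    feature_matrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "LinearSequenceModel",
    "PBMRegression",
    "ChIPClassification",
    "train_regressor",
    "train_classifier",
    "predict_scores",
    "detection_top_n",
    "cross_design_evaluate",
    "cross_design_symmetric",
    "crossval_auc",
    "CrossDesignResult",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters shared by the SVR and SVM models.

    epsilon : SVR tube width (fixed at 0.1 in all reference experiments).
    C : regularization strength (not pinned by the protocol; default 1.0).
    params : di-mismatch kernel parameters; training enforces k - m >= 8.
    max_features : cap on discriminatively selected k-mer features (4000).
    mode : "regression" (PBM) or "classification" (ChIP windows).
    """

    epsilon: float = 0.1
    C: float = 1.0
    params: DiMismatchParams = field(default_factory=DiMismatchParams)
    max_features: int = 4000
    mode: str = "regression"
    #: optional grid for internal cross-validated C selection on the
    #: training sample (regression only); None keeps C fixed
    C_grid: Optional[tuple] = None
    #: solver convergence tolerance (libsvm tol)
    tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.mode not in ("regression", "classification"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "regression" and not self.epsilon > 0:
            raise ValueError("epsilon must be > 0 for regression")
        if not self.C > 0:
            raise ValueError("C must be > 0")


@dataclass
class LinearSequenceModel:
    """Fitted results: an affine function of the di-mismatch feature map.

    ``predict(x) = weights . Phi(x) + bias`` where Phi sums thresholded
    di-mismatch scores of every length-k window of x against each k-mer
    feature.
    """

    space: FeatureSpace
    weights: np.ndarray
    bias: float
    config: TrainingConfig
    provenance: str = ""
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if len(self.weights) != len(self.space):
            raise ValueError("one weight per feature required")

    # -- scoring ----------------------------------------------------------
    def predict(self, sequences: Sequence[str], method: str = "explicit") -> np.ndarray:
        """Scores for sequences (>= k nt).  ``method='table'`` uses the
        precomputed k-mer contribution table; both paths agree to 1e-9."""
        if method == "table":
            table = self.contribution_table()
            return np.array([table.score_sequence(s) for s in sequences])
        X = feature_matrix(sequences, self.space, self.config.params)
        return X @ self.weights + self.bias

    def contribution_table(self) -> KmerContributionTable:
        if not hasattr(self, "_table"):
            self._table = KmerContributionTable(
                self.space, self.weights, self.bias, self.config.params
            )
        return self._table

    def weight_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"kmer": self.space.features, "weight": self.weights})

    def summary(self, top: int = 10) -> str:
        p = self.config.params
        w = self.weight_frame().sort_values("weight", ascending=False)
        lines = [
            "Linear di-mismatch sequence model",
            "=" * 48,
            f"mode:            {self.config.mode}",
            f"kernel:          k={p.k}, m={p.m}, strand={p.strand_mode}"
            f" (threshold {p.min_matching_dinucs} matching dinucleotides)",
            f"features:        {len(self.space)}",
            f"bias:            {self.bias:+.6g}",
        ]
        for key, val in sorted(self.diagnostics.items()):
            lines.append(f"{key + ':':<17}{val:.4g}" if isinstance(val, float) else f"{key + ':':<17}{val}")
        if self.provenance:
            lines.append(f"provenance:      {self.provenance}")
        lines.append("-" * 48)
        lines.append(f"top {top} positively weighted k-mer features:")
        for _, row in w.head(top).iterrows():
            lines.append(f"  {row.kmer}  {row.weight:+.5f}")
        return "\n".join(lines)

    # -- serialization: JSON header + feature/weight TSV ------------------
    def save(self, path) -> None:
        p = self.config.params
        header = {
            "epsilon": self.config.epsilon,
            "C": self.config.C,
            "k": p.k,
            "m": p.m,
            "strand_mode": p.strand_mode,
            "max_features": self.config.max_features,
            "mode": self.config.mode,
            "bias": self.bias,
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            fh.write("#" + json.dumps(header) + "\n")
            fh.write("kmer\tweight\n")
            for f, w in zip(self.space.features, self.weights):
                fh.write(f"{f}\t{float(w)!r}\n")

    @classmethod
    def load(cls, path) -> "LinearSequenceModel":
        with open(path) as fh:
            header = json.loads(fh.readline().lstrip("#"))
            df = pd.read_csv(fh, sep="\t")
        config = TrainingConfig(
            epsilon=header["epsilon"],
            C=header["C"],
            params=DiMismatchParams(header["k"], header["m"], header["strand_mode"]),
            max_features=header["max_features"],
            mode=header["mode"],
        )
        order = np.argsort(df["kmer"].to_numpy())
        space = FeatureSpace(tuple(df["kmer"].to_numpy()[order]), header["k"])
        return cls(
            space=space,
            weights=df["weight"].to_numpy()[order],
            bias=header["bias"],
            config=config,
            provenance=header.get("provenance", ""),
        )


def _select_columns(
    X: np.ndarray, is_pos: np.ndarray, features: np.ndarray, max_features: int
) -> np.ndarray:
    """Indices of the columns with largest |mean_pos - mean_neg|,
    ties broken lexicographically, result sorted so feature order stays
    lexicographic."""
    diff = np.abs(X[is_pos].mean(axis=0) - X[~is_pos].mean(axis=0))
    order = np.lexsort((features, -diff))
    return np.sort(order[:max_features])


def _select_C_by_cv(X: np.ndarray, y: np.ndarray, cfg: TrainingConfig, folds: int = 5) -> float:
    """Pick C from cfg.C_grid by k-fold cross-validated Spearman rank
    correlation of held-out predictions (ties resolved toward the smaller,
    more regularized C).  Deterministic fold assignment."""
    from scipy.stats import spearmanr
    from sklearn.model_selection import KFold

    kf = KFold(n_splits=folds, shuffle=True, random_state=0)
    best = None
    for C in sorted(cfg.C_grid):
        rhos = []
        for tr, te in kf.split(X):
            svr = SVR(kernel="linear", C=C, epsilon=cfg.epsilon)
            svr.fit(X[tr], y[tr])
            rho = spearmanr(svr.predict(X[te]), y[te]).statistic
            rhos.append(0.0 if np.isnan(rho) else rho)
        mean_rho = float(np.mean(rhos))
        if best is None or mean_rho > best[0] + 1e-12:
            best = (mean_rho, C)
    logger.info("cross-validated C selection: C=%g (rho=%.3f)", best[1], best[0])
    return best[1]


class PBMRegression:
    """Epsilon-insensitive SVR of normalized probe intensity on di-mismatch
    features.

    Built from a tail-sampled :class:`~dimismatch.pbm.TrainingSample`; the
    feature dictionary is the set of k-mers occurring in the training
    probes, reduced to the ``max_features`` most class-discriminative ones.
    """

    def __init__(self, sample, config: Optional[TrainingConfig] = None):
        self.config = config or TrainingConfig(mode="regression")
        if self.config.mode != "regression":
            raise ValueError("PBMRegression requires mode='regression'")
        self.config.params.require_training_valid()
        self.sample = sample

    def fit(self) -> LinearSequenceModel:
        cfg = self.config
        seqs = self.sample.sequences
        labels = np.asarray(self.sample.labels, dtype=np.float64)
        space = build_feature_space(seqs, cfg.params)
        X = feature_matrix(seqs, space, cfg.params)
        is_pos = np.r_[
            np.ones(len(self.sample.positives), dtype=bool),
            np.zeros(len(self.sample.negatives), dtype=bool),
        ]
        cols = _select_columns(X, is_pos, np.array(space.features), cfg.max_features)
        space = FeatureSpace(tuple(np.array(space.features)[cols]), cfg.params.k)
        X = X[:, cols]

        if np.ptp(labels) == 0:
            logger.warning("degenerate labels (all equal); model will be near-constant")
        C = cfg.C
        if cfg.C_grid:
            C = _select_C_by_cv(X, labels, cfg)
        svr = SVR(kernel="linear", C=C, epsilon=cfg.epsilon, tol=cfg.tol)
        svr.fit(X, labels)
        weights = np.asarray(svr.coef_).ravel()
        bias = float(svr.intercept_[0])
        fitted = X @ weights + bias
        resid = labels - fitted
        return LinearSequenceModel(
            space=space,
            weights=weights,
            bias=bias,
            config=cfg,
            provenance=f"PBMRegression design={getattr(self.sample, 'design_id', '')} n={len(seqs)}",
            diagnostics={
                "n_train": len(seqs),
                "n_support": int(svr.n_support_.sum()) if hasattr(svr, "n_support_") else len(svr.support_),
                "train_rmse": float(np.sqrt(np.mean(resid**2))),
                "C_used": float(C),
            },
        )


class ChIPClassification:
    """Soft-margin linear SVM separating peak windows from flank windows.

    ``windows`` is any object exposing ``sequences`` (60-nt strings) and
    ``class_labels`` (+1/-1).  The kernel setting is the standard
    (k, m) = (13, 5) unless overridden in the config.
    """

    def __init__(self, windows, config: Optional[TrainingConfig] = None):
        self.config = config or TrainingConfig(mode="classification")
        if self.config.mode != "classification":
            raise ValueError("ChIPClassification requires mode='classification'")
        self.config.params.require_training_valid()
        self.windows = windows

    def fit(self) -> LinearSequenceModel:
        cfg = self.config
        seqs = list(self.windows.sequences)
        y = np.asarray(self.windows.class_labels, dtype=np.float64)
        if len(np.unique(y)) < 2:
            raise ValueError("classification requires both classes present")
        space = build_feature_space(seqs, cfg.params)
        X = feature_matrix(seqs, space, cfg.params)
        cols = _select_columns(X, y > 0, np.array(space.features), cfg.max_features)
        space = FeatureSpace(tuple(np.array(space.features)[cols]), cfg.params.k)
        X = X[:, cols]

        svc = SVC(kernel="linear", C=cfg.C, tol=cfg.tol)
        svc.fit(X, y)
        weights = np.asarray(svc.coef_).ravel()
        bias = float(svc.intercept_[0])
        acc = float(np.mean(np.sign(X @ weights + bias) == np.sign(y)))
        return LinearSequenceModel(
            space=space,
            weights=weights,
            bias=bias,
            config=cfg,
            provenance=f"ChIPClassification n={len(seqs)}",
            diagnostics={"n_train": len(seqs), "train_accuracy": acc},
        )


def fit_in_space(
    sequences: Sequence[str],
    labels,
    space: FeatureSpace,
    config: TrainingConfig,
) -> LinearSequenceModel:
    """Fit an SVR or SVM in a fixed, caller-supplied feature space (no
    dictionary construction or feature selection)."""
    y = np.asarray(labels, dtype=np.float64)
    X = feature_matrix(sequences, space, config.params)
    if config.mode == "regression":
        est = SVR(kernel="linear", C=config.C, epsilon=config.epsilon, tol=config.tol)
    else:
        if len(np.unique(y)) < 2:
            raise ValueError("classification requires both classes present")
        est = SVC(kernel="linear", C=config.C, tol=config.tol)
    est.fit(X, y)
    return LinearSequenceModel(
        space=space,
        weights=np.asarray(est.coef_).ravel(),
        bias=float(est.intercept_[0]),
        config=config,
        provenance=f"fit_in_space n={len(sequences)} |space|={len(space)}",
        diagnostics={"n_train": len(sequences)},
    )


def train_regressor(sample, config: Optional[TrainingConfig] = None) -> LinearSequenceModel:
    """Functional wrapper around :class:`PBMRegression`."""
    return PBMRegression(sample, config).fit()


def train_classifier(windows, config: Optional[TrainingConfig] = None) -> LinearSequenceModel:
    """Functional wrapper around :class:`ChIPClassification`."""
    return ChIPClassification(windows, config).fit()


def predict_scores(model: LinearSequenceModel, sequences: Sequence[str]) -> np.ndarray:
    return model.predict(sequences)


def detection_top_n(
    pred_scores,
    true_scores,
    n: int,
    ids: Optional[Sequence] = None,
) -> int:
    """Size of the overlap between the top-n items by predicted score and
    the top-n by measured score.  Ties are broken by (score, id)."""
    pred = np.asarray(pred_scores, dtype=np.float64)
    true = np.asarray(true_scores, dtype=np.float64)
    if pred.shape != true.shape:
        raise ValueError("score lists must have equal length")
    if n > len(pred):
        raise ValueError(f"n={n} exceeds number of items {len(pred)}")
    idarr = np.arange(len(pred)) if ids is None else np.asarray(ids)
    top_pred = set(np.lexsort((idarr, -pred))[:n].tolist())
    top_true = set(np.lexsort((idarr, -true))[:n].tolist())
    return len(top_pred & top_true)


@dataclass
class CrossDesignResult:
    """Outcome of the cross-design evaluation protocol."""

    detection: int
    n: int
    model: LinearSequenceModel
    predictions: np.ndarray

    @property
    def rate(self) -> float:
        return self.detection / self.n


def cross_design_evaluate(
    train_set,
    test_set,
    config: Optional[TrainingConfig] = None,
    n: int = 100,
    z_threshold: float = 4.0,
    min_positives: int = 500,
) -> CrossDesignResult:
    """Full cross-design protocol: normalize, tail-sample and train on one
    array design, predict every probe of the other design, and report the
    detection of the test design's top-n probes."""
    from .pbm import normalize_intensities, sample_training_probes

    train_norm = normalize_intensities(train_set)
    test_norm = normalize_intensities(test_set)
    sample = sample_training_probes(train_norm, z_threshold=z_threshold, min_positives=min_positives)
    model = train_regressor(sample, config)
    pred = model.predict(test_norm.sequences)
    ids = np.array([p.id for p in test_norm.probes])
    det = detection_top_n(pred, test_norm.normalized, n, ids=ids)
    return CrossDesignResult(detection=det, n=n, model=model, predictions=pred)


def cross_design_symmetric(
    design_a,
    design_b,
    config: Optional[TrainingConfig] = None,
    n: int = 100,
    **kwargs,
) -> tuple:
    """Run cross-design evaluation in both directions and average the
    detection rates.  Returns (mean_detection, result_ab, result_ba)."""
    ab = cross_design_evaluate(design_a, design_b, config, n=n, **kwargs)
    ba = cross_design_evaluate(design_b, design_a, config, n=n, **kwargs)
    return (ab.detection + ba.detection) / 2.0, ab, ba


def crossval_auc(
    windows,
    config: Optional[TrainingConfig] = None,
    folds: int = 10,
    seed: int = 0,
) -> tuple:
    """Stratified k-fold cross-validated ROC AUC of the window classifier.

    The k-mer dictionary is built once from all windows (an unsupervised
    step); discriminative feature selection and SVM fitting are repeated
    inside each training fold.  Returns (mean_auc, per_fold_aucs).
    """
    cfg = config or TrainingConfig(mode="classification")
    seqs = list(windows.sequences)
    y = np.asarray(windows.class_labels, dtype=np.float64)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < folds:
        raise ValueError(f"need >= {folds} examples per class for {folds}-fold stratified CV")
    space = build_feature_space(seqs, cfg.params)
    X = feature_matrix(seqs, space, cfg.params)
    return crossval_auc_matrix(X, y, np.array(space.features), cfg, folds=folds, seed=seed)


def crossval_auc_matrix(
    X: np.ndarray,
    y: np.ndarray,
    feats: np.ndarray,
    config: Optional[TrainingConfig] = None,
    folds: int = 10,
    seed: int = 0,
) -> tuple:
    """Cross-validated AUC on a precomputed feature matrix; lets repeated
    evaluations (e.g. permutation nulls) share the expensive feature map."""
    cfg = config or TrainingConfig(mode="classification")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(X, y):
        cols = _select_columns(X[tr], y[tr] > 0, feats, cfg.max_features)
        svc = SVC(kernel="linear", C=cfg.C)
        svc.fit(X[np.ix_(tr, cols)], y[tr])
        dec = svc.decision_function(X[np.ix_(te, cols)])
        aucs.append(roc_auc_score(y[te], dec))
    aucs = np.array(aucs)
    return float(aucs.mean()), aucs
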