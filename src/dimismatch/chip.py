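"""ChIP-seq window construction and in vivo model training/comparison.

From a ranked peak list and a genome, the top peaks define positive
examples: the 60-bp window centered on each peak summit.  The matched
negative is the 60-bp window whose center lies 300 bp to the left of the
summit (flanking sequence from the same locus, controlling for local
composition).  Peak calling itself is upstream; peaks are inputs (BED-like,
optional summit column, midpoint used otherwise).

`run_chip_training` fits the in vivo SVM with 10-fold cross-validated AUC;
`compare_models` scores a fixed window set with any collection of models
(in vivo SVMs by direct decision value, in vitro SVRs by maximum sliding
36-mer window score) and tabulates AUCs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Dict, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .models import LinearSequenceModel, TrainingConfig, crossval_auc, train_classifier
from .scan import max_window_score

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "PeakSet",
    "LabeledWindowSet",
    "read_peaks",
    "extract_training_windows",
    "run_chip_training",
    "compare_models",
]

WINDOW = 60
HALF = WINDOW // 2
NEG_OFFSET = 300


@dataclass(frozen=True)
class Peak:
    chrom: str
    summit: int  # 0-based coordinate of the peak summit
    score: float


@dataclass
class PeakSet:
    """Ranked ChIP peaks (scores non-increasing when ranked=True)."""

    peaks: list
    ranked: bool = True

    def __post_init__(self) -> None:
        if self.ranked:
            scores = [p.score for p in self.peaks]
            if any(a < b for a, b in zip(scores, scores[1:])):
                raise ValueError("ranked PeakSet requires non-increasing scores")

    def __len__(self) -> int:
        return len(self.peaks)

    def top(self, n: int) -> "PeakSet":
        peaks = self.peaks if self.ranked else sorted(self.peaks, key=lambda p: -p.score)
        return PeakSet(list(peaks[:n]), ranked=True)


@dataclass
class LabeledWindowSet:
    """Balanced 60-nt windows with +/-1 labels and genomic origins."""

    sequences: list
    labels: np.ndarray
    origins: list

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        bad = [i for i, s in enumerate(self.sequences) if len(s) != WINDOW]
        if bad:
            raise ValueError(f"windows of wrong length at indices {bad[:5]} (need {WINDOW} nt)")
        if not set(np.unique(self.labels)) <= {-1, 1}:
            raise ValueError("labels must be +1/-1")
        if len(self.labels) != len(self.sequences) or len(self.origins) != len(self.sequences):
            raise ValueError("sequences, labels and origins must align")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def class_labels(self) -> np.ndarray:
        return self.labels.astype(np.float64)

    def save_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for seq, lab, orig in zip(self.sequences, self.labels, self.origins):
                fh.write(f">{orig}|label={int(lab):+d}\n{seq}\n")


def read_peaks(path, summit_col: Optional[int] = None, score_col: int = 4) -> PeakSet:
    """Read a BED-like peak file (chrom, start, end, [name, score, ...]).

    ``summit_col`` gives the 0-based column index holding an absolute summit
    coordinate; without it the interval midpoint is used.  Peaks are sorted
    by descending score.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    peaks = []
    for _, row in df.iterrows():
        chrom, start, end = str(row[0]), int(row[1]), int(row[2])
        summit = int(row[summit_col]) if summit_col is not None else (start + end) // 2
        score = float(row[score_col]) if df.shape[1] > score_col else 0.0
        peaks.append(Peak(chrom, summit, score))
    peaks.sort(key=lambda p: -p.score)
    return PeakSet(peaks, ranked=True)


def _frac_n(seq: str) -> float:
    return sum(1 for c in seq if c not in "ACGT") / max(len(seq), 1)


def extract_training_windows(
    peaks: PeakSet,
    genome: Mapping[str, str],
    n_peaks: int = 1000,
    neg_offset: int = NEG_OFFSET,
    neg_side: str = "left",
) -> LabeledWindowSet:
    """Build the balanced peak/flank window set from the top peaks.

    For each of the top ``n_peaks`` peaks the positive is the 60-bp window
    centered on the summit, [summit-30, summit+30); the negative is the
    60-bp window whose center is ``neg_offset`` bp to the left of the summit
    (``neg_side='right'`` flips the direction).  Peaks whose windows run off
    the chromosome or are more than 50% non-ACGT are skipped with a log
    entry, keeping the output balanced.
    """
    if neg_side not in ("left", "right"):
        raise ValueError("neg_side must be 'left' or 'right'")
    sign = -1 if neg_side == "left" else 1
    seqs, labels, origins = [], [], []
    n_skipped = 0
    for peak in peaks.top(n_peaks).peaks:
        chrom_seq = genome.get(peak.chrom)
        if chrom_seq is None:
            raise KeyError(f"chromosome {peak.chrom!r} not in genome")
        pos_start = peak.summit - HALF
        neg_center = peak.summit + sign * neg_offset
        neg_start = neg_center - HALF
        ok = True
        for s in (pos_start, neg_start):
            if s < 0 or s + WINDOW > len(chrom_seq):
                ok = False
        if ok:
            pos_seq = chrom_seq[pos_start : pos_start + WINDOW].upper()
            neg_seq = chrom_seq[neg_start : neg_start + WINDOW].upper()
            if _frac_n(pos_seq) > 0.5 or _frac_n(neg_seq) > 0.5:
                ok = False
        if not ok:
            n_skipped += 1
            logger.info("skipping peak %s:%d (edge or N-heavy window)", peak.chrom, peak.summit)
            continue
        seqs.append(pos_seq)
        labels.append(1)
        origins.append(f"{peak.chrom}:{pos_start}-{pos_start + WINDOW}")
        seqs.append(neg_seq)
        labels.append(-1)
        origins.append(f"{peak.chrom}:{neg_start}-{neg_start + WINDOW}")
    if n_skipped:
        logger.warning("skipped %d peaks with unusable windows", n_skipped)
    if sum(1 for l in labels if l == 1) < 10:
        raise ValueError("fewer than 10 usable peaks")
    return LabeledWindowSet(seqs, np.array(labels), origins)


def run_chip_training(
    windows: LabeledWindowSet,
    config: Optional[TrainingConfig] = None,
    folds: int = 10,
    seed: int = 0,
):
    """Train the in vivo SVM and report cross-validated performance.

    Returns (model trained on all windows, mean CV AUC, per-fold AUCs).
    """
    cfg = config or TrainingConfig(mode="classification")
    mean_auc, fold_aucs = crossval_auc(windows, cfg, folds=folds, seed=seed)
    model = train_classifier(windows, cfg)
    model.diagnostics["cv_auc"] = mean_auc
    return model, mean_auc, fold_aucs


Scorer = Union[LinearSequenceModel, Callable[[str], float]]


def compare_models(
    windows: LabeledWindowSet,
    models: Mapping[str, Scorer],
    window_length: int = 36,
) -> pd.DataFrame:
    """AUC of each named model on a fixed labeled window set.

    A classification model scores a 60-mer by its decision value; a
    regression (PBM-trained) model by its maximum sliding
    ``window_length``-mer score; a bare callable is applied per sequence.
    Returns a DataFrame (model, auc) sorted by AUC descending.
    """
    y = windows.class_labels
    rows = []
    for name, scorer in models.items():
        if isinstance(scorer, LinearSequenceModel):
            if scorer.config.mode == "regression":
                scores = [max_window_score(scorer, s, window_length) for s in windows.sequences]
            else:
                scores = scorer.predict(windows.sequences)
        else:
            scores = [scorer(s) for s in windows.sequences]
        rows.append((name, roc_auc_score(y, np.asarray(scores, dtype=np.float64))))
    return (
        pd.DataFrame(rows, columns=["model", "auc"])
        .sort_values("auc", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
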