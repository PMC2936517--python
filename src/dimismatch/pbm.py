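"""Protein-binding-microarray (PBM) probe data handling.

A PBM array measures a TF's fluorescence intensity over ~44K designed
double-stranded 36-nt probes.  Only a few hundred probes indicate real
binding, so training a regressor on all probes would reward predicting
"unbound" everywhere.  This module normalizes intensities, samples an
informative training set from the two tails of the intensity distribution
(positives from the bound tail, the same number of negatives from the
unbound tail), and performs discriminative k-mer feature selection by the
difference of class-mean di-mismatch scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .kernel import DiMismatchParams, FeatureSpace, feature_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "Probe",
    "ProbeSet",
    "TrainingSample",
    "read_probe_table",
    "write_probe_table",
    "normalize_intensities",
    "sample_training_probes",
    "select_features",
]

_VALID = set("ACGT")


@dataclass(frozen=True)
class Probe:
    """One array probe: id, variable 36-nt double-stranded region, raw
    fluorescence intensity."""

    id: str
    sequence: str
    intensity: float


@dataclass
class ProbeSet:
    """A set of probes from one array design, optionally with normalized
    intensities (robust z-scores of log intensity)."""

    probes: list
    design_id: str = ""
    normalized: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        ids = [p.id for p in self.probes]
        if len(set(ids)) != len(ids):
            dupes = pd.Series(ids).value_counts()
            raise ValueError(f"duplicate probe ids: {list(dupes[dupes > 1].index[:5])}")
        if self.normalized is not None and len(self.normalized) != len(self.probes):
            raise ValueError("normalized vector length does not match probe count")

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def sequences(self) -> list:
        return [p.sequence for p in self.probes]

    @property
    def intensities(self) -> np.ndarray:
        return np.array([p.intensity for p in self.probes], dtype=np.float64)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "id": [p.id for p in self.probes],
                "sequence": self.sequences,
                "intensity": self.intensities,
            }
        )
        if self.normalized is not None:
            df["normalized"] = self.normalized
        return df


@dataclass
class TrainingSample:
    """Balanced positive/negative probe sample for model training.

    ``labels`` are the normalized intensities of positives followed by
    negatives (regression targets); classification models binarize them.
    """

    positives: list
    negatives: list
    labels: np.ndarray
    design_id: str = ""

    def __post_init__(self) -> None:
        if len(self.positives) != len(self.negatives):
            raise ValueError("positive and negative sets must be the same size")
        pos_ids = {p.id for p in self.positives}
        if pos_ids & {p.id for p in self.negatives}:
            raise ValueError("positive and negative sets overlap")
        if len(self.labels) != len(self.positives) + len(self.negatives):
            raise ValueError("labels length must equal total sample size")

    @property
    def sequences(self) -> list:
        return [p.sequence for p in self.positives] + [p.sequence for p in self.negatives]

    @property
    def class_labels(self) -> np.ndarray:
        """+1 for positives, -1 for negatives."""
        n = len(self.positives)
        return np.r_[np.ones(n), -np.ones(n)]

    def save(self, fasta_prefix: str) -> None:
        """Write <prefix>.pos.fasta, <prefix>.neg.fasta and <prefix>.labels.tsv."""
        for tag, probes in (("pos", self.positives), ("neg", self.negatives)):
            with open(f"{fasta_prefix}.{tag}.fasta", "w") as fh:
                for p in probes:
                    fh.write(f">{p.id}\n{p.sequence}\n")
        ids = [p.id for p in self.positives] + [p.id for p in self.negatives]
        pd.DataFrame({"id": ids, "label": self.labels}).to_csv(
            f"{fasta_prefix}.labels.tsv", sep="\t", index=False
        )


def read_probe_table(path, probe_length: int = 36, header: str = "auto") -> ProbeSet:
    """Read a tab-separated probe table (columns: id, sequence, intensity).

    Sequences are uppercased and validated to be exactly ``probe_length``
    ACGT characters; duplicate ids are rejected.
    """
    head = pd.read_csv(path, sep="\t", header=None, nrows=1)
    has_header = header == "yes" or (
        header == "auto" and not _looks_like_row(head.iloc[0], probe_length)
    )
    df = pd.read_csv(path, sep="\t", header=0 if has_header else None)
    if df.empty:
        raise ValueError(f"{path}: no data rows (is the single row malformed?)")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected 3 columns (id, sequence, intensity), got {df.shape[1]}")
    df = df.iloc[:, :3]
    df.columns = ["id", "sequence", "intensity"]
    df["sequence"] = df["sequence"].astype(str).str.upper()

    bad_len = df.index[df["sequence"].str.len() != probe_length]
    if len(bad_len):
        rows = ", ".join(str(i) for i in bad_len[:10])
        raise ValueError(f"{path}: rows with sequence length != {probe_length}: {rows}")
    bad_chr = df.index[~df["sequence"].str.fullmatch(f"[ACGT]{{{probe_length}}}")]
    if len(bad_chr):
        raise ValueError(f"{path}: non-ACGT sequences at rows {list(bad_chr[:10])}")
    intens = pd.to_numeric(df["intensity"], errors="coerce")
    bad_num = df.index[~np.isfinite(intens)]
    if len(bad_num):
        raise ValueError(f"{path}: non-numeric intensity at rows {list(bad_num[:10])}")

    probes = [
        Probe(str(i), s, float(y))
        for i, s, y in zip(df["id"], df["sequence"], intens)
    ]
    return ProbeSet(probes, design_id=str(path))


def write_probe_table(probes: ProbeSet, path) -> None:
    probes.to_frame()[["id", "sequence", "intensity"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def _looks_like_row(row, probe_length: int) -> bool:
    try:
        seq = str(row.iloc[1])
        float(row.iloc[2])
    except (ValueError, TypeError, IndexError):
        return False
    return len(seq) == probe_length and set(seq.upper()) <= _VALID


def normalize_intensities(probes: ProbeSet) -> ProbeSet:
    """Robust z-score of log intensities: (log y - median) / (1.4826 * MAD).

    The transform is strictly monotone, so normalized ranks equal raw
    ranks.  Non-positive intensities are shifted so the minimum maps to 1
    before the log (with a logged warning); a zero MAD falls back to the
    standard deviation, floored to keep the all-equal case at 0.
    """
    if len(probes) < 2:
        raise ValueError("need at least 2 probes to normalize")
    y = probes.intensities
    if (y <= 0).any():
        logger.warning(
            "%d non-positive intensities; shifting by %g before log",
            int((y <= 0).sum()),
            1.0 - y.min(),
        )
        y = y - y.min() + 1.0
    ly = np.log(y)
    med = np.median(ly)
    mad = np.median(np.abs(ly - med))
    scale = 1.4826 * mad
    if scale < 1e-12:
        scale = max(float(np.std(ly)), 1e-12)
    z = (ly - med) / scale
    return ProbeSet(list(probes.probes), design_id=probes.design_id, normalized=z)


def sample_training_probes(
    probes: ProbeSet,
    z_threshold: float = 4.0,
    min_positives: int = 500,
) -> TrainingSample:
    """Sample an informative training set from the intensity-distribution tails.

    Positives are the probes with normalized intensity >= ``z_threshold``;
    if fewer than ``min_positives`` qualify, the top ``min_positives``
    probes by normalized intensity are taken instead.  The same number of
    negatives comes from the other end of the distribution.  Ties are broken
    by probe id for reproducibility.
    """
    if probes.normalized is None:
        raise ValueError("normalize_intensities must be applied first")
    z = probes.normalized
    ids = np.array([p.id for p in probes.probes])
    # descending by z, ascending by id on ties
    order_desc = np.lexsort((ids, -z))
    n_above = int((z >= z_threshold).sum())
    n_pos = n_above if n_above >= min_positives else min_positives
    if 2 * n_pos > len(probes):
        raise ValueError(
            f"degenerate sampling: 2*{n_pos} positives exceed {len(probes)} probes"
        )
    pos_idx = order_desc[:n_pos]
    neg_idx = order_desc[::-1][:n_pos]
    labels = np.r_[z[pos_idx], z[neg_idx]]
    return TrainingSample(
        positives=[probes.probes[i] for i in pos_idx],
        negatives=[probes.probes[i] for i in neg_idx],
        labels=labels,
        design_id=probes.design_id,
    )


def select_features(
    sample: TrainingSample,
    space: FeatureSpace,
    params: DiMismatchParams,
    max_features: int = 4000,
) -> FeatureSpace:
    """Keep the k-mers most over-represented in either probe class.

    For each feature the mean di-mismatch feature value is computed over
    positive and over negative probes; features are ranked by
    |mean_pos - mean_neg| descending (ties lexicographic) and the top
    ``max_features`` kept.
    """
    if len(space) == 0:
        raise ValueError("empty feature space")
    pos_mat = feature_matrix([p.sequence for p in sample.positives], space, params)
    neg_mat = feature_matrix([p.sequence for p in sample.negatives], space, params)
    diff = np.abs(pos_mat.mean(axis=0) - neg_mat.mean(axis=0))
    feats = np.array(space.features)
    order = np.lexsort((feats, -diff))
    kept = feats[order[:max_features]]
    return FeatureSpace(tuple(sorted(kept)), space.k)
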