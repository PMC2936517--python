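"""Comparator scorers: 8-mer E-scores (E-max), Z-max, and PSSM log-odds.

E-scores are rank-based enrichment statistics for 8-mer patterns over a PBM
probe ranking.  The variant implemented here is the rescaled Mann-Whitney
AUC computed on the full probe ranking: for each contiguous 8-mer (both
strands merged into a canonical form),

    E = AUC(probes containing the 8-mer vs. probes not containing it) - 0.5

so values lie in [-0.5, 0.5], +0.5 meaning the 8-mer occurs only in the
highest-intensity probes.  This is a simpler full-ranking analogue of the
published split-half Wilcoxon statistic; gapped 8-mer patterns are out of
scope.  E-max scores a sequence by the maximum E-score over the 8-mers it
contains; Z-max replaces the E-score by the median training-probe intensity
of each 8-mer.  PSSM scanning is the standard log-odds score against a
background model, maximized over windows and strands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy.stats import rankdata

from .kernel import reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "EScoreTable",
    "PSSM",
    "compute_escores",
    "emax_score",
    "ZMaxTable",
    "zmax_score",
    "pssm_logodds_max",
    "read_pssm",
    "write_pssm",
    "make_motif_pssm",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


def _canonical8(kmer: str) -> Optional[str]:
    if set(kmer) <= set(_BASES):
        return min(kmer, reverse_complement(kmer))
    return None


def _contained_8mers(sequence: str) -> set:
    s = sequence.upper()
    out = set()
    for i in range(len(s) - 7):
        c = _canonical8(s[i : i + 8])
        if c is not None:
            out.add(c)
    return out


@dataclass
class EScoreTable:
    """Canonical 8-mer -> enrichment score in [-0.5, 0.5]."""

    scores: Dict[str, float]
    source_design: str = ""

    def __post_init__(self) -> None:
        vals = np.array(list(self.scores.values()), dtype=float)
        if len(vals) and (vals.min() < -0.5 - 1e-9 or vals.max() > 0.5 + 1e-9):
            raise ValueError("E-scores must lie in [-0.5, 0.5]")

    def __getitem__(self, kmer: str) -> float:
        return self.scores[min(kmer, reverse_complement(kmer))]

    def __len__(self) -> int:
        return len(self.scores)


def compute_escores(probes, min_support: int = 20) -> EScoreTable:
    """Rank-sum enrichment score for every contiguous 8-mer.

    Probes are ranked by intensity (normalized if present, else raw -- the
    two give identical ranks); for each canonical 8-mer present in at least
    ``min_support`` probes the score is the Mann-Whitney AUC of
    containing-vs-non-containing probes minus 0.5.
    """
    if len(probes) == 0:
        raise ValueError("empty probe set")
    y = probes.normalized if probes.normalized is not None else probes.intensities
    ranks = rankdata(y)  # average ranks on ties
    n = len(ranks)

    containing: Dict[str, list] = {}
    for i, seq in enumerate(probes.sequences):
        for c in _contained_8mers(seq):
            containing.setdefault(c, []).append(i)

    scores: Dict[str, float] = {}
    for kmer, idx in containing.items():
        n1 = len(idx)
        n0 = n - n1
        if n1 < min_support or n0 == 0:
            continue
        r1 = ranks[idx].sum()
        auc = (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)
        scores[kmer] = auc - 0.5
    return EScoreTable(scores, source_design=getattr(probes, "design_id", ""))


def emax_score(sequence: str, table: EScoreTable, threshold: Optional[float] = None) -> float:
    """Maximum E-score over the 8-mers a sequence contains (both strands).

    With ``threshold`` set (the reference protocol used 0.35), 8-mers
    scoring below it are ignored and a sequence containing none returns the
    -0.5 sentinel; the sentinel is also returned when no contained 8-mer is
    in the table.
    """
    best = -0.5
    found = False
    for c in _contained_8mers(sequence):
        s = table.scores.get(c)
        if s is None or (threshold is not None and s < threshold):
            continue
        found = True
        if s > best:
            best = s
    return best if found else -0.5


class ZMaxTable:
    """Canonical 8-mer -> median intensity of the training probes containing
    it.  Built once from a probe set and reused across query sequences."""

    def __init__(self, probes):
        y = probes.intensities
        containing: Dict[str, list] = {}
        for i, seq in enumerate(probes.sequences):
            for c in _contained_8mers(seq):
                containing.setdefault(c, []).append(i)
        self.medians = {k: float(np.median(y[idx])) for k, idx in containing.items()}

    def score(self, sequence: str) -> float:
        """Max over contained 8-mers of the 8-mer's median training
        intensity; 8-mers unseen in training are ignored.  Returns -inf if
        no contained 8-mer was seen."""
        vals = [
            self.medians[c]
            for c in _contained_8mers(sequence)
            if c in self.medians
        ]
        return max(vals) if vals else float("-inf")


def zmax_score(sequence: str, probes) -> float:
    """Convenience one-shot Z-max (builds the median table; prefer
    :class:`ZMaxTable` when scoring many sequences)."""
    return ZMaxTable(probes).score(sequence)


# ---------------------------------------------------------------------------
# PSSMs
# ---------------------------------------------------------------------------


@dataclass
class PSSM:
    """Position-specific scoring matrix: per-position base probabilities.

    ``matrix`` has shape (width, 4) in A, C, G, T order; rows sum to 1.
    Log-odds are taken against ``background`` with ``pseudocount`` already
    folded into the probabilities at construction time (scoring adds a
    small epsilon only to guard log(0)).
    """

    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.0
    name: str = "motif"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.background = np.asarray(self.background, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PSSM matrix must have shape (width, 4)")
        if self.matrix.shape[0] == 0:
            raise ValueError("PSSM width must be positive")
        rowsums = self.matrix.sum(axis=1)
        if np.abs(rowsums - 1).max() > 1e-6:
            logger.warning("PSSM rows off by up to %g; renormalizing", np.abs(rowsums - 1).max())
        self.matrix = self.matrix / rowsums[:, None]
        if abs(self.background.sum() - 1) > 1e-6:
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))

    def log_odds(self, eps: float = 1e-9) -> np.ndarray:
        return np.log((self.matrix + eps) / (self.background[None, :] + eps))

    def reverse_complement(self) -> "PSSM":
        return PSSM(
            self.matrix[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            pseudocount=self.pseudocount,
            name=self.name + "_rc",
        )


def _encode_acgt(sequence: str) -> np.ndarray:
    s = sequence.upper()
    out = np.full(len(s), -1, dtype=np.int64)
    for i, ch in enumerate(s):
        out[i] = _BASE_INDEX.get(ch, -1)
    return out


def pssm_logodds_max(pssm: PSSM, sequence: str) -> float:
    """Maximum log-odds score of a PSSM over all windows and both strands.

    Windows containing non-ACGT characters are skipped; a sequence shorter
    than the PSSM width is an error.
    """
    w = pssm.width
    codes = _encode_acgt(sequence)
    if len(codes) < w:
        raise ValueError(f"sequence length {len(codes)} < PSSM width {w}")
    lo_f = pssm.log_odds()
    lo_r = pssm.reverse_complement().log_odds()
    wins = np.lib.stride_tricks.sliding_window_view(codes, w)
    valid = (wins >= 0).all(axis=1)
    if not valid.any():
        raise ValueError("no ACGT-only window of PSSM width in sequence")
    v = wins[valid]
    pos = np.arange(w)
    sf = lo_f[pos, v].sum(axis=1)
    sr = lo_r[pos, v].sum(axis=1)
    return float(np.maximum(sf, sr).max())


def make_motif_pssm(consensus: str, alpha: float = 0.85, name: str = "motif") -> PSSM:
    """Sharp PSSM around a consensus: probability ``alpha`` on the consensus
    base at each position, the remainder spread uniformly."""
    mat = np.full((len(consensus), 4), (1 - alpha) / 3.0)
    for i, b in enumerate(consensus.upper()):
        mat[i, _BASE_INDEX[b]] = alpha
    return PSSM(mat, name=name)


# -- minimal MEME format ----------------------------------------------------


def write_pssm(pssm: PSSM, path, nsites: int = 20) -> None:
    """Write a PSSM in minimal MEME motif format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{b} {p:.6f}" for b, p in zip(_BASES, pssm.background)) + "\n\n"
        )
        fh.write(f"MOTIF {pssm.name}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {pssm.width} nsites= {nsites} E= 0\n"
        )
        for row in pssm.matrix:
            fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")


def read_pssm(path) -> PSSM:
    """Read the first motif from a minimal MEME file."""
    background = np.full(4, 0.25)
    name = "motif"
    rows: list = []
    width = None
    with open(path) as fh:
        lines = iter(fh.readlines())
    in_matrix = False
    for line in lines:
        s = line.strip()
        if s.startswith("Background letter frequencies"):
            continue
        toks = s.split()
        if toks and toks[0] == "A" and len(toks) >= 8 and toks[2] == "C":
            background = np.array([float(toks[i]) for i in (1, 3, 5, 7)])
        elif s.startswith("MOTIF"):
            parts = s.split()
            if len(parts) > 1:
                name = parts[1]
        elif s.startswith("letter-probability matrix"):
            in_matrix = True
            kv = s.split(":", 1)[1].split()
            for key, val in zip(kv[::2], kv[1::2]):
                if key == "w=":
                    width = int(val)
        elif in_matrix and s:
            try:
                vals = [float(t) for t in toks]
            except ValueError:
                in_matrix = False
                continue
            if len(vals) != 4:
                raise ValueError(f"{path}: malformed matrix row {s!r}")
            rows.append(vals)
            if width is not None and len(rows) == width:
                in_matrix = False
    if not rows:
        raise ValueError(f"{path}: no letter-probability matrix found")
    if width is not None and len(rows) != width:
        raise ValueError(f"{path}: expected {width} matrix rows, found {len(rows)}")
    return PSSM(np.array(rows), background=background, name=name)
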