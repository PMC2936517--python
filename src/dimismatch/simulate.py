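"""Seeded synthetic PBM and ChIP-like data with planted motif structure.

Real PBM and ChIP-seq compendia cannot ship with the package, so every
stage of the pipeline is exercised against generated data with known
ground truth.  The generators emulate the *shape* of the real experiments:

* Two disjoint PBM "array designs" of uniform-random 36-mers.  A small
  fraction of probes receives a binding site sampled from a planted PSSM
  (random offset and strand); log-intensity is an additive site-energy
  model -- the sum over probe windows of a softplus-transformed PSSM
  log-odds, scaled by an effect size -- plus Gaussian noise.  As on real
  arrays, only a few hundred probes carry appreciable signal.

* A ChIP-like experiment: a random genome with non-overlapping peak
  summits; each positive 60-bp window carries a primary-motif site and,
  optionally, a cofactor site instead of (or beside) the primary one;
  flank negatives are kept motif-free.  This mirrors the situation where a
  TF occupies part of its peaks indirectly through a partner.

Uniform random probes stand in for the de Bruijn designs of real arrays
(complete 10-mer coverage is not needed to test recovery); microarray
noise physics is not modeled.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .baselines import PSSM, make_motif_pssm
from .chip import LabeledWindowSet, Peak, PeakSet
from .kernel import reverse_complement
from .pbm import Probe, ProbeSet

__all__ = [
    "SyntheticSpec",
    "SimulatedPBM",
    "SimulatedChIP",
    "simulate_pbm_experiment",
    "simulate_chip_experiment",
    "default_primary_pssm",
    "default_cofactor_pssm",
    "site_energies",
]

_BASES = np.array(list("ACGT"))

#: default planted motif consensi (11 nt: comparable to the k=13 feature
#: length; sharpness alpha=0.85 leaves a realistic gradient of site quality)
PRIMARY_CONSENSUS = "TGACGTCATTA"
COFACTOR_CONSENSUS = "CCATTGTTGAC"


def default_primary_pssm(alpha: float = 0.85) -> PSSM:
    return make_motif_pssm(PRIMARY_CONSENSUS, alpha=alpha, name="primary")


def default_cofactor_pssm(alpha: float = 0.85) -> PSSM:
    return make_motif_pssm(COFACTOR_CONSENSUS, alpha=alpha, name="cofactor")


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic experiments.

    plant_fraction defaults to 0.01: at the default 40,000 probes per
    design this plants ~400 bound probes, matching the "few hundred bound
    probes of ~44K" regime of real arrays.  noise_sd is the s.d. of the
    Gaussian noise on log intensity; effect sizes scale the planted
    PSSM's softplus energy.
    """

    seed: int = 0
    n_probes: int = 40_000
    probe_length: int = 36
    planted_pssms: Optional[List[Tuple[PSSM, float]]] = None
    noise_sd: float = 0.5
    plant_fraction: float = 0.01
    genome_length: int = 700_000
    n_peaks: int = 1000
    cofactor: Optional[PSSM] = None
    cofactor_fraction: float = 0.0
    cofactor_replaces: bool = True

    def __post_init__(self) -> None:
        if self.planted_pssms is None:
            self.planted_pssms = [(default_primary_pssm(), 1.0)]
        if not 0 < self.plant_fraction < 1:
            raise ValueError("plant_fraction must lie in (0, 1)")
        if any(e < 0 for _, e in self.planted_pssms):
            raise ValueError("effect sizes must be >= 0")
        for pssm, _ in self.planted_pssms:
            if pssm.width > self.probe_length:
                raise ValueError(
                    f"planted motif width {pssm.width} exceeds probe length {self.probe_length}"
                )


@dataclass
class SimulatedPBM:
    """Two disjoint simulated array designs plus the planting ground truth
    (indices of probes that received a site, per design)."""

    design_a: ProbeSet
    design_b: ProbeSet
    planted_a: np.ndarray
    planted_b: np.ndarray

    def __iter__(self):
        return iter((self.design_a, self.design_b))


@dataclass
class SimulatedChIP:
    """Simulated genome, ranked peaks, labeled windows, and the implanted
    sites: list of (summit, motif name, genome offset, site sequence)."""

    genome: Dict[str, str]
    peaks: PeakSet
    windows: LabeledWindowSet
    sites: list = field(default_factory=list)


def _random_seqs(rng: np.random.Generator, n: int, length: int) -> List[str]:
    mat = rng.integers(0, 4, size=(n, length))
    return ["".join(_BASES[row]) for row in mat]


def _sample_site(rng: np.random.Generator, pssm: PSSM) -> str:
    out = []
    for row in pssm.matrix:
        out.append(_BASES[rng.choice(4, p=row)])
    return "".join(out)


def _encode(seqs: List[str]) -> np.ndarray:
    lut = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)
    return lut[arr]


def site_energies(sequences: List[str], pssm: PSSM) -> np.ndarray:
    """Additive softplus site energy of each sequence under a PSSM: the sum
    over all windows and both strands of log(1 + exp(log-odds))."""
    codes = _encode(sequences)
    w = pssm.width
    lo = np.stack([pssm.log_odds(), pssm.reverse_complement().log_odds()])
    wins = np.lib.stride_tricks.sliding_window_view(codes, w, axis=1)  # (n, W, w)
    pos = np.arange(w)
    out = np.zeros(len(sequences))
    for strand in range(2):
        scores = lo[strand][pos, wins].sum(axis=2)  # (n, W)
        out += np.logaddexp(0.0, scores).sum(axis=1)
    return out


def _make_design(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    design_id: str,
    taken: set,
) -> Tuple[ProbeSet, np.ndarray]:
    n, L = spec.n_probes, spec.probe_length
    seqs: List[str] = []
    while len(seqs) < n:
        for s in _random_seqs(rng, n - len(seqs), L):
            if s not in taken:
                taken.add(s)
                seqs.append(s)

    n_plant = int(round(spec.plant_fraction * n))
    planted_idx = np.sort(rng.choice(n, size=n_plant, replace=False))
    which_pssm = rng.integers(0, len(spec.planted_pssms), size=n_plant)
    for j, i in enumerate(planted_idx):
        pssm, _ = spec.planted_pssms[which_pssm[j]]
        site = _sample_site(rng, pssm)
        if rng.integers(2):
            site = reverse_complement(site)
        off = int(rng.integers(0, L - pssm.width + 1))
        s = seqs[i]
        taken.discard(s)
        s = s[:off] + site + s[off + pssm.width :]
        seqs[i] = s
        taken.add(s)

    log_y = rng.normal(0.0, spec.noise_sd, size=n)
    for pssm, effect in spec.planted_pssms:
        if effect > 0:
            log_y += effect * site_energies(seqs, pssm)
    probes = [
        Probe(f"{design_id}_{i:06d}", seqs[i], float(np.exp(log_y[i]))) for i in range(n)
    ]
    return ProbeSet(probes, design_id=design_id), planted_idx


def simulate_pbm_experiment(spec: SyntheticSpec) -> SimulatedPBM:
    """Generate two disjoint array designs under the planted-PSSM intensity
    model.  Deterministic given the spec's seed; probe sequences are unique
    within and across designs."""
    rng = np.random.default_rng(spec.seed)
    taken: set = set()
    design_a, planted_a = _make_design(rng, spec, "A", taken)
    design_b, planted_b = _make_design(rng, spec, "B", taken)
    assert not (set(design_a.sequences) & set(design_b.sequences))
    return SimulatedPBM(design_a, design_b, planted_a, planted_b)


def _contains_motif(seq: str, consensi: List[str]) -> bool:
    rc = reverse_complement(seq)
    return any(c in seq or c in rc for c in consensi)


def simulate_chip_experiment(spec: SyntheticSpec) -> SimulatedChIP:
    """Generate a random genome with planted peaks and the matching
    peak/flank window set.

    Summits are non-overlapping (pairwise distance > 600 bp) and placed so
    both the positive window [summit-30, summit+30) and the negative
    window centered 300 bp to the left fit on the chromosome.  Every
    positive carries a primary-motif site; a ``cofactor_fraction`` of
    positives carries the cofactor site instead of (``cofactor_replaces``)
    or beside the primary.  Negative windows are re-drawn if they contain
    either motif consensus exactly.
    """
    n = spec.n_peaks
    L = spec.genome_length
    if L <= 600 * n:
        raise ValueError(f"genome_length {L} must exceed 600 * n_peaks = {600 * n}")
    slot = L // n
    rng = np.random.default_rng(spec.seed + 1)
    genome = list("".join(_random_seqs(rng, 1, L)))

    primary, _ = spec.planted_pssms[0]
    consensi = [primary.consensus] + ([spec.cofactor.consensus] if spec.cofactor else [])

    jitter_max = max(slot - 601, 0)
    summits = []
    for i in range(n):
        j = int(rng.integers(0, jitter_max + 1)) if jitter_max else 0
        summits.append(i * slot + 330 + j)

    def _match_positions(window: str, cons: str) -> set:
        """(offset, strand) of every exact consensus occurrence."""
        rc = reverse_complement(cons)
        out = set()
        for off in range(len(window) - len(cons) + 1):
            if window[off : off + len(cons)] == cons:
                out.add((off, "+"))
            if window[off : off + len(cons)] == rc:
                out.add((off, "-"))
        return out

    def _implant_clean(rng, genome, win_start, plan, consensi) -> None:
        """Write the planned sites into the 60-bp window, redrawing the
        background until the only consensus occurrences are the implanted
        spans (chance hits would corrupt the ground truth)."""
        for _ in range(200):
            genome[win_start : win_start + 60] = list(_random_seqs(rng, 1, 60)[0])
            for _, site, start in plan:
                genome[start : start + len(site)] = list(site)
            window = "".join(genome[win_start : win_start + 60])
            expected = {cons: set() for cons in consensi}
            for _, site, start in plan:
                off = start - win_start
                for cons in consensi:
                    if site == cons:
                        expected[cons].add((off, "+"))
                    if site == reverse_complement(cons):
                        expected[cons].add((off, "-"))
            if all(_match_positions(window, cons) == expected[cons] for cons in consensi):
                return
        raise RuntimeError("could not implant sites without chance consensus hits")

    sites: list = []
    has_cofactor = (
        rng.random(n) < spec.cofactor_fraction
        if spec.cofactor is not None
        else np.zeros(n, dtype=bool)
    )
    for i, s in enumerate(summits):
        if has_cofactor[i] and spec.cofactor_replaces:
            plan = [(spec.cofactor.name, _sample_site(rng, spec.cofactor), s - spec.cofactor.width // 2)]
        elif has_cofactor[i]:
            plan = [
                (primary.name, _sample_site(rng, primary), s - 26),
                (spec.cofactor.name, _sample_site(rng, spec.cofactor), s + 6),
            ]
        else:
            plan = [(primary.name, _sample_site(rng, primary), s - primary.width // 2)]
        _implant_clean(rng, genome, s - 30, plan, consensi)
        for name, site, start in plan:
            sites.append((s, name, start, site))

    # keep flank negatives motif-free
    for s in summits:
        start = s - 330
        while _contains_motif("".join(genome[start : start + 60]), consensi):
            genome[start : start + 60] = list(_random_seqs(rng, 1, 60)[0])

    genome_str = "".join(genome)
    peaks = PeakSet(
        [Peak("chrSim", s, float(n - i)) for i, s in enumerate(summits)], ranked=True
    )
    seqs, labels, origins = [], [], []
    for s in summits:
        seqs.append(genome_str[s - 30 : s + 30])
        labels.append(1)
        origins.append(f"chrSim:{s - 30}-{s + 30}")
        seqs.append(genome_str[s - 330 : s - 270])
        labels.append(-1)
        origins.append(f"chrSim:{s - 330}-{s - 270}")
    windows = LabeledWindowSet(seqs, np.array(labels), origins)
    return SimulatedChIP({"chrSim": genome_str}, peaks, windows, sites)
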