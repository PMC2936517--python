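# Methods

## The di-mismatch kernel

A k-mer is represented by its k−1 overlapping dinucleotides.  The
di-mismatch score between k-mers `a` and `b` counts positions where the
dinucleotides agree, zeroed when the count falls below
`min_matching_dinucs = (k−1) − m`; `m` is therefore the maximum tolerated
number of *mismatching* dinucleotides.  Working in the dinucleotide
alphabet makes the mismatch neighborhood of a k-mer much smaller than in
the plain mismatch kernel, and it penalizes scattered substitutions more
than consecutive ones: j consecutive substitutions disrupt j+1
dinucleotides, any other interior placement disrupts more (exhaustively
verified for k = 13, j ≤ 4 in the test suite).  End positions disrupt only
one dinucleotide, which is why the consecutiveness guarantee is stated for
interior placements.

A sequence maps to the feature vector `Phi(x)_f = Σ_windows d(s, f)` over
a dictionary of k-mer features.  Two conventions are deliberate choices
where the procedure leaves room:

* **Window aggregation is summation**, not maximum, matching the additive
  form of the feature definition.
* **Double-strandedness**: features are stored in canonical form (the
  lexicographically smaller of a k-mer and its reverse complement) and a
  window is scored against a feature as `max(d(w, f), d(w, rc(f)))`.
  This makes every sequence score invariant under reverse complementation
  of the sequence, which is asserted on random inputs.  `strand_mode =
  "single"` disables both behaviors (useful for unit arithmetic).
* **Ambiguous bases**: any window containing a non-ACGT character scores
  0 against every feature.

Feature order is lexicographic and all accumulation happens in fixed
iteration order, so every quantity in the package is bit-reproducible.

### Implementation

The matching-dinucleotide count between two k-mers equals the inner
product of their one-hot dinucleotide encodings, so batched
window-vs-feature counts are computed either by a cache-blocked numba loop
(default when numba is importable; the per-feature code table fits in L2)
or by a sparse-one-hot × dense matrix product.  Counts are integers ≤ k−1
and exact in float32.  A trained linear model scans sequence in linear
time through a memoized per-k-mer contribution table
(`table[u] = Σ_f w_f · d(u, f)`): a window's score is one lookup, a
region profile is a sliding window-sum over per-position contributions.
The naive double-loop implementations live only in the tests, as
independent oracles.

## PBM training protocol

Probe intensities are normalized as robust z-scores of log intensity
((log y − median) / (1.4826·MAD); MAD falling back to the standard
deviation when zero).  The transform is monotone, so ranks are preserved;
non-positive intensities are shifted to a minimum of 1 before the log with
a warning.  The positive-tail threshold is z ≥ 4.0 by default (the
protocol's numeric cutoff is configurable); if fewer than 500 probes
qualify, the top 500 by normalized intensity are taken, and the same
number of negatives is drawn from the bottom of the distribution.
Negative sampling uses the bottom tail only.

Features are the k-mers occurring in the training probes, ranked by the
absolute difference of their class-mean di-mismatch feature values and
capped at 4000 (ties broken lexicographically).  The SVR uses a linear
kernel on the explicit features with ε = 0.1 fixed.  C is not pinned by
the protocol; the default is 1.0.  Because C controls how strongly the
model fits design-specific probe composition, `TrainingConfig.C_grid`
optionally selects C by 5-fold cross-validated Spearman correlation on
the training sample (deterministic folds, ties resolved toward the more
regularized value); the cross-design evaluation protocol uses grid
(0.01, 0.1, 1.0).  Feature selection for this internal grid search is
done once on the full training sample — acceptable for hyperparameter
selection since no test-design information is involved.

Model quality is measured as "detection of the top n": the size of the
intersection between the top-n probes by prediction and by measurement
(ties broken by id), with n = 100; cross-design evaluation trains on one
array design and detects on the disjoint other, optionally averaging the
two directions.  Under random predictions the expectation is
hypergeometric, n²/N.

## ChIP training protocol

From the top 1000 peaks (inputs; peak calling is out of scope), each
positive is the 60-bp window centered on the summit and each negative the
60-bp window whose center lies 300 bp to the left — flanking sequence
from the same locus.  Peaks whose windows leave the chromosome or exceed
50% ambiguous bases are skipped (an addition of this implementation; the
source protocol is silent), keeping the set balanced.  The SVM uses the
fixed (k, m) = (13, 5) kernel and C = 1.0.  Cross-validated AUC uses
stratified 10-fold CV; the k-mer dictionary is built once from all
windows (an unsupervised step), while the class-mean feature selection is
re-run inside each training fold so no label information crosses folds.

## Baselines

* **E-scores**: for each contiguous canonical 8-mer present in ≥ 20
  probes, the Mann–Whitney AUC of containing- vs non-containing probes on
  the full intensity ranking, minus 0.5 — a full-ranking analogue of the
  published split-half Wilcoxon statistic, bounded in [−0.5, 0.5].
  Gapped patterns are out of scope.  E-max scores a sequence by its best
  contained 8-mer; with the optional threshold (0.35 in the reference
  protocol) sequences with no qualifying 8-mer return the −0.5 sentinel.
* **Z-max**: per-8-mer median training-probe intensity, maximized over
  the 8-mers a sequence contains.
* **PSSM log-odds**: maximum over windows and strands of
  Σ log(p/background), with a small epsilon guarding log 0.  Minimal MEME
  format I/O is provided.

## Feature analysis

Each model k-mer is embedded as the vector of its optimal ungapped
alignment scores (matching positions, max over offsets and strands)
against the positive training sequences; k-mers supported by the same
probes land on nearby vectors.  2-means clustering (Euclidean distance on
the raw vectors, 10 seeded restarts) splits the features into two groups;
per cluster the top 500 k-mers by model weight are kept and the kept
union is projected to 2D by PCA.  Cluster ids are relabeled
deterministically (cluster 1 holds the largest weight).  The cluster
representative is the member in the top weight quartile closest to the
cluster centroid; it is expanded to a PSSM by stacking the best-aligned
k-length windows (strand-resolved) of the 50 best-aligned positive
sequences, with a 0.5 pseudocount.  Weights enter only the filtering and
representative selection, not the clustering distance.  Retraining on one
cluster's k-mers, then comparing AUCs on an occupancy-labeled window set,
attributes in vivo signal to one motif cluster.

## Synthetic data

The generators provide ground truth for every pipeline stage; they
emulate the shape of the real experiments, not their physics.

* **PBM**: two disjoint designs of uniform-random unique 36-mers (real
  arrays use de Bruijn designs with complete 10-mer coverage — not needed
  for recovery testing).  A fraction of probes receives a site sampled
  from a planted PSSM at random offset/strand.  Log intensity is
  `Σ_p effect_p · E_p(x) + N(0, noise_sd)` where `E_p` is the sum over
  windows and strands of softplus(PSSM log-odds) — bright probes are
  those with good sites, and site quality varies realistically because
  sites are sampled from the PSSM (default sharpness α = 0.85).
  Defaults: 40,000 probes, plant fraction 0.01 (≈ 400 bound probes,
  matching the "few hundred bound of ~44K" regime of real arrays),
  effect 1.0, noise s.d. 0.5 on the log scale.
* **ChIP**: a random genome with non-overlapping summits (pairwise
  distance > 600 bp, placed so both windows fit the chromosome).  Every
  positive window carries a primary-motif site; optionally a fraction of
  positives carries a cofactor site instead of (or beside) the primary —
  the indirect-binding scenario.  Window backgrounds and flank negatives
  are redrawn until free of chance exact-consensus occurrences, so the
  implanted-site record is the exact ground truth.

What passing the recovery tests shows: the pipeline can learn a planted
sequence-to-intensity mapping and recover planted motif structure under
realistic sparsity.  What it does not show: robustness to array spatial
artifacts, replicate noise, probe-composition biases, chromatin effects,
or motif families outside the planted-PSSM form.

## Problem sizes in the test suite

Recovery runs are scaled to keep the suite quick while leaving the
qualitative regime intact: 4,000 probes/design with 120 planted
(cross-design detection; the bound-probe *count*, not fraction, is the
invariant of real arrays), ≤ 1,000 selected features, 250 peaks for the
ChIP classifier, 3,000 probes with two motifs (75 planted each) for the
feature analysis.  Statistical nulls (permutation AUC, hypergeometric
detection) use 10–1,000 replicates as noted in each test.

## Known limitations

* The E-score variant is a full-ranking AUC statistic, not the exact
  split-half array statistic of the published tables.
* Normalization is a single robust-z pipeline; array-specific spatial
  corrections are out of scope.
* The SVM/SVR is strictly linear in di-mismatch feature space; no RBF or
  multi-TF extensions.
* Gapped k-mer features and gapped 8-mer patterns are not implemented.
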