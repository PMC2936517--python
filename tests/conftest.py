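"""Shared fixtures: small deterministic inputs plus session-scoped synthetic
experiments reused across the unit and recovery suites."""

import numpy as np
import pytest

from dimismatch import (
    DiMismatchParams,
    TrainingConfig,
    build_feature_space,
    feature_matrix,
    normalize_intensities,
    sample_training_probes,
    train_regressor,
)
from dimismatch.simulate import (
    SyntheticSpec,
    default_cofactor_pssm,
    default_primary_pssm,
    simulate_chip_experiment,
    simulate_pbm_experiment,
)

BASES = np.array(list("ACGT"))


def random_seq(rng, length):
    return "".join(rng.choice(BASES, length))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def chip_sim():
    """Planted-motif ChIP-like experiment: 250 peaks, 500 balanced 60-nt
    windows."""
    spec = SyntheticSpec(seed=2, n_peaks=250, genome_length=250 * 700)
    return simulate_chip_experiment(spec)


@pytest.fixture(scope="session")
def chip_design_matrix(chip_sim):
    """Precomputed di-mismatch feature matrix of the ChIP windows over the
    full k-mer dictionary (shared by CV and permutation tests)."""
    cfg = TrainingConfig(mode="classification", max_features=1000)
    seqs = list(chip_sim.windows.sequences)
    space = build_feature_space(seqs, cfg.params)
    X = feature_matrix(seqs, space, cfg.params)
    return X, chip_sim.windows.class_labels, np.array(space.features), cfg


@pytest.fixture(scope="session")
def two_motif_fit():
    """PBM experiment with two planted motifs (primary + cofactor) and the
    SVR fitted to one design: the substrate of the feature-analysis tests."""
    spec = SyntheticSpec(
        seed=11,
        n_probes=3000,
        plant_fraction=0.05,
        planted_pssms=[(default_primary_pssm(), 1.0), (default_cofactor_pssm(), 1.0)],
    )
    sim = simulate_pbm_experiment(spec)
    probes = normalize_intensities(sim.design_a)
    sample = sample_training_probes(probes)
    cfg = TrainingConfig(max_features=1000, C_grid=(0.01, 0.1, 1.0))
    model = train_regressor(sample, cfg)
    return {"sim": sim, "sample": sample, "config": cfg, "model": model}
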