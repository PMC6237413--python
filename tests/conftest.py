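import numpy as np
import pytest

from rddsim import (
    Individual,
    MixingModel,
    MomentSpec,
    RecruiterTypeTable,
    RunConfig,
    bb_from_moments,
    point_mass,
    simulate_tree,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def seed_individual():
    return Individual(
        id="s0", recruiter_id=None, wave=0, sex="F", age_group="a2", education="B"
    )


def homogeneous_config(mu, sigma2, p, cap=1000, c=4, mixing=None):
    """Single-type run configuration from (mean, variance, acceptance)."""
    inv = point_mass(int(round(mu)), c) if sigma2 == 0 else bb_from_moments(
        MomentSpec(mu, sigma2), c
    )
    return RunConfig(
        types=RecruiterTypeTable.homogeneous(inv, p),
        mixing=mixing or MixingModel.random(),
        cap=cap,
    )


def survival_frequency(mu, sigma2, p, runs, master_seed, cap=1000):
    """Fraction of single-seed runs whose tree reaches the cap."""
    cfg = homogeneous_config(mu, sigma2, p, cap=cap)
    seed = Individual(
        id="s0", recruiter_id=None, wave=0, sex="F", age_group="a2", education="B"
    )
    hits = 0
    for i in range(runs):
        tree_rng = np.random.default_rng(
            np.random.SeedSequence(master_seed, spawn_key=(i, 1))
        )
        hits += simulate_tree(seed, cfg, tree_rng).size >= cap
    return hits / runs
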