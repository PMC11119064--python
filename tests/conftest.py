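"""Shared fixtures: small synthetic cohorts and train/test splits."""

import numpy as np
import pytest
from hypothesis import settings

from fcnets.synthetic import SimSpec, generate_cohort, worked_example_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def worked_cohort():
    """The canonical fixture cohort: N=20, two balanced classes of 40."""
    return worked_example_cohort()


def strong_effect_cohort(seed: int):
    """Study-condition cohort: delta-r=0.4 on 5% of edges, N=20, 50+50."""
    spec = SimSpec(n_regions=20, n_per_class=(50, 50), effect_size=0.4,
                   effect_edges=0.05, seed=seed)
    cohort, truth = generate_cohort(spec)
    return cohort, truth


def null_cohort(seed: int, n_per_class=(50, 50), n_regions=20, n_timepoints=150):
    """Cohort with no class signal anywhere (effect_size=0, shared phenotypes)."""
    spec = SimSpec(n_regions=n_regions, n_per_class=n_per_class,
                   n_timepoints=n_timepoints, effect_size=0.0, seed=seed)
    cohort, _ = generate_cohort(spec)
    return cohort


def split_80_20(cohort):
    """First 40 of each class of 50 for training, last 10 for testing."""
    n = cohort.n_subjects // 2
    train = cohort.subset(list(range(40)) + list(range(n, n + 40)))
    test = cohort.subset(list(range(40, n)) + list(range(n + 40, 2 * n)))
    return train, test


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
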