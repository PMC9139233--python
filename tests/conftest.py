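"""Shared fixtures.

The trained-network fixtures are session-scoped because training, while
scaled down (20 cases x 50k events), still takes ~1 min; every test that
needs a fitted F-DNN/L-DNN pair shares the same pair.
"""

from __future__ import annotations

import numpy as np
import pytest

from mrdflow.classifier import NetworkSpec, SplitSpec, train_f_dnn, train_l_dnn
from mrdflow.simulate import CaseConfig, make_cohort, simulate_case

#: Scaled-down study conditions used across the suite: a 20-case development
#: cohort (50k events/case) with the development-cohort MRD-positive share,
#: 60% of positives in the low-count stratum and 30% of high-burden
#: positives carrying the atypical CD20-bright clone.
DEV_COHORT_ARGS = dict(
    n_cases=20,
    mrd_positive_fraction=143 / 202,
    low_count_fraction=0.6,
    seed=5,
    n_events=50_000,
    atypical_high_fraction=0.3,
)

TRAIN_SPEC = NetworkSpec(max_epochs=300)
SPLIT_SPEC = SplitSpec(seed=5)
TRAIN_SEED = 5


@pytest.fixture(scope="session")
def dev_cohort():
    return make_cohort(**DEV_COHORT_ARGS)


@pytest.fixture(scope="session")
def trained_f(dev_cohort):
    model, split = train_f_dnn(dev_cohort, TRAIN_SPEC, SPLIT_SPEC, seed=TRAIN_SEED)
    return model, split


@pytest.fixture(scope="session")
def trained_l(dev_cohort):
    model, split = train_l_dnn(dev_cohort, TRAIN_SPEC, SPLIT_SPEC, seed=TRAIN_SEED)
    return model, split


@pytest.fixture(scope="session")
def eval_cohort():
    """Independent validation-style cohort: 16 cases, 25/34 MRD-positive."""
    return make_cohort(16, 25 / 34, 0.7, seed=77, n_events=50_000)


@pytest.fixture(scope="session")
def small_case():
    """One modest labeled case for I/O and workflow plumbing tests."""
    return simulate_case(
        CaseConfig(n_events=5_000, seed=42, case_id="fixture_case")
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
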