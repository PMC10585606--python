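"""Shared fixtures: small synthetic cohorts at a reduced sampling rate.

Most tests run the generator at 100 samples/s with 15-s trials (1500
samples) so full pipelines stay fast; timing-critical filter tests and
the exact-recovery checks use the native 500 samples/s resolution.
"""

import numpy as np
import pandas as pd
import pytest

import pupilamp as pa

# Reduced-resolution settings: same trial durations, 5x fewer samples.
FAST = dict(rate=100.0, trial_samples=1500, ar1_coef=0.95)


@pytest.fixture(scope="session")
def fast_params() -> pa.GenerativeParams:
    """Small noisy cohort: 3 subjects x 2 runs x 17 trials."""
    return pa.GenerativeParams(n_subjects=3, runs_per_subject=2,
                               rng_seed=7, **FAST)


@pytest.fixture(scope="session")
def fast_cohort(fast_params):
    return pa.generate_cohort(fast_params)


@pytest.fixture(scope="session")
def fast_result(fast_params, fast_cohort):
    return pa.analyze_cohort(pa.cohort_sessions(fast_cohort),
                             fast_params.analysis_config())


@pytest.fixture(scope="session")
def clean_params() -> pa.GenerativeParams:
    """Noise-free, blink-free cohort: the exact-reconstruction regime."""
    return pa.GenerativeParams(n_subjects=3, runs_per_subject=2,
                               noise_sd=0.0, amp_jitter=0.0,
                               blink_rate_per_min=0.0,
                               subject_shape_jitter=0.0, rng_seed=3, **FAST)


@pytest.fixture(scope="session")
def clean_cohort(clean_params):
    return pa.generate_cohort(clean_params)


@pytest.fixture(scope="session")
def clean_result(clean_params, clean_cohort):
    return pa.analyze_cohort(pa.cohort_sessions(clean_cohort),
                             clean_params.analysis_config())


def cohort_truth(cohort) -> pd.DataFrame:
    """Stacked ground-truth table with a subject column."""
    return pd.concat([s.truth.assign(subject=s.subject_id) for s in cohort],
                     ignore_index=True)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
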