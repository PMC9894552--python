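"""Shared fixtures, including the two heavy Monte-Carlo studies.

The expensive repeated-simulation runs are session-scoped so that the
type-I-error, uniformity, unbiasedness and SE-calibration checks all share
one computation.  All seeds are fixed constants.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import parsec as P

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def valid_full():
    return P.validate_parameters(P.FULL_SETTING)


@pytest.fixture(scope="session")
def small_cohort_phenos(valid_full):
    """A small cohort plus phenotypes for structural unit tests."""
    rng = np.random.default_rng(101)
    cohort = P.simulate_families(40, 60, seed=rng)
    phenos = P.simulate_phenotypes(cohort, valid_full, seed=rng)
    return cohort, phenos


@pytest.fixture(scope="session")
def null_calibration_run():
    """200 null-covariance datasets of 500 families x 500 SNPs, fitted with
    jackknife SEs (B=50): the type-I-error / p-uniformity study."""
    return P.run_calibration(
        P.NULL_COV_DIR_SETTING,
        n_families=500,
        n_snps=500,
        n_repeats=200,
        seed=20260924,
        n_blocks=50,
    )


@pytest.fixture(scope="session")
def full_recovery_run():
    """100 datasets of 1000 families x 1000 SNPs under the full 14-parameter
    setting, with jackknife SEs: the unbiasedness / SE-calibration study."""
    return P.run_calibration(
        P.FULL_SETTING,
        n_families=1000,
        n_snps=1000,
        n_repeats=100,
        seed=20260925,
        n_blocks=50,
    )
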