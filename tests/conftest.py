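"""Shared fixtures: simulated samples, cohorts and noise-free configurations."""

from __future__ import annotations

import warnings

import pytest

from suitflux import SimConfig
from suitflux.synthetic_cohort import simulate_blank, simulate_cohort, simulate_sample


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    # normality warnings on 12-sample cohorts are by design and not under test
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*fails normality.*")
        yield


@pytest.fixture(scope="session")
def default_sample():
    """One default-noise sample (duplicate traces + CS wells + ground truth)."""
    return simulate_sample(SimConfig(seed=11), "control", 0)


def noise_free_config(**overrides) -> SimConfig:
    """Degenerate generator: no noise, no dispersion, no group effect spread."""
    base = dict(
        n_per_group=2,
        fcr_cv_pct=0.0,
        duplicate_cv_pct={"control": 0.0, "affected": 0.0},
        abs_scale_cv_pct=0.0,
        cs_cv_pct=0.0,
        cs_duplicate_cv_pct=0.0,
        sigma_o2_uM=0.0,
        cs_sigma_au=0.0,
        seed=1,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def noise_free_sample():
    return simulate_sample(noise_free_config(), "control", 0)


@pytest.fixture(scope="session")
def small_cohort():
    """A 3-per-group default-noise cohort kept in memory."""
    return simulate_cohort(SimConfig(n_per_group=3, seed=21, store_flux_series=False))


@pytest.fixture(scope="session")
def default_blank():
    return simulate_blank(SimConfig(seed=17))
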