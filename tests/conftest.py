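"""Shared fixtures: desk-scale synthetic cohorts built once per session.

The desk-scale cohorts keep the full subject counts (36 AD + 29 HC) but use
short recordings (20 s, enough for the 10 tenfold windows) at 128 Hz, so the
whole feature pipeline runs in seconds while every count the evaluation
protocol prints (650/520/130 segments) matches the full-size study design.
"""

import numpy as np
import pytest

import eeggcn as e


@pytest.fixture(scope="session")
def default_ds():
    """Default-contrast cohort (36 AD / 29 HC), tenfold-windowed dataset."""
    spec = e.CohortSpec(n_ad=36, n_hc=29, duration=20, sampling_rate=128, seed=1)
    return e.build_dataset(e.iter_cohort(spec))


@pytest.fixture(scope="session")
def tiny_ds():
    """Six-subject dataset for fast model-level tests."""
    spec = e.CohortSpec(n_ad=3, n_hc=3, duration=20, sampling_rate=128, seed=3)
    return e.build_dataset(e.iter_cohort(spec))


@pytest.fixture(scope="session")
def pz_planted_ds():
    """Cohort whose only class signal is a strong variance drop at Pz.

    Band profiles and connectivity are identical across classes; the AD group
    has theta/alpha/beta variance suppressed at Pz only. Used by the
    leave-one-channel-out recovery tests.
    """
    flat = {b: 1.0 for b in e.BAND_NAMES}
    spec = e.CohortSpec(
        n_ad=16, n_hc=16, duration=20, sampling_rate=128, seed=7,
        band_variance_profile={"AD": dict(flat), "HC": dict(flat)},
        connectivity_strength={"AD": 0.4, "HC": 0.4},
        subject_variability=0.2,
        channel_variance_profile={
            "AD": {"Pz": {"theta": 0.15, "alpha": 0.1, "beta": 0.15}}
        },
    )
    return e.build_dataset(e.iter_cohort(spec))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
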