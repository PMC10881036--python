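"""Shared fixtures: synthetic cohorts are expensive, so the staging cohort
and its feature table are built once per test session."""

import warnings

import pytest

from flysleep import SessionConfig, generate_cohort
from flysleep import pipeline as P
from flysleep import staging as ST

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", message=".*ConvergenceWarning.*")


@pytest.fixture(scope="session")
def staging_cohort():
    """Six flies, one hour each, with the default stage-profile effects."""
    cfg = SessionConfig(duration=3600.0, sleep_bout_rate=2.5,
                        with_pose=False)
    return generate_cohort(6, cfg, seed=100)


@pytest.fixture(scope="session")
def staging_spectra(staging_cohort):
    return [P.stage_spectra(s) for s in staging_cohort]


@pytest.fixture(scope="session")
def feature_table(staging_cohort, staging_spectra):
    return ST.build_feature_table(staging_spectra,
                                  P.midsleep_durations(staging_cohort))


@pytest.fixture(scope="session")
def short_session():
    """A 45-minute session with guaranteed sleep bouts, LFP and pose."""
    from flysleep import generate_session
    cfg = SessionConfig(duration=2700.0, seed=3, sleep_bout_rate=3.0)
    return generate_session(cfg)
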