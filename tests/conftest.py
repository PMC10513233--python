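import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-size synthetic cohort, shared across tests."""
    from sedbouts.synth import simulate_cohort

    return simulate_cohort(rng_seed=0)


@pytest.fixture(scope="session")
def default_bundle(default_cohort):
    """Full analysis of the shared cohort."""
    import warnings

    from sedbouts.pipeline import analyze_cohort

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return analyze_cohort(default_cohort)


def make_series(counts, start="2024-01-01 08:00", subject_id="s1", group="HC"):
    """Small helper: EpochSeries from a plain list (None/nan = missing)."""
    from sedbouts.actigraphy_io import EpochSeries

    counts = np.array(
        [np.nan if c is None else float(c) for c in counts], dtype=float
    )
    times = pd.date_range(start, periods=len(counts), freq="min")
    return EpochSeries(
        subject_id=subject_id, group=group, start_times=times, counts=counts
    )
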