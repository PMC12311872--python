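import numpy as np
import pandas as pd
import pytest

from circamark.wearable_io import MINUTES_PER_DAY, MinuteSeries

MONDAY = pd.Timestamp("2024-03-04")  # record start used throughout the tests


def make_series(values, kind="heart_rate", missing=None, start=MONDAY) -> MinuteSeries:
    values = np.asarray(values, dtype=float)
    if missing is None:
        missing = np.zeros(len(values), dtype=bool)
    return MinuteSeries(start=start, values=values, missing=np.asarray(missing, bool), kind=kind)


def days_of(profile_fn, n_days: int, kind="heart_rate") -> MinuteSeries:
    """Build an n-day MinuteSeries from a function of absolute minute index."""
    t = np.arange(n_days * MINUTES_PER_DAY, dtype=float)
    return make_series(profile_fn(t), kind=kind)


@pytest.fixture(scope="session")
def default_cohort():
    """Small default-effect cohort shared by cohort-level tests."""
    import circamark as cm
    from circamark.simulate import SimConfig, case_spec, control_spec

    cfg = SimConfig(case=case_spec(n=20), control=control_spec(n=40), seed=11)
    records, manifest = cm.simulate_cohort(cfg)
    return records, manifest


@pytest.fixture(scope="session")
def default_marker_table(default_cohort):
    import circamark as cm

    records, _ = default_cohort
    return cm.marker_table(records)
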