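"""Shared fixtures: small hand-built series and toy training sets."""

from __future__ import annotations

from datetime import datetime

import numpy as np
import pytest

from actisurv import ActigraphySeries, CohortSimParams


def make_series(
    activity,
    interval_s: float = 1.0,
    worn=None,
    patient_id: str = "T001",
    start=datetime(2020, 1, 1),
) -> ActigraphySeries:
    """Build a series whose three channels all equal ``activity``."""
    activity = np.asarray(activity, dtype=np.float32)
    if worn is None:
        worn = np.ones(len(activity), dtype=bool)
    worn = np.asarray(worn, dtype=bool)
    act = activity.copy()
    act[~worn] = np.nan
    return ActigraphySeries(
        patient_id=patient_id,
        start_time=start,
        interval_s=interval_s,
        activity=act,
        angle=act.copy(),
        spin=act.copy(),
        worn=worn,
    )


@pytest.fixture
def fast_sim_params() -> CohortSimParams:
    """Coarse-grained simulator settings that keep unit tests quick."""
    return CohortSimParams(
        n_patients=8,
        sampling_interval_s=600.0,
        stay_days_range=(3, 4),
        seed=7,
    )


@pytest.fixture
def separable_toy():
    """Four constant sequences: two high-activity (stable, label 0) and two
    low-activity (death, label 1), trivially linearly separable."""
    T = 48
    rng = np.random.default_rng(11)
    X = np.empty((4, T, 3), dtype=np.float32)
    labels = np.array([1.0, 1.0, 0.0, 0.0], dtype=np.float32)
    for k in range(4):
        level = 0.3 if labels[k] == 1 else 2.0
        X[k] = level + 0.01 * rng.normal(size=(T, 3))
    lengths = np.full(4, T)
    return X, labels, lengths
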