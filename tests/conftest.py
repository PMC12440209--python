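"""Shared fixtures: small synthetic traces, records and trained systems."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from glycloop.core_io import (
    BolusEvent, GlucoseTrace, MealEvent, PatientRecord, TherapyParams,
)
from glycloop.ensemble import SearchConfig, train_system
from glycloop.planted import make_planted_dataset
from glycloop.profiling import build_profile_index

T0 = pd.Timestamp("2024-03-01 00:00")


def make_trace(values, start=T0, step=5, missing=None):
    values = np.asarray(values, dtype=float)
    if missing is None:
        missing = np.zeros(len(values), dtype=bool)
    return GlucoseTrace(start_time=start, values=values,
                        missing=np.asarray(missing, dtype=bool), step_min=step)


def constant_trace(value, n, start=T0):
    return make_trace(np.full(n, float(value)), start=start)


@pytest.fixture
def therapy():
    return TherapyParams(cr=10.0, cf=30.0, cgm_target=150.0, dia_hours=4.0)


@pytest.fixture
def day_record(therapy):
    """One complete day at 120 mg/dL with a noon meal and its bolus."""
    trace = constant_trace(120.0, 288)
    noon = T0 + pd.Timedelta(hours=12)
    return PatientRecord(
        patient_id="p1", trace=trace,
        meals=[MealEvent(time=noon, cho_announced=60.0)],
        boluses=[BolusEvent(time=noon, units=6.0)],
        therapy=therapy,
    )


#: light search used everywhere training speed matters in tests
FAST_SEARCH = SearchConfig(n_estimators=(40, 120), n_draws=3, cv=3)


@pytest.fixture(scope="session")
def planted_dataset():
    return make_planted_dataset(n_per_subgroup=40, imbalance=3, seed=7)


@pytest.fixture(scope="session")
def trained_planted(planted_dataset):
    """Centroid store + both trained systems on the planted dataset."""
    ds = planted_dataset
    store = build_profile_index(ds, seed=11, som_epochs=120)
    s1 = train_system(ds, "S1", store, seed=13, search=FAST_SEARCH)
    s2 = train_system(ds, "S2", store, seed=17, search=FAST_SEARCH)
    return ds, store, s1, s2
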