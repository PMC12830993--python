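import numpy as np
import pandas as pd
import pytest

import pirlms
from pirlms.preprocess import SamplingEvent, Scan


@pytest.fixture(scope="session")
def small_cohort():
    """Small separable two-class cohort: 6 lymphoma + 8 PDX specimens,
    4 events each — fast enough for unit-level checks."""
    cfg = pirlms.CohortConfig(
        n_specimens_per_class=(6, 8), events_per_specimen=4, seed=11
    )
    scans, truth = pirlms.generate_cohort(cfg)
    matrix = pirlms.run_pipeline(scans, truth)
    return cfg, scans, truth, matrix


@pytest.fixture(scope="session")
def full_cohort():
    """Study-scale modelling cohort: 20 lymphoma + 90 PDX specimens with
    ~12 sampling events each, default noise and bad-event rates."""
    cfg = pirlms.CohortConfig(seed=20230101)
    scans, truth = pirlms.generate_cohort(cfg)
    matrix = pirlms.run_pipeline(scans, truth)
    return cfg, truth, matrix


@pytest.fixture(scope="session")
def full_model(full_cohort):
    _, truth, matrix = full_cohort
    good = matrix.good_mask()
    return pirlms.fit(
        matrix.values[good],
        matrix.annotations.loc[good, "class_label"].to_numpy(),
    )


@pytest.fixture(scope="session")
def blind_cohort():
    """Blind-set-shaped cohort: 30 lymphoma + 118 PDX specimens."""
    cfg = pirlms.CohortConfig(
        n_specimens_per_class=(30, 118),
        events_per_specimen=(12, 16),
        cancer_types=pirlms.synthetic.BLIND_CANCER_TYPES,
        seed=20240101,
    )
    scans, sealed = pirlms.generate_blind_set(cfg)
    matrix = pirlms.run_pipeline(scans, sealed.metadata)
    return cfg, sealed, matrix


def make_event(peaks, n_scans=13, event_id="ev"):
    """Build a SamplingEvent whose every scan holds the given (mz, intensity)
    peaks; helper for hand-constructed preprocessing tests."""
    mz = np.array([p[0] for p in peaks], dtype=float)
    inten = np.array([p[1] for p in peaks], dtype=float)
    scans = [Scan(i, mz.copy(), inten.copy()) for i in range(n_scans)]
    return SamplingEvent.from_scans(event_id, scans)


@pytest.fixture
def toy_event():
    return make_event([(717.5070, 5e4), (500.05, 2e4), (885.5, 1e4)])
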