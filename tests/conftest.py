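"""Shared fixtures: synthetic cohorts and fitted pipelines reused across tests.

Everything is generated programmatically with fixed seeds; session scope keeps
the expensive model fits to one per test run.
"""

from __future__ import annotations

import numpy as np
import pytest

from mskmark import biomarkers, landmark, phantoms, triage


@pytest.fixture(scope="session")
def triage_cohort():
    """Default synthetic knee cohort, z-scored to its healthy reference."""
    spec = phantoms.SyntheticCohortSpec(n_subjects=500, rng_seed=11)
    df = phantoms.make_triage_cohort(spec)
    markers = [f for f in triage.TRIAGE_FEATURES if f not in ("sex", "age", "weight")]
    ref = biomarkers.fit_reference(
        df, markers, (df["knee_abnormal"] == 0).to_numpy(),
        provenance="healthy knees")
    return biomarkers.zscore(df, ref)


@pytest.fixture(scope="session")
def stage_fit(triage_cohort):
    y = triage_cohort["knee_abnormal"].to_numpy(dtype=int)
    groups = triage_cohort["subject_id"].to_numpy()
    fit = triage.fit_stage(triage_cohort[list(triage.TRIAGE_FEATURES)], y, groups,
                           seed=0)
    return fit, y, groups


@pytest.fixture(scope="session")
def landmark_cohort_data():
    spec = phantoms.LongitudinalCohortSpec(n_knees=1000, rng_seed=7)
    return phantoms.make_landmark_cohort(spec)


@pytest.fixture(scope="session")
def landmark_cohort(landmark_cohort_data):
    return landmark.build_landmark(landmark_cohort_data, task="tkr")


@pytest.fixture(scope="session")
def landmark_predictions(landmark_cohort):
    return landmark.fit_risk_model(landmark_cohort, model="rf", seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
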