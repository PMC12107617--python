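import math

import numpy as np
import pytest

import qtctbt as q
from qtctbt.simulate import DEFAULT_COVARIATES


def reference_covariates():
    """Covariate distributions collapsed to the reference medians (CV 0)."""
    return {k: (v[0], 0.0, v[2], v[3]) for k, v in DEFAULT_COVARIATES.items()}


@pytest.fixture(scope="session")
def published():
    return q.published_model_spec()


@pytest.fixture()
def ref_subject():
    # Reference covariates: age 33 y, weight 56 kg, albumin 35 g/L, TTP 230.5 h.
    return q.SubjectProfile("ref", study="C208", arm="active", weight_kg=56.0)


@pytest.fixture()
def tiny_records():
    """Two subjects: one triplicate occasion each plus a singleton for S2."""
    rows = []
    for rep, hr, qt in zip((1, 2, 3), (80.0, 82.0, 78.0), (380.0, 376.0, 384.0)):
        rows.append(
            q.EcgRecord("S1", "C208", "active", -1 / 7, 9.0, "S1-occ0", rep, hr, qt, 0.0)
        )
    rows.append(q.EcgRecord("S2", "C209", "active", 2.0, 14.0, "S2-occ0", 1, 70.0, 400.0, 250.0))
    rows.append(q.EcgRecord("S2", "C209", "active", 2.0, 14.0, "S2-occ0", 2, 71.5, 398.0, 250.0))
    rows.append(q.EcgRecord("S2", "C209", "active", 8.0, 10.0, "S2-occ1", 1, 68.0, 402.0, 420.0))
    return rows


@pytest.fixture()
def tiny_subjects():
    return [
        q.SubjectProfile("S1", study="C208", arm="active", age_y=40.0, weight_kg=60.0,
                         albumin_gL=32.0, ttp_mgit_h=180.0),
        q.SubjectProfile("S2", study="C209", arm="active", age_y=25.0, weight_kg=50.0,
                         albumin_gL=38.0, ttp_mgit_h=300.0),
    ]


@pytest.fixture(scope="session")
def matched_cf_dataset():
    """Cohort simulated and QT-generated under the true time-varying CF.

    60 subjects, reduced IIV (baseline/recovered HR), default visit
    schedule; shared across evaluation/endpoints tests.
    """
    design = q.CohortDesign(n_subjects=60)
    model = q.published_model_spec(("hr_base", "hr_rec"))
    records, cohort = q.make_dataset(design, model, seed=20260922)
    return q.records_to_frame(records, cohort), cohort
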