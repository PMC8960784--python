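"""Shared fixtures: synthetic cohorts and extracted feature tables.

Heavy fixtures are session-scoped; everything is seeded so the suite is
fully deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import spiraltremor as st

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")

GROUPS = ("control", "ET0", "ET1plus", "ET2plus")


@pytest.fixture(scope="session")
def default_cohort() -> list[st.SyntheticSubject]:
    """One default 35-subject cohort (18/6/5/6), fixed seed."""
    return st.make_cohort(seed=0)


def _features_frame(cohort: list[st.SyntheticSubject]) -> pd.DataFrame:
    rows = []
    for s in cohort:
        for site, accel in s.accel_by_site.items():
            f = st.extract_features(accel, s.pen, subject_id=s.subject_id)
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "site": site,
                    "psd_ratio": f.psd_ratio,
                    "task_time": f.task_time,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def cohort_features(default_cohort) -> pd.DataFrame:
    """Extracted features for the default cohort, all subjects x sites."""
    return _features_frame(default_cohort)


@pytest.fixture(scope="session")
def cohort_table(default_cohort, cohort_features) -> pd.DataFrame:
    """Joined cohort table (features + clinical) for the default cohort."""
    from spiraltremor.synthetic import cohort_clinical_frame

    return st.build_cohort_table(
        cohort_features, cohort_clinical_frame(default_cohort)
    )


@pytest.fixture(scope="session")
def replicate_s2_features() -> pd.DataFrame:
    """Mid-forearm features pooled over 20 seeded replicate cohorts.

    Used both for the generator-fidelity check (group means vs configured
    means) and for replicate-level classification sanity.  Traces are
    discarded after feature extraction to bound memory.
    """
    rows = []
    for rep in range(20):
        cohort = st.make_cohort(seed=1000 + rep)
        for s in cohort:
            f = st.extract_features(s.accel_by_site["S2"], s.pen, s.subject_id)
            rows.append(
                {
                    "replicate": rep,
                    "subject_id": s.subject_id,
                    "group": s.group_label,
                    "site": "S2",
                    "psd_ratio": f.psd_ratio,
                    "task_time": f.task_time,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
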