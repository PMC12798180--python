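import numpy as np
import pandas as pd
import pytest

from dctsem.core_io import Study, StudyConfig, derive_subject_fields
from dctsem.features import BINDER_FEATURES
from dctsem.profiles import study_profiles
from dctsem.qc import apply_exclusions, filter_study
from dctsem.synthetic import SyntheticSpec, simulate_study


def tiny_binder(item_ids, seed=0):
    """A small valid Binder matrix (all 65 features) for handcrafted fixtures."""
    rng = np.random.default_rng(seed)
    scores = rng.uniform(0, 6, size=(len(item_ids), len(BINDER_FEATURES)))
    return pd.DataFrame(scores, index=pd.Index(item_ids, name="item_id"),
                        columns=list(BINDER_FEATURES))


def make_trials(rows):
    df = pd.DataFrame(rows, columns=["subject_id", "item_id", "choice", "rt_ms",
                                     "button_layout", "is_attention_check",
                                     "attention_passed"])
    df["is_attention_check"] = df["is_attention_check"].astype(bool)
    df["attention_passed"] = df["attention_passed"].astype("boolean")
    return df


def make_subjects(rows):
    base = {f"phq{i}": 0 for i in range(1, 10)}
    records = []
    for r in rows:
        rec = {"age": 30, "gender": "female", **base, **r}
        records.append(rec)
    return derive_subject_fields(pd.DataFrame(records))


@pytest.fixture
def small_study():
    """2 subjects x 3 items, no attention checks, fully valid."""
    binder = tiny_binder(["w1", "w2", "w3"])
    subjects = make_subjects([
        {"subject_id": "a", "language": "English", "system_terms": 2},
        {"subject_id": "b", "language": "Spanish", "system_terms": 3},
    ])
    trials = make_trials([
        ("a", "w1", "proximal", 500.0, "horizontal", False, pd.NA),
        ("a", "w2", "distal", 600.0, "vertical", False, pd.NA),
        ("a", "w3", "distal", 700.0, "horizontal", False, pd.NA),
        ("b", "w1", "medial", 450.0, "vertical", False, pd.NA),
        ("b", "w2", "proximal", 520.0, "horizontal", False, pd.NA),
        ("b", "w3", "distal", 610.0, "vertical", False, pd.NA),
    ])
    return Study(trials=trials, subjects=subjects, binder=binder)


@pytest.fixture(scope="session")
def cohort300():
    """Clean synthetic cohort, 300 subjects, default planted effects."""
    spec = SyntheticSpec(seed=0).scaled_to(300)
    study, truth = simulate_study(spec)
    return study, truth, spec


@pytest.fixture(scope="session")
def pipeline300(cohort300):
    """QC-filtered profiles + subjects for the 300-subject cohort."""
    study, truth, spec = cohort300
    retained = filter_study(study, apply_exclusions(study, StudyConfig()))
    profiles = study_profiles(retained)
    return profiles, retained.subjects, retained
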