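"""Domain containers, file I/O, PHQ-9 grouping and seeding.

The study is held as three pandas DataFrames:

* ``trials`` — one row per demonstrative choice (including attention-check
  trials), columns ``subject_id, item_id, choice, rt_ms, button_layout,
  is_attention_check, attention_passed``.
* ``subjects`` — one row per participant with language, demographics and the
  nine PHQ-9 item scores; ``phq9_sum`` and ``group`` are derived on load.
* ``binder`` — items x 65 Binder feature scores, indexed by ``item_id``.

All tables are plain UTF-8 CSV with a header row.  Choices are stored as the
normalized labels ``proximal``/``medial``/``distal``; the language-specific
surface form ("este", "那个", ...) may ride along in an optional
``surface_form`` column but is never used by the analysis.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .features import BINDER_FEATURES, N_FEATURES

CHOICES = ("proximal", "medial", "distal")
GROUP_CONTROL = 0
GROUP_DEPRESSION = 1
PHQ9_THRESHOLD = 10
N_PHQ_ITEMS = 9
PHQ_COLUMNS = tuple(f"phq{i}" for i in range(1, N_PHQ_ITEMS + 1))

#: The seven study languages and the size of their demonstrative system.
#: Spanish and Filipino have three terms (proximal/medial/distal); the rest
#: contrast only proximal and distal.
LANGUAGE_SYSTEMS: dict[str, int] = {
    "English": 2,
    "German": 2,
    "Italian": 2,
    "Spanish": 3,
    "Chinese": 2,
    "Russian": 2,
    "Filipino": 3,
}

TRIAL_COLUMNS = (
    "subject_id", "item_id", "choice", "rt_ms", "button_layout",
    "is_attention_check", "attention_passed",
)
SUBJECT_COLUMNS = ("subject_id", "language", "system_terms", "age", "gender") + PHQ_COLUMNS

CODING_SCHEMES: dict[str, int] = {
    "drop_medial": 0,
    "medial_as_distal": -1,
    "medial_as_proximal": 1,
}


class StudyValidationError(ValueError):
    """A table violates the study schema or referential integrity."""


def child_seed(seed: int, *keys: int | str) -> int:
    """Derive a deterministic sub-seed (< 2**31) from a parent seed and keys.

    Every stochastic operation in the package draws its own generator from
    the single study seed via this function, so reruns are bit-reproducible
    and independent stages never share a stream.
    """
    ints = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode("utf-8")))
        else:
            ints.append(int(k) & 0xFFFFFFFF)
    ss = np.random.SeedSequence(ints)
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def rng_for(seed: int, *keys: int | str) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, *keys))


@dataclass
class StudyConfig:
    """Analysis constants shared by all stages.

    The quality-control thresholds are the protocol's exclusion rules:
    reaction times under ``rt_fast_ms`` on more than ``rt_fast_frac`` of
    trials, normalized response entropy below ``entropy_min``, or more than
    ``max_check_fails`` of ``n_checks`` failed attention checks.
    """

    coding_scheme: str = "drop_medial"
    rt_fast_ms: float = 300.0
    rt_fast_frac: float = 0.10
    entropy_min: float = 0.80
    max_check_fails: int = 3
    n_checks: int = 15
    test_frac: float = 0.30
    val_frac_of_train: float = 0.20
    n_bootstrap: int = 1000
    downsample: str = "train"  # "train" (default) or "pre_split"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coding_scheme not in CODING_SCHEMES:
            raise ValueError(f"unknown coding scheme {self.coding_scheme!r}")
        for name in ("test_frac", "val_frac_of_train"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for name in ("rt_fast_ms", "rt_fast_frac", "entropy_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.downsample not in ("train", "pre_split"):
            raise ValueError("downsample must be 'train' or 'pre_split'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise StudyValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class Study:
    """A loaded study: trials, subjects and the item Binder matrix."""

    trials: pd.DataFrame
    subjects: pd.DataFrame
    binder: pd.DataFrame

    @property
    def item_ids(self) -> pd.Index:
        return self.binder.index

    def trials_of(self, subject_id: str, checks: bool = False) -> pd.DataFrame:
        t = self.trials[self.trials["subject_id"] == subject_id]
        if not checks:
            t = t[~t["is_attention_check"]]
        return t


def assign_group(phq9_items: Iterable[int]) -> tuple[int, int]:
    """Classify a participant from their nine PHQ-9 item scores.

    Returns ``(group, phq9_sum)`` where group is 1 (depression) iff the sum
    of the nine 0-3 item scores reaches 10, the moderate-depression cutoff,
    and 0 (control) otherwise.
    """
    items = list(phq9_items)
    if len(items) != N_PHQ_ITEMS:
        raise ValueError(f"expected {N_PHQ_ITEMS} PHQ-9 items, got {len(items)}")
    for i, v in enumerate(items, start=1):
        iv = int(v)
        if iv != v or not 0 <= iv <= 3:
            raise ValueError(f"PHQ-9 item {i} out of range [0, 3]: {v!r}")
    total = int(sum(items))
    group = GROUP_DEPRESSION if total >= PHQ9_THRESHOLD else GROUP_CONTROL
    return group, total


def derive_subject_fields(subjects: pd.DataFrame) -> pd.DataFrame:
    """Attach ``phq9_sum`` and ``group`` columns derived from the PHQ items."""
    out = subjects.copy()
    items = out[list(PHQ_COLUMNS)].to_numpy()
    out["phq9_sum"] = items.sum(axis=1).astype(int)
    out["group"] = (out["phq9_sum"] >= PHQ9_THRESHOLD).astype(int)
    return out


def _check_columns(df: pd.DataFrame, required: tuple[str, ...], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise StudyValidationError(f"{table} is missing columns {missing}")


def validate_study(study: Study) -> None:
    """Raise :class:`StudyValidationError` on any schema or integrity breach.

    Checks performed: column schemas; choice labels; nonnegative RTs;
    attention_passed present iff is_attention_check; PHQ items in [0, 3];
    system size consistent with language; medial choices only for 3-term
    subjects; and referential integrity of subject and (non-check) item ids.
    """
    trials, subjects, binder = study.trials, study.subjects, study.binder
    _check_columns(trials, TRIAL_COLUMNS, "trials")
    _check_columns(subjects, SUBJECT_COLUMNS, "subjects")

    if binder.shape[1] != N_FEATURES:
        raise StudyValidationError(
            f"binder matrix must have {N_FEATURES} feature columns, has {binder.shape[1]}")
    if list(binder.columns) != list(BINDER_FEATURES):
        raise StudyValidationError("binder feature columns do not match the 65 Binder names")
    if binder.isna().any().any():
        raise StudyValidationError("binder matrix contains missing cells")
    if binder.index.duplicated().any():
        dup = binder.index[binder.index.duplicated()][0]
        raise StudyValidationError(f"duplicate item in binder matrix: {dup!r}")

    bad = ~trials["choice"].isin(CHOICES)
    if bad.any():
        row = trials[bad].iloc[0]
        raise StudyValidationError(
            f"unknown choice label {row['choice']!r} "
            f"(subject {row['subject_id']!r}, item {row['item_id']!r})")
    if (trials["rt_ms"] < 0).any():
        row = trials[trials["rt_ms"] < 0].iloc[0]
        raise StudyValidationError(f"negative rt_ms for subject {row['subject_id']!r}")

    is_check = trials["is_attention_check"].astype(bool)
    passed_defined = trials["attention_passed"].notna()
    if (is_check & ~passed_defined).any():
        row = trials[is_check & ~passed_defined].iloc[0]
        raise StudyValidationError(
            f"attention-check trial without attention_passed (subject {row['subject_id']!r})")
    if (~is_check & passed_defined).any():
        row = trials[~is_check & passed_defined].iloc[0]
        raise StudyValidationError(
            f"attention_passed set on a non-check trial (subject {row['subject_id']!r})")

    if subjects["subject_id"].duplicated().any():
        dup = subjects.loc[subjects["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise StudyValidationError(f"duplicate subject id {dup!r}")
    for col in PHQ_COLUMNS:
        vals = subjects[col]
        if vals.isna().any():
            sid = subjects.loc[vals.isna(), "subject_id"].iloc[0]
            raise StudyValidationError(f"malformed PHQ-9 row for subject {sid!r}: {col} missing")
        out_of_range = ~vals.isin([0, 1, 2, 3])
        if out_of_range.any():
            sid = subjects.loc[out_of_range, "subject_id"].iloc[0]
            raise StudyValidationError(
                f"malformed PHQ-9 row for subject {sid!r}: {col}={vals[out_of_range].iloc[0]!r}")

    unknown_lang = ~subjects["language"].isin(LANGUAGE_SYSTEMS)
    if unknown_lang.any():
        lang = subjects.loc[unknown_lang, "language"].iloc[0]
        raise StudyValidationError(f"unknown language {lang!r}")
    expected_terms = subjects["language"].map(LANGUAGE_SYSTEMS)
    mismatch = subjects["system_terms"].astype(int) != expected_terms
    if mismatch.any():
        sid = subjects.loc[mismatch, "subject_id"].iloc[0]
        raise StudyValidationError(f"system_terms inconsistent with language for {sid!r}")

    known_subjects = set(subjects["subject_id"])
    orphan = ~trials["subject_id"].isin(known_subjects)
    if orphan.any():
        sid = trials.loc[orphan, "subject_id"].iloc[0]
        raise StudyValidationError(f"trial references unknown subject {sid!r}")

    noncheck = trials[~is_check]
    known_items = set(binder.index)
    orphan_item = ~noncheck["item_id"].isin(known_items)
    if orphan_item.any():
        iid = noncheck.loc[orphan_item, "item_id"].iloc[0]
        raise StudyValidationError(f"trial references item {iid!r} absent from the Binder matrix")

    terms = subjects.set_index("subject_id")["system_terms"]
    medial = noncheck[noncheck["choice"] == "medial"]
    if len(medial):
        two_term = medial["subject_id"].map(terms).astype(int) == 2
        if two_term.any():
            sid = medial.loc[two_term, "subject_id"].iloc[0]
            raise StudyValidationError(
                f"medial choice by 2-term-system subject {sid!r}")


def trial_counts(study: Study) -> pd.Series:
    """Non-check trials per subject (reported on load for integrity review)."""
    noncheck = study.trials[~study.trials["is_attention_check"].astype(bool)]
    counts = noncheck.groupby("subject_id").size()
    return counts.reindex(study.subjects["subject_id"], fill_value=0)


def read_binder(path: str | Path) -> pd.DataFrame:
    binder = pd.read_csv(path, dtype={"item_id": str}).set_index("item_id")
    return binder


def read_study(trials_path: str | Path, subjects_path: str | Path,
               binder_path: str | Path, validate: bool = True) -> Study:
    """Load and validate the three study tables from CSV."""
    trials = pd.read_csv(
        trials_path, dtype={"subject_id": str, "item_id": str, "choice": str})
    trials["is_attention_check"] = trials["is_attention_check"].astype(bool)
    trials["attention_passed"] = _parse_optional_bool(trials["attention_passed"])
    subjects = pd.read_csv(subjects_path, dtype={"subject_id": str, "language": str})
    binder = read_binder(binder_path)
    study = Study(trials=trials, subjects=derive_subject_fields(subjects), binder=binder)
    if validate:
        validate_study(study)
    return study


def _parse_optional_bool(col: pd.Series) -> pd.Series:
    mapping = {"True": True, "False": False, True: True, False: False,
               1.0: True, 0.0: False}
    return col.map(lambda v: mapping.get(v, pd.NA)).astype("boolean")


def write_study(study: Study, out_dir: str | Path) -> dict[str, Path]:
    """Write trials.csv, subjects.csv and binder.csv; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "trials": out / "trials.csv",
        "subjects": out / "subjects.csv",
        "binder": out / "binder.csv",
    }
    trials = study.trials.copy()
    trials["attention_passed"] = trials["attention_passed"].map(
        lambda v: "" if pd.isna(v) else str(bool(v)))
    trials.to_csv(paths["trials"], index=False)
    subjects = study.subjects.drop(columns=["phq9_sum", "group"], errors="ignore")
    subjects.to_csv(paths["subjects"], index=False)
    study.binder.to_csv(paths["binder"], index_label="item_id")
    return paths


def exclude_missing(study: Study) -> tuple[pd.Series, pd.Series]:
    """Flag subjects with incomplete records.

    A subject is "missing" if any demographic or PHQ-9 field is absent or if
    they did not answer every item in the Binder matrix exactly once (the
    analogue of server-error data loss in online studies).  Returns a boolean
    Series indexed by subject_id and the per-subject non-check trial counts.
    """
    subj = study.subjects.set_index("subject_id")
    demo_missing = subj[list(("language", "age", "gender") + PHQ_COLUMNS)].isna().any(axis=1)
    counts = trial_counts(study)
    counts.index = study.subjects["subject_id"]
    n_items = len(study.binder)
    incomplete = counts != n_items
    missing = demo_missing | incomplete
    return missing, counts
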