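"""Low-effort and missing-data exclusions.

A subject is excluded when any of the following holds (strict comparisons,
reading the protocol's wording literally):

* more than 10% of non-check trials faster than 300 ms,
* normalized response entropy below 0.80,
* more than 3 of 15 failed attention checks,
* incomplete data (missing demographics, PHQ-9 items or trials).

Entropy is computed over the chosen demonstrative *forms* (not physical
button positions, which were randomized per trial) and normalized by
log2(K), K being the number of forms in the subject's system, so the single
0.80 threshold applies to 2- and 3-term languages alike.  Attention-check
trials are excluded from the RT-fraction and entropy computations: they have
a correct answer and would bias both.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import Study, StudyConfig, exclude_missing

QC_REASONS = ("fast_rt", "low_entropy", "attention", "missing")


def fast_rt_fraction(trials_of_subject: pd.DataFrame,
                     threshold_ms: float = 300.0) -> float:
    """Fraction of non-check trials with RT strictly below the threshold."""
    t = trials_of_subject[~trials_of_subject["is_attention_check"].astype(bool)]
    if len(t) == 0:
        raise ValueError("subject has no non-check trials")
    return float((t["rt_ms"].to_numpy() < threshold_ms).mean())


def response_entropy(trials_of_subject: pd.DataFrame,
                     n_forms: int | None = None) -> float:
    """Shannon entropy (bits) of the form distribution, normalized to [0, 1].

    ``n_forms`` is the size of the subject's demonstrative system; when not
    given it defaults to the number of distinct forms actually used.  The
    convention 0*log(0) = 0 applies, so an all-proximal responder scores 0.
    """
    t = trials_of_subject[~trials_of_subject["is_attention_check"].astype(bool)]
    if len(t) == 0:
        raise ValueError("subject has no non-check trials")
    counts = t["choice"].value_counts()
    k = int(n_forms) if n_forms is not None else len(counts)
    if k < 2:
        return 0.0
    p = counts.to_numpy(dtype=float) / counts.sum()
    p = p[p > 0]
    h = float(-(p * np.log2(p)).sum())
    return h / np.log2(k)


def count_check_fails(trials_of_subject: pd.DataFrame) -> int:
    checks = trials_of_subject[trials_of_subject["is_attention_check"].astype(bool)]
    return int((~checks["attention_passed"].astype("boolean")).sum())


def apply_exclusions(study: Study, config: StudyConfig | None = None) -> pd.DataFrame:
    """Per-subject QC metrics and exclusion decisions.

    Returns a DataFrame indexed by subject_id with columns
    ``fast_rt_fraction, response_entropy, n_check_fails, excluded, reasons``;
    ``reasons`` is a semicolon-joined subset of
    ``fast_rt, low_entropy, attention, missing`` and is empty iff the subject
    is retained.
    """
    config = config or StudyConfig()
    missing, counts = exclude_missing(study)
    terms = study.subjects.set_index("subject_id")["system_terms"]

    rows = []
    grouped = dict(iter(study.trials.groupby("subject_id", sort=False)))
    for sid in study.subjects["subject_id"]:
        t = grouped.get(sid, study.trials.iloc[0:0])
        has_trials = len(t[~t["is_attention_check"].astype(bool)]) > 0
        frac = fast_rt_fraction(t, config.rt_fast_ms) if has_trials else np.nan
        ent = response_entropy(t, n_forms=int(terms[sid])) if has_trials else np.nan
        fails = count_check_fails(t)
        reasons = []
        if has_trials and frac > config.rt_fast_frac:
            reasons.append("fast_rt")
        if has_trials and ent < config.entropy_min:
            reasons.append("low_entropy")
        if fails > config.max_check_fails:
            reasons.append("attention")
        if bool(missing[sid]):
            reasons.append("missing")
        rows.append({
            "subject_id": sid,
            "fast_rt_fraction": frac,
            "response_entropy": ent,
            "n_check_fails": fails,
            "excluded": bool(reasons),
            "reasons": ";".join(reasons),
        })
    return pd.DataFrame(rows).set_index("subject_id")


def retained_subjects(report: pd.DataFrame) -> list[str]:
    return list(report.index[~report["excluded"]])


def filter_study(study: Study, report: pd.DataFrame) -> Study:
    """Drop excluded subjects (and their trials) from the study."""
    keep = set(retained_subjects(report))
    return Study(
        trials=study.trials[study.trials["subject_id"].isin(keep)].reset_index(drop=True),
        subjects=study.subjects[study.subjects["subject_id"].isin(keep)].reset_index(drop=True),
        binder=study.binder,
    )
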