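"""Semantic profiles: the pipeline's core per-subject statistic.

Each retained subject's demonstrative choices are recoded to +1 (proximal),
-1 (distal) and a scheme-dependent value for medial (0 to drop it, -1 to
fold it into distal, +1 to fold it into proximal), giving a subjects x items
response matrix R.  The semantic profile is

    P = R . B / n_items

with B the items x 65 Binder matrix: one value per Binder feature,
positive when the subject chose proximal more often for items scoring high
on that feature, negative for a distal preference, and 0 for no asymmetry.
The denominator is always the total item count, including medial-coded-0
trials under ``drop_medial`` — medial responses are effectively ignored
rather than renormalized away.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import CODING_SCHEMES, Study


def recode_responses(trials: pd.DataFrame, binder: pd.DataFrame,
                     scheme: str = "drop_medial",
                     subject_ids: list[str] | None = None) -> pd.DataFrame:
    """Subjects x items matrix of coded choices, columns in Binder order.

    ``trials`` should contain only QC-retained subjects; attention-check
    trials are dropped here.  A subject answering an item twice or missing
    an item is a protocol violation and raises.
    """
    if scheme not in CODING_SCHEMES:
        raise ValueError(f"unknown coding scheme {scheme!r}")
    medial_value = CODING_SCHEMES[scheme]
    codes = {"proximal": 1, "medial": medial_value, "distal": -1}

    t = trials[~trials["is_attention_check"].astype(bool)]
    if subject_ids is not None:
        t = t[t["subject_id"].isin(set(subject_ids))]
    unknown = ~t["choice"].isin(codes)
    if unknown.any():
        raise ValueError(f"unknown form {t.loc[unknown, 'choice'].iloc[0]!r}")

    coded = t["choice"].map(codes)
    matrix = pd.pivot_table(
        t.assign(code=coded), index="subject_id", columns="item_id",
        values="code", aggfunc="count")
    # aggfunc count detects duplicates; rebuild values with a strict pivot
    if (matrix > 1).any().any():
        sid = matrix.index[(matrix > 1).any(axis=1)][0]
        raise ValueError(f"subject {sid!r} answered an item more than once")
    matrix = t.assign(code=coded).pivot(index="subject_id", columns="item_id",
                                        values="code")
    matrix = matrix.reindex(columns=binder.index)
    if matrix.isna().any().any():
        sid = matrix.index[matrix.isna().any(axis=1)][0]
        raise ValueError(f"subject {sid!r} is missing responses for some items")
    out = matrix.astype(int)
    out.attrs["scheme"] = scheme
    if subject_ids is not None:
        out = out.loc[[s for s in subject_ids if s in out.index]]
    return out


def compute_profiles(responses: pd.DataFrame, binder: pd.DataFrame) -> pd.DataFrame:
    """(R . B) / n_items — subjects x features semantic-profile matrix."""
    if list(responses.columns) != list(binder.index):
        if set(responses.columns) != set(binder.index):
            raise ValueError("response items do not match the Binder matrix rows")
        responses = responses[binder.index]
    values = responses.to_numpy(dtype=float) @ binder.to_numpy(dtype=float)
    values /= len(binder)
    out = pd.DataFrame(values, index=responses.index, columns=binder.columns)
    out.attrs["scheme"] = responses.attrs.get("scheme")
    out.attrs["scaling"] = "raw"
    return out


@dataclass
class ProfileScaler:
    """Per-feature z-scoring with training-set statistics.

    Statistics are estimated once on a training set and reapplied verbatim to
    validation/test rows; a constant training feature maps to all zeros.
    """

    means: pd.Series
    sds: pd.Series

    @classmethod
    def fit(cls, profiles: pd.DataFrame) -> "ProfileScaler":
        means = profiles.mean(axis=0)
        sds = profiles.std(axis=0, ddof=0)
        return cls(means=means, sds=sds)

    def transform(self, profiles: pd.DataFrame) -> pd.DataFrame:
        if list(profiles.columns) != list(self.means.index):
            raise ValueError("profile columns do not match scaler features")
        safe = self.sds.where(self.sds > 0, 1.0)
        out = (profiles - self.means) / safe
        out.loc[:, self.sds <= 0] = 0.0
        out.attrs["scheme"] = profiles.attrs.get("scheme")
        out.attrs["scaling"] = "zscored"
        return out


def scale_profiles(profiles: pd.DataFrame,
                   scaler: ProfileScaler | None = None
                   ) -> tuple[pd.DataFrame, ProfileScaler]:
    """Z-score profiles; fit statistics here if no scaler is given."""
    if scaler is None:
        scaler = ProfileScaler.fit(profiles)
    return scaler.transform(profiles), scaler


def study_profiles(study: Study, scheme: str = "drop_medial",
                   subject_ids: list[str] | None = None) -> pd.DataFrame:
    """Convenience: recode a (QC-filtered) study and compute raw profiles."""
    responses = recode_responses(study.trials, study.binder, scheme=scheme,
                                 subject_ids=subject_ids)
    return compute_profiles(responses, study.binder)
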