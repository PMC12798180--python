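"""Synthetic DCT cohorts with the statistical structure the analysis assumes.

The generator emulates a multi-language Demonstrative Choice Task study:

* seven language samples (two of which use a 3-term demonstrative system),
* a 290-item task whose items carry 65 Binder feature scores with a
  correlated emotion block (the multicollinearity the classifiers must
  handle),
* PHQ-9 item scores ordinalized from a latent severity, calibrated so the
  expected depression prevalence (sum >= 10) matches a target,
* a logistic (2-term) / proportional-odds (3-term) choice model in scaled
  Binder space with group-specific feature weights — the planted truth that
  downstream recovery tests check against,
* log-normal reaction times, 15 appended attention-check trials per subject,
  and optional injection of the three low-effort behaviors the quality
  control stage is built to catch.

Everything is deterministic given the spec's seed; each stage draws a child
seed via :func:`dctsem.core_io.child_seed`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .core_io import (
    LANGUAGE_SYSTEMS,
    PHQ_COLUMNS,
    Study,
    child_seed,
    derive_subject_fields,
    validate_study,
)
from .features import (
    BINDER_FEATURES,
    DEFAULT_PLANTED_NEGATIVE,
    DEFAULT_PLANTED_POSITIVE,
    NEGATIVE_EMOTION,
    N_FEATURES,
    POSITIVE_EMOTION,
)

#: Included sample sizes per language in the study this generator emulates.
DEFAULT_N_SUBJECTS: dict[str, int] = {
    "English": 1654,
    "German": 488,
    "Italian": 462,
    "Spanish": 492,
    "Chinese": 279,
    "Filipino": 199,
    "Russian": 307,
}

DEFAULT_PLANTED_WEIGHT = 0.4
PHQ_CUTS = (0.5, 1.5, 2.5)


def default_beta_dep() -> dict[str, float]:
    """Depression-group effect template: proximal pull on negative-emotion
    features, distal push on positive-emotion features."""
    beta = {f: DEFAULT_PLANTED_WEIGHT for f in DEFAULT_PLANTED_POSITIVE}
    beta.update({f: -DEFAULT_PLANTED_WEIGHT for f in DEFAULT_PLANTED_NEGATIVE})
    return beta


@dataclass
class SyntheticSpec:
    """Generative parameters of a synthetic cohort.

    ``beta_dep`` / ``beta_ctrl`` map Binder feature names to log-odds weights
    (per SD of the feature) on choosing the proximal form; unnamed features
    get weight zero.  ``cutpoints`` are the proportional-odds thresholds of
    3-term systems (distal | medial | proximal on the same linear predictor).
    """

    n_subjects: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_N_SUBJECTS))
    n_items: int = 290
    prevalence: float = 0.34
    beta_dep: Mapping[str, float] = field(default_factory=default_beta_dep)
    beta_ctrl: Mapping[str, float] = field(default_factory=dict)
    base_intercept: float = 0.2
    intercept_sd: float = 0.2
    cutpoints: tuple[float, float] = (-1.2, 0.55)
    rt_meanlog: float = math.log(600.0)
    rt_sdlog: float = 0.3
    fast_responder_rate: float = 0.0
    constant_responder_rate: float = 0.0
    inattentive_rate: float = 0.0
    n_checks: int = 15
    p_check_pass: float = 0.98
    p_check_pass_inattentive: float = 0.3
    phq_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ValueError("n_items must be positive")
        if not 0.0 <= self.prevalence < 1.0:
            raise ValueError("prevalence must lie in [0, 1)")
        for name in ("fast_responder_rate", "constant_responder_rate", "inattentive_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for beta in (self.beta_dep, self.beta_ctrl):
            unknown = set(beta) - set(BINDER_FEATURES)
            if unknown:
                raise ValueError(f"unknown Binder features in beta: {sorted(unknown)}")
        unknown_lang = set(self.n_subjects) - set(LANGUAGE_SYSTEMS)
        if unknown_lang:
            raise ValueError(f"unknown languages: {sorted(unknown_lang)}")
        if not self.cutpoints[0] < self.cutpoints[1]:
            raise ValueError("cutpoints must be increasing")

    def beta_vector(self, group: int) -> np.ndarray:
        beta = self.beta_dep if group == 1 else self.beta_ctrl
        vec = np.zeros(N_FEATURES)
        for name, w in beta.items():
            vec[BINDER_FEATURES.index(name)] = w
        return vec

    def scaled_to(self, total: int, languages: tuple[str, ...] | None = None) -> "SyntheticSpec":
        """A copy with ``total`` subjects split proportionally across languages."""
        base = {k: v for k, v in self.n_subjects.items()
                if languages is None or k in languages}
        weight = sum(base.values())
        exact = {k: total * v / weight for k, v in base.items()}
        counts = {k: int(math.floor(v)) for k, v in exact.items()}
        remainders = sorted(base, key=lambda k: exact[k] - counts[k], reverse=True)
        for k in remainders[: total - sum(counts.values())]:
            counts[k] += 1
        counts = {k: max(v, 2) for k, v in counts.items()}
        return replace(self, n_subjects=counts)


def generate_binder_matrix(n_items: int, seed: int) -> pd.DataFrame:
    """Items x 65 feature scores on the native 0-6 rating scale.

    Emotion-domain features share a latent per-item valence, so negative
    (positive) emotion features are mutually positively correlated and
    anti-correlated across the valence boundary — the collinearity structure
    of real semantic norms.  All other features are independent noise around
    the scale midpoint.
    """
    if n_items < 1:
        raise ValueError("n_items must be positive")
    rng = np.random.default_rng(child_seed(seed, "binder"))
    valence = rng.normal(size=n_items)
    scores = np.empty((n_items, N_FEATURES))
    for j, name in enumerate(BINDER_FEATURES):
        eps = rng.normal(size=n_items)
        if name in NEGATIVE_EMOTION:
            col = 3.0 - 1.2 * valence + 0.8 * eps
        elif name in POSITIVE_EMOTION:
            col = 3.0 + 1.2 * valence + 0.8 * eps
        else:
            col = 3.0 + 1.4 * eps
        scores[:, j] = col
    np.clip(scores, 0.0, 6.0, out=scores)
    width = max(3, len(str(n_items)))
    item_ids = [f"item_{i + 1:0{width}d}" for i in range(n_items)]
    return pd.DataFrame(scores, index=pd.Index(item_ids, name="item_id"),
                        columns=list(BINDER_FEATURES))


def _phq_severity_offset(prevalence: float, noise_sd: float) -> float:
    """Offset mu such that P(sum of 9 ordinalized items >= 10) = prevalence.

    Item score = #{cutpoints below mu + s + e} with s ~ N(0,1) shared across
    a subject's items and e ~ N(0, noise_sd) per item.  The prevalence is
    computed exactly (quadrature over s, convolution over items) and solved
    for mu by bisection — a deterministic calibration, no sampling involved.
    """
    if prevalence <= 0.0:
        return -30.0
    nodes, weights = np.polynomial.hermite_e.hermegauss(81)
    weights = weights / math.sqrt(2.0 * math.pi)

    from scipy.stats import norm

    def prev(mu: float) -> float:
        total = 0.0
        for s, w in zip(nodes, weights):
            cdf = norm.cdf([(c - mu - s) / noise_sd for c in PHQ_CUTS])
            pmf = np.diff(np.concatenate([[0.0], cdf, [1.0]]))
            dist = np.array([1.0])
            for _ in range(9):
                dist = np.convolve(dist, pmf)
            total += w * dist[10:].sum()
        return total

    lo, hi = -15.0, 10.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if prev(mid) < prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


_OFFSET_CACHE: dict[tuple[float, float], float] = {}


def simulate_subjects(spec: SyntheticSpec) -> pd.DataFrame:
    """Draw the subject table: demographics, PHQ-9 items, derived group."""
    key = (round(spec.prevalence, 8), round(spec.phq_noise_sd, 8))
    if key not in _OFFSET_CACHE:
        _OFFSET_CACHE[key] = _phq_severity_offset(*key)
    mu = _OFFSET_CACHE[key]

    rng = np.random.default_rng(child_seed(spec.seed, "subjects"))
    rows = []
    counter = 0
    for language in sorted(spec.n_subjects):
        n = int(spec.n_subjects[language])
        terms = LANGUAGE_SYSTEMS[language]
        severity = rng.normal(size=n)
        ages = np.clip(np.round(rng.normal(35.0, 12.0, size=n)), 18, 89).astype(int)
        genders = rng.choice(
            ["female", "male", "nonbinary", "other"], size=n,
            p=[0.51, 0.45, 0.03, 0.01])
        latent = (mu + severity[:, None]
                  + rng.normal(scale=spec.phq_noise_sd, size=(n, 9)))
        items = (latent[:, :, None] > np.array(PHQ_CUTS)).sum(axis=2)
        for i in range(n):
            counter += 1
            row = {
                "subject_id": f"s{counter:05d}",
                "language": language,
                "system_terms": terms,
                "age": ages[i],
                "gender": genders[i],
            }
            row.update({col: int(items[i, j]) for j, col in enumerate(PHQ_COLUMNS)})
            rows.append(row)
    return derive_subject_fields(pd.DataFrame(rows))


def simulate_trials(subjects: pd.DataFrame, binder: pd.DataFrame,
                    spec: SyntheticSpec) -> pd.DataFrame:
    """Draw every subject's choices, RTs and attention-check trials.

    2-term subjects: P(proximal | item) = logistic(base + alpha_subj +
    beta_group . z(binder_row)).  3-term subjects: proportional odds on the
    same linear predictor with the spec cutpoints separating distal, medial
    and proximal.  RTs are log-normal and independent of semantics.
    """
    n_items = len(binder)
    b = binder.to_numpy(dtype=float)
    sd = b.std(axis=0)
    z = (b - b.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    eta_item = {g: z @ spec.beta_vector(g) for g in (0, 1)}

    rng = np.random.default_rng(child_seed(spec.seed, "trials"))
    n_subj = len(subjects)
    alphas = rng.normal(scale=spec.intercept_sd, size=n_subj)
    groups = subjects["group"].to_numpy()
    terms = subjects["system_terms"].to_numpy()
    eta = (spec.base_intercept + alphas[:, None]
           + np.stack([eta_item[g] for g in groups]))

    u = rng.uniform(size=(n_subj, n_items))
    k_lo, k_hi = spec.cutpoints
    # 2-term: proximal vs distal.  3-term: distal | medial | proximal.
    choice = np.where(u < expit(eta), 0, 2)  # 0=proximal, 2=distal
    three = terms == 3
    if three.any():
        p_prox = expit(eta[three] - k_hi)
        p_prox_or_med = expit(eta[three] - k_lo)
        u3 = u[three]
        c3 = np.full(u3.shape, 2)
        c3[u3 < p_prox_or_med] = 1
        c3[u3 < p_prox] = 0
        choice[three] = c3

    rts = rng.lognormal(mean=spec.rt_meanlog, sigma=spec.rt_sdlog,
                        size=(n_subj, n_items))
    layouts = rng.choice(["horizontal", "vertical"], size=(n_subj, n_items))

    labels = np.array(["proximal", "medial", "distal"])
    subject_ids = subjects["subject_id"].to_numpy()
    trials = pd.DataFrame({
        "subject_id": np.repeat(subject_ids, n_items),
        "item_id": np.tile(binder.index.to_numpy(), n_subj),
        "choice": labels[choice.ravel()],
        "rt_ms": np.round(rts.ravel(), 1),
        "button_layout": layouts.ravel(),
        "is_attention_check": False,
        "attention_passed": pd.NA,
    })

    # Attention checks: separate trials with a known correct answer; an
    # attentive subject passes each with p_check_pass.
    nc = spec.n_checks
    check_ids = [f"check_{i + 1:02d}" for i in range(nc)]
    passed = rng.uniform(size=(n_subj, nc)) < spec.p_check_pass
    # Attentive subjects never cross the >3-failures exclusion threshold:
    # excess failures are flipped so injected inattentive ids stay the exact
    # ground truth for QC recovery.
    over = (~passed).sum(axis=1) > 3
    for i in np.flatnonzero(over):
        fail_idx = np.flatnonzero(~passed[i])
        passed[i, fail_idx[: len(fail_idx) - 3]] = True
    check_rts = rng.lognormal(mean=spec.rt_meanlog, sigma=spec.rt_sdlog,
                              size=(n_subj, nc))
    check_choice = np.where(
        rng.uniform(size=(n_subj, nc)) < 0.5, "proximal", "distal")
    checks = pd.DataFrame({
        "subject_id": np.repeat(subject_ids, nc),
        "item_id": np.tile(np.array(check_ids), n_subj),
        "choice": check_choice.ravel(),
        "rt_ms": np.round(check_rts.ravel(), 1),
        "button_layout": rng.choice(["horizontal", "vertical"], size=n_subj * nc),
        "is_attention_check": True,
        "attention_passed": passed.ravel(),
    })
    out = pd.concat([trials, checks], ignore_index=True)
    out["attention_passed"] = out["attention_passed"].astype("boolean")
    return out.sort_values(["subject_id", "is_attention_check", "item_id"],
                           kind="stable", ignore_index=True)


def inject_low_effort(trials: pd.DataFrame, subjects: pd.DataFrame,
                      spec: SyntheticSpec) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Overwrite designated subjects' behavior with low-effort patterns.

    Fast responders get 15% of their RTs in 100-280 ms; constant responders
    answer one fixed form on 97% of non-check trials; inattentive subjects
    pass each check with the low pass rate (forced to at least 4 failures so
    the ground truth is unambiguous).  Returns the modified trials and the
    injected subject ids per behavior — the truth the QC stage is tested
    against.
    """
    rng = np.random.default_rng(child_seed(spec.seed, "inject"))
    trials = trials.copy()
    ids = subjects["subject_id"].to_numpy()
    n = len(ids)
    n_fast = int(round(spec.fast_responder_rate * n))
    n_const = int(round(spec.constant_responder_rate * n))
    n_inatt = int(round(spec.inattentive_rate * n))
    if n_fast + n_const + n_inatt > n:
        raise ValueError("low-effort rates sum to more than the cohort")
    picked = rng.choice(ids, size=n_fast + n_const + n_inatt, replace=False)
    fast = list(picked[:n_fast])
    const = list(picked[n_fast:n_fast + n_const])
    inatt = list(picked[n_fast + n_const:])

    is_check = trials["is_attention_check"].astype(bool).to_numpy()
    by_subject = trials["subject_id"].to_numpy()

    for sid in fast:
        idx = np.flatnonzero((by_subject == sid) & ~is_check)
        k = int(math.ceil(0.15 * len(idx)))
        sel = rng.choice(idx, size=k, replace=False)
        trials.loc[sel, "rt_ms"] = np.round(rng.uniform(100.0, 280.0, size=k), 1)

    terms = subjects.set_index("subject_id")["system_terms"]
    for sid in const:
        idx = np.flatnonzero((by_subject == sid) & ~is_check)
        forms = ["proximal", "distal"] if int(terms[sid]) == 2 else \
            ["proximal", "medial", "distal"]
        form = forms[int(rng.integers(len(forms)))]
        k = int(math.ceil(0.97 * len(idx)))
        sel = rng.choice(idx, size=k, replace=False)
        trials.loc[sel, "choice"] = form

    for sid in inatt:
        idx = np.flatnonzero((by_subject == sid) & is_check)
        passed = rng.uniform(size=len(idx)) < spec.p_check_pass_inattentive
        n_fail = int((~passed).sum())
        if n_fail < 4:  # guarantee > 3 failures for an unambiguous truth
            passed[: 4 - n_fail] = False
        trials.loc[idx, "attention_passed"] = passed
    trials["attention_passed"] = trials["attention_passed"].astype("boolean")

    truth = {"fast_responders": sorted(map(str, fast)),
             "constant_responders": sorted(map(str, const)),
             "inattentive": sorted(map(str, inatt))}
    return trials, truth


def simulate_study(spec: SyntheticSpec, validate: bool = True) -> tuple[Study, dict]:
    """Full cohort draw: Binder matrix, subjects, trials, optional injection.

    Returns the Study and a truth dict holding the planted effect vectors and
    the injected low-effort subject ids.
    """
    binder = generate_binder_matrix(spec.n_items, spec.seed)
    subjects = simulate_subjects(spec)
    trials = simulate_trials(subjects, binder, spec)
    truth: dict = {
        "beta_dep": dict(spec.beta_dep),
        "beta_ctrl": dict(spec.beta_ctrl),
        "injected": {"fast_responders": [], "constant_responders": [], "inattentive": []},
    }
    if spec.fast_responder_rate or spec.constant_responder_rate or spec.inattentive_rate:
        trials, injected = inject_low_effort(trials, subjects, spec)
        truth["injected"] = injected
    study = Study(trials=trials, subjects=subjects, binder=binder)
    if validate:
        validate_study(study)
    return study, truth
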