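"""Bootstrapped robustness and SHAP-based semantic-effect summaries.

Feature attributions come from the exact TreeSHAP algorithm built into
xgboost (``pred_contribs``): per test sample, per feature, the additive
contribution to the model's log-odds margin.  The headline per-feature
summary is oriented so that a positive value means *high scores on this
feature push predictions toward depression* — concretely, the mean SHAP
value among test samples whose (scaled) feature value lies above the
feature's median.  The plain mean and the mean |SHAP| ranking are also
emitted.

Robustness is assessed by re-splitting: each bootstrap run redraws the
stratified 70/30 split, rebalances, retrains the tuned configuration,
records test metrics and feature effects, and the aggregate gives the
distributional summaries (median, SD, central 95% interval) that the
per-feature effect plots and rank-correlation / clustering comparisons are
built from.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.stats import kendalltau, spearmanr
from xgboost import DMatrix, XGBClassifier

from .classify import (FittedModel, balance_by_downsampling,
                       evaluate_model, make_split, _fit_on)
from .core_io import child_seed


def shap_contributions(model: FittedModel, profiles_raw: pd.DataFrame
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Exact per-sample tree-path attributions and the model margins.

    Returns ``(contribs, margins)`` where ``contribs`` is (n_samples,
    n_features + 1) — the last column is the base value — and the rows sum
    to ``margins`` (the log-odds outputs) exactly, up to float tolerance.
    Only defined for the tree-ensemble candidate.
    """
    if not isinstance(model.estimator, XGBClassifier):
        raise TypeError(
            f"SHAP effects are defined for the tree ensemble, got {model.name!r}")
    X = model.scaler.transform(profiles_raw)
    dm = DMatrix(X.to_numpy(), feature_names=list(X.columns))
    booster = model.estimator.get_booster()
    contribs = booster.predict(dm, pred_contribs=True)
    margins = booster.predict(dm, output_margin=True)
    return np.asarray(contribs), np.asarray(margins)


def compute_feature_effects(model: FittedModel,
                            profiles_raw: pd.DataFrame) -> pd.DataFrame:
    """Per-feature signed effect summary over the given (test) samples.

    Columns: ``effect`` (mean SHAP among above-median samples; positive =
    high feature scores push toward depression), ``mean_shap`` (plain mean),
    ``mean_abs_shap`` (importance magnitude).
    """
    if len(profiles_raw) == 0:
        raise ValueError("empty sample set")
    contribs, _ = shap_contributions(model, profiles_raw)
    shap = contribs[:, :-1]
    X = model.scaler.transform(profiles_raw).to_numpy()
    n_feat = shap.shape[1]
    effect = np.zeros(n_feat)
    for j in range(n_feat):
        high = X[:, j] > np.median(X[:, j])
        if high.any():
            effect[j] = shap[high, j].mean()
    return pd.DataFrame(
        {"effect": effect, "mean_shap": shap.mean(axis=0),
         "mean_abs_shap": np.abs(shap).mean(axis=0)},
        index=pd.Index(profiles_raw.columns, name="feature"))


def bootstrap_run(profiles: pd.DataFrame, subjects: pd.DataFrame,
                  params: Mapping, n_runs: int, seed: int,
                  candidate: str = "tree_ensemble",
                  language: str | None = None
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-split / retrain / re-evaluate ``n_runs`` times.

    Each run draws a fresh stratified split from its own recorded child
    seed, downsamples the training partition, retrains the given (already
    tuned) configuration and evaluates on the new test set.  Returns
    ``(summary, effects)``: one summary row and one 65-feature oriented
    effect row per run.  A failing run is recorded with its error, never
    silently dropped.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be at least 2")
    if language is not None:
        keep = subjects["language"] == language
        subjects = subjects[keep].reset_index(drop=True)
        profiles = profiles.loc[subjects["subject_id"]]
    y = subjects.set_index("subject_id")["group"]

    summaries, effect_rows = [], []
    for r in range(n_runs):
        run_seed = child_seed(seed, "bootstrap", r)
        record: dict = {"run": r, "seed": run_seed, "status": "ok", "error": ""}
        try:
            split = make_split(subjects, run_seed)
            train_bal = balance_by_downsampling(
                split.train_ids, y, child_seed(run_seed, "bal"))
            est, scaler = _fit_on(candidate, params, profiles, y, train_bal,
                                  run_seed)
            model = FittedModel(name=candidate, params=dict(params),
                                estimator=est, scaler=scaler,
                                training_ids=list(train_bal))
            raw = evaluate_model(model, profiles, subjects, split.test_ids)
            bal = evaluate_model(model, profiles, subjects, split.test_ids,
                                 balance_seed=child_seed(run_seed, "eval_bal"))
            record.update({"f1": raw["f1"], "roc_auc": raw["roc_auc"],
                           "f1_balanced": bal["f1"],
                           "accuracy_balanced": bal["accuracy"]})
            effects = compute_feature_effects(
                model, profiles.loc[split.test_ids])["effect"]
            effect_rows.append(effects.rename(r))
        except Exception as exc:  # recorded, not dropped
            record.update({"status": "failed", "error": str(exc)})
        summaries.append(record)
    summary = pd.DataFrame(summaries)
    effects = pd.DataFrame(effect_rows)
    effects.index.name = "run"
    return summary, effects


def summarize_effects(effects: pd.DataFrame) -> pd.DataFrame:
    """Distribution summaries of per-run effects: one row per feature."""
    q = effects.quantile([0.025, 0.5, 0.975])
    out = pd.DataFrame({
        "mean": effects.mean(),
        "median": q.loc[0.5],
        "sd": effects.std(ddof=1),
        "q2.5": q.loc[0.025],
        "q97.5": q.loc[0.975],
    })
    out["sign"] = np.sign(out["mean"]).astype(int)
    out.index.name = "feature"
    return out


def correlate_effects(table_a: pd.Series | pd.DataFrame,
                      table_b: pd.Series | pd.DataFrame,
                      method: str = "spearman") -> float:
    """Rank correlation of two per-feature effect vectors.

    Accepts effect Series or summary frames (uses their ``mean`` column).
    Returns NaN when either vector has zero rank variance.
    """
    a = table_a["mean"] if isinstance(table_a, pd.DataFrame) else table_a
    b = table_b["mean"] if isinstance(table_b, pd.DataFrame) else table_b
    if list(a.index) != list(b.index):
        if set(a.index) != set(b.index):
            raise ValueError("effect tables cover different features")
        b = b.loc[a.index]
    av, bv = a.to_numpy(dtype=float), b.to_numpy(dtype=float)
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        return float("nan")
    if method == "spearman":
        return float(spearmanr(av, bv).statistic)
    if method == "kendall":
        return float(kendalltau(av, bv).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def pairwise_effect_correlations(tables: Mapping[str, pd.Series | pd.DataFrame],
                                 method: str = "spearman") -> pd.DataFrame:
    """Symmetric scope x scope rank-correlation matrix of mean effects."""
    names = list(tables)
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            r = correlate_effects(tables[a], tables[names[j]], method=method)
            out.iloc[i, j] = out.iloc[j, i] = r
    return out


def cluster_features(effect_matrix: pd.DataFrame
                     ) -> tuple[list[str], np.ndarray | None]:
    """Hierarchically cluster features by their effect vectors across scopes.

    ``effect_matrix`` is scopes x features (mean effects).  Average linkage
    on Euclidean distances; returns the deterministic leaf order and the
    linkage matrix (None for a single feature).
    """
    if effect_matrix.shape[0] < 2:
        raise ValueError("clustering needs at least two scopes")
    features = list(effect_matrix.columns)
    if len(features) == 1:
        return features, None
    vectors = effect_matrix.to_numpy(dtype=float).T
    linkage = sch.linkage(vectors, method="average", metric="euclidean")
    order = sch.leaves_list(linkage)
    return [features[i] for i in order], linkage
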