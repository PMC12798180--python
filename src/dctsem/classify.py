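"""Depression-vs-control classification from semantic profiles.

Pipeline: a 70/30 train/test split stratified by (group x language), with
20% of the training set held out as a validation set for hyperparameter
tuning; the training partition is downsampled to equal class counts
(anchoring chance accuracy at 0.5 on any balanced view); profiles are
z-scored with statistics fit on the balanced training rows only; five
candidate families are tuned by validation F1 and refit on the full
balanced training set; evaluation reports F1, ROC-AUC, precision, recall
and accuracy on the raw test set, on a class-balanced test view, and on
each language-specific test subset.  A label-shuffled baseline runs the
identical pipeline on permuted training labels to give an empirical null.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.metrics import (accuracy_score, f1_score, precision_score,
                             recall_score, roc_auc_score)
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from xgboost import XGBClassifier

from .core_io import child_seed
from .profiles import ProfileScaler

CANDIDATE_NAMES = ("ridge", "knn", "tree_ensemble", "nn2", "nn3")

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "ridge": {"C": [0.1, 1.0, 10.0]},
    "ridge_regression": {"alpha": [0.1, 1.0, 10.0]},
    "knn": {"n_neighbors": [5, 15], "leaf_size": [30], "weights": ["uniform", "distance"]},
    "tree_ensemble": {"n_estimators": [20, 50], "learning_rate": [0.1, 0.3],
                      "max_depth": [3, 6], "reg_alpha": [0.01], "reg_lambda": [0.001]},
    "nn2": {"batch_size": [32, 64], "epochs": [100]},
    "nn3": {"batch_size": [32, 64], "epochs": [100]},
}

#: A reasonable single configuration per candidate, used where a fit is
#: needed without tuning (e.g. repeated baseline runs).
DEFAULT_PARAMS: dict[str, dict] = {
    "ridge": {"C": 1.0},
    "ridge_regression": {"alpha": 1.0},
    "knn": {"n_neighbors": 5, "leaf_size": 30, "weights": "uniform"},
    "tree_ensemble": {"n_estimators": 50, "learning_rate": 0.1, "max_depth": 6,
                      "reg_alpha": 0.01, "reg_lambda": 0.001},
    "nn2": {"batch_size": 32, "epochs": 100},
    "nn3": {"batch_size": 32, "epochs": 100},
}


class _ThresholdedRidge:
    """Plain ridge regression on 0/1 labels, thresholded at 0.5.

    Variant reading of "Ridge Regression" for a binary outcome; the default
    candidate is L2-penalized logistic regression.
    """

    def __init__(self, alpha: float = 1.0):
        self._ridge = Ridge(alpha=alpha)

    def fit(self, X, y):
        self._ridge.fit(X, np.asarray(y, dtype=float))
        return self

    def decision_function(self, X):
        return self._ridge.predict(X) - 0.5

    def predict(self, X):
        return (self._ridge.predict(X) >= 0.5).astype(int)

    def predict_proba(self, X):
        p = np.clip(self._ridge.predict(X), 0.0, 1.0)
        return np.column_stack([1.0 - p, p])


def make_estimator(name: str, params: Mapping, seed: int = 0):
    """Instantiate a candidate with the given hyperparameters."""
    p = dict(params)
    if name == "ridge":
        return LogisticRegression(penalty="l2", C=p.get("C", 1.0),
                                  solver="lbfgs", max_iter=2000)
    if name == "ridge_regression":
        return _ThresholdedRidge(alpha=p.get("alpha", 1.0))
    if name == "knn":
        return KNeighborsClassifier(
            n_neighbors=p.get("n_neighbors", 5), leaf_size=p.get("leaf_size", 30),
            weights=p.get("weights", "uniform"))
    if name == "tree_ensemble":
        return XGBClassifier(
            n_estimators=p.get("n_estimators", 50),
            learning_rate=p.get("learning_rate", 0.1),
            max_depth=p.get("max_depth", 6),
            reg_alpha=p.get("reg_alpha", 0.01),
            reg_lambda=p.get("reg_lambda", 0.001),
            objective="binary:logistic", eval_metric="logloss",
            tree_method="hist", n_jobs=1,
            random_state=child_seed(seed, name))
    if name in ("nn2", "nn3"):
        hidden = (128, 64) if name == "nn2" else (128, 64, 32)
        return MLPClassifier(
            hidden_layer_sizes=hidden, activation="relu",
            batch_size=p.get("batch_size", 32), max_iter=p.get("epochs", 100),
            solver="adam", random_state=child_seed(seed, name))
    raise ValueError(f"unknown candidate {name!r}")


@dataclass
class Split:
    """Disjoint fit/validation/test subject-id lists plus the seed used."""

    fit_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    seed: int

    @property
    def train_ids(self) -> list[str]:
        return self.fit_ids + self.val_ids

    def assert_disjoint(self) -> None:
        sets = [set(self.fit_ids), set(self.val_ids), set(self.test_ids)]
        for a, b in itertools.combinations(sets, 2):
            if a & b:
                raise AssertionError("split partitions overlap")


def make_split(subjects: pd.DataFrame, seed: int, test_frac: float = 0.30,
               val_frac_of_train: float = 0.20,
               stratify_by: Sequence[str] = ("group", "language")) -> Split:
    """70/30 test split then 80/20 fit/validation, stratified by group x language."""
    strata = subjects[list(stratify_by)].astype(str).agg("|".join, axis=1)
    counts = strata.value_counts()
    empty = counts[counts < 2]
    if len(empty):
        raise ValueError(f"stratum too small to split: {empty.index[0]!r}")
    ids = subjects["subject_id"].to_numpy()
    train, test = train_test_split(
        ids, test_size=test_frac, stratify=strata,
        random_state=child_seed(seed, "split_test"))
    train_strata = strata[subjects["subject_id"].isin(train)]
    train_order = subjects.loc[subjects["subject_id"].isin(train), "subject_id"]
    fit, val = train_test_split(
        train_order.to_numpy(), test_size=val_frac_of_train,
        stratify=train_strata.to_numpy(),
        random_state=child_seed(seed, "split_val"))
    return Split(fit_ids=list(fit), val_ids=list(val), test_ids=list(test), seed=seed)


def balance_by_downsampling(ids: Sequence[str], groups: pd.Series,
                            seed: int) -> list[str]:
    """Equalize class counts: minority untouched, majority sampled without
    replacement.  ``groups`` maps subject_id -> 0/1."""
    ids = list(ids)
    y = groups.loc[ids]
    by_class = {g: [i for i in ids if y[i] == g] for g in (0, 1)}
    if not by_class[0] or not by_class[1]:
        missing = 0 if not by_class[0] else 1
        raise ValueError(f"class {missing} is empty; cannot balance")
    n_min = min(len(by_class[0]), len(by_class[1]))
    rng = np.random.default_rng(child_seed(seed, "downsample"))
    out: list[str] = []
    for g in (0, 1):
        members = by_class[g]
        if len(members) > n_min:
            members = list(rng.choice(members, size=n_min, replace=False))
        out.extend(members)
    return sorted(out)


@dataclass
class FittedModel:
    """A tuned candidate with its scaler and training provenance."""

    name: str
    params: dict
    estimator: object
    scaler: ProfileScaler
    training_ids: list[str] = field(default_factory=list)
    tuning_table: pd.DataFrame | None = None

    def predict_scores(self, profiles_raw: pd.DataFrame) -> np.ndarray:
        X = self.scaler.transform(profiles_raw).to_numpy()
        if hasattr(self.estimator, "predict_proba"):
            return np.asarray(self.estimator.predict_proba(X))[:, 1]
        return np.asarray(self.estimator.decision_function(X))

    def predict_labels(self, profiles_raw: pd.DataFrame) -> np.ndarray:
        X = self.scaler.transform(profiles_raw).to_numpy()
        return np.asarray(self.estimator.predict(X)).astype(int)


def _grid_entries(grid: Mapping[str, list]) -> list[dict]:
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def _fit_on(name: str, params: Mapping, profiles: pd.DataFrame, y: pd.Series,
            ids: Sequence[str], seed: int) -> tuple[object, ProfileScaler]:
    scaler = ProfileScaler.fit(profiles.loc[list(ids)])
    X = scaler.transform(profiles.loc[list(ids)]).to_numpy()
    est = make_estimator(name, params, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence chatter at small epoch counts
        est.fit(X, y.loc[list(ids)].to_numpy())
    return est, scaler


def tune_and_train(name: str, profiles: pd.DataFrame, subjects: pd.DataFrame,
                   split: Split, grids: Mapping[str, Mapping] | None = None,
                   seed: int = 0, objective: str = "f1") -> FittedModel:
    """Grid search on validation F1 (or ROC-AUC), then refit on fit+val.

    The fit partition is balanced by downsampling before every candidate
    fit; the validation set stays as drawn.  Ties in the argmax resolve to
    the earliest grid entry.  The final model is trained on the balanced
    full training set (fit + validation).
    """
    grid = dict((grids or DEFAULT_GRIDS)[name])
    entries = _grid_entries(grid)
    if not entries:
        raise ValueError(f"empty grid for candidate {name!r}")
    y = subjects.set_index("subject_id")["group"]
    fit_bal = balance_by_downsampling(split.fit_ids, y, child_seed(seed, "fit_bal"))

    records = []
    best_score, best_params = -np.inf, None
    for i, params in enumerate(entries):
        est, scaler = _fit_on(name, params, profiles, y, fit_bal, seed)
        Xv = scaler.transform(profiles.loc[split.val_ids]).to_numpy()
        yv = y.loc[split.val_ids].to_numpy()
        if objective == "f1":
            score = f1_score(yv, np.asarray(est.predict(Xv)).astype(int), zero_division=0)
        elif objective == "roc_auc":
            score = _roc_auc(est, Xv, yv)
        else:
            raise ValueError(f"unknown tuning objective {objective!r}")
        if not np.isfinite(score):
            raise ValueError(f"non-finite validation score for {name!r} params {params}")
        records.append({**params, "val_score": float(score)})
        if score > best_score:
            best_score, best_params = score, params

    train_bal = balance_by_downsampling(split.train_ids, y, child_seed(seed, "train_bal"))
    est, scaler = _fit_on(name, best_params, profiles, y, train_bal, seed)
    return FittedModel(name=name, params=dict(best_params), estimator=est,
                       scaler=scaler, training_ids=list(train_bal),
                       tuning_table=pd.DataFrame(records))


def _roc_auc(est, X, y) -> float:
    if len(np.unique(y)) < 2:
        return np.nan
    if hasattr(est, "predict_proba"):
        s = np.asarray(est.predict_proba(X))[:, 1]
    else:
        s = np.asarray(est.decision_function(X))
    return float(roc_auc_score(y, s))


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                    y_score: np.ndarray | None = None) -> dict[str, float]:
    """F1 / precision / recall / accuracy / ROC-AUC from predictions."""
    out = {
        "f1": float(f1_score(y_true, y_pred, zero_division=0)),
        "precision": float(precision_score(y_true, y_pred, zero_division=0)),
        "recall": float(recall_score(y_true, y_pred, zero_division=0)),
        "accuracy": float(accuracy_score(y_true, y_pred)),
    }
    if y_score is not None and len(np.unique(y_true)) == 2:
        out["roc_auc"] = float(roc_auc_score(y_true, y_score))
    else:
        out["roc_auc"] = np.nan
    return out


def evaluate_model(model: FittedModel, profiles: pd.DataFrame,
                   subjects: pd.DataFrame, ids: Sequence[str],
                   balance_seed: int | None = None) -> dict[str, float]:
    """Metrics on the given subject ids; optionally on a balanced subsample."""
    ids = list(ids)
    y = subjects.set_index("subject_id")["group"]
    if balance_seed is not None:
        ids = balance_by_downsampling(ids, y, balance_seed)
    P = profiles.loc[ids]
    return compute_metrics(y.loc[ids].to_numpy(),
                           model.predict_labels(P), model.predict_scores(P))


def evaluate_per_language(model: FittedModel, profiles: pd.DataFrame,
                          subjects: pd.DataFrame, split: Split,
                          balance_seed: int | None = None) -> pd.DataFrame:
    """Test-set metrics on the full test set and each language subset.

    Languages absent from the test set yield a row flagged ``absent`` rather
    than fabricated numbers.
    """
    subj = subjects.set_index("subject_id")
    test = [i for i in split.test_ids]
    rows = [{"subset": "full_test", "absent": False,
             **evaluate_model(model, profiles, subjects, test, balance_seed)}]
    for language in sorted(subjects["language"].unique()):
        lang_ids = [i for i in test if subj.loc[i, "language"] == language]
        if not lang_ids or len(set(subj.loc[lang_ids, "group"])) == 0:
            rows.append({"subset": language, "absent": True})
            continue
        try:
            metrics = evaluate_model(model, profiles, subjects, lang_ids,
                                     balance_seed)
        except ValueError:  # a class empty in this language's test subset
            rows.append({"subset": language, "absent": True})
            continue
        rows.append({"subset": language, "absent": False, **metrics})
    return pd.DataFrame(rows)


def shuffled_label_baseline(name: str, profiles: pd.DataFrame,
                            subjects: pd.DataFrame, split: Split,
                            seed: int, params: Mapping | None = None
                            ) -> dict[str, dict[str, float]]:
    """The empirical null: identical pipeline, permuted *training* labels.

    Labels are permuted uniformly at random among the training subjects
    only; the test labels are never touched.  Returns metrics on the raw
    test set and on a balanced test view.
    """
    y = subjects.set_index("subject_id")["group"].copy()
    rng = np.random.default_rng(child_seed(seed, "shuffle"))
    train = split.train_ids
    permuted = y.copy()
    permuted.loc[train] = rng.permutation(y.loc[train].to_numpy())
    assert (permuted.loc[split.test_ids] == y.loc[split.test_ids]).all()

    shuffled_subjects = subjects.copy()
    shuffled_subjects["group"] = shuffled_subjects["subject_id"].map(permuted)
    train_bal = balance_by_downsampling(
        train, permuted, child_seed(seed, "null_bal"))
    est, scaler = _fit_on(name, params or DEFAULT_PARAMS[name], profiles,
                          permuted, train_bal, seed)
    model = FittedModel(name=name, params=dict(params or DEFAULT_PARAMS[name]),
                        estimator=est, scaler=scaler, training_ids=list(train_bal))
    return {
        "raw": evaluate_model(model, profiles, subjects, split.test_ids),
        "balanced": evaluate_model(model, profiles, subjects, split.test_ids,
                                   balance_seed=child_seed(seed, "null_eval_bal")),
    }


def assert_no_leakage(model: FittedModel, split: Split) -> None:
    """Audit: no test subject entered fitting or scaling statistics."""
    leak = set(model.training_ids) & set(split.test_ids)
    if leak:
        raise AssertionError(f"test subjects leaked into training: {sorted(leak)[:5]}")


def run_comparison(profiles: pd.DataFrame, subjects: pd.DataFrame, seed: int,
                   candidates: Sequence[str] = CANDIDATE_NAMES,
                   grids: Mapping[str, Mapping] | None = None,
                   objective: str = "f1"
                   ) -> tuple[pd.DataFrame, dict[str, FittedModel], Split]:
    """Tune and evaluate every candidate on one shared split.

    Returns (comparison table, fitted models, split).  The table has one row
    per candidate x evaluation view (train / raw test / balanced test).
    """
    split = make_split(subjects, seed)
    split.assert_disjoint()
    rows = []
    models: dict[str, FittedModel] = {}
    for name in candidates:
        model = tune_and_train(name, profiles, subjects, split,
                               grids=grids, seed=seed, objective=objective)
        assert_no_leakage(model, split)
        models[name] = model
        views = {
            "train": evaluate_model(model, profiles, subjects, model.training_ids),
            "test": evaluate_model(model, profiles, subjects, split.test_ids),
            "test_balanced": evaluate_model(
                model, profiles, subjects, split.test_ids,
                balance_seed=child_seed(seed, "eval_bal")),
        }
        for view, metrics in views.items():
            rows.append({"candidate": name, "view": view, **metrics,
                         **{f"hp_{k}": v for k, v in model.params.items()}})
    return pd.DataFrame(rows), models, split
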