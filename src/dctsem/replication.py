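"""Replication arm: depression classification from PCA of raw responses.

Instead of Binder-feature profiles, the subjects x words response matrix
(+1/0/-1 coded choices) is reduced with centered PCA and the component
scores feed four logistic-regression variants:

* ``mDCT`` — component scores only,
* ``mDCT+GenderAge`` — component scores plus z-scored age and one-hot
  gender,
* ``mGenderAge`` — demographics only,
* ``mRandomBaseline`` — the mDCT inputs with training labels shuffled.

Each variant's accuracy is bootstrapped over re-drawn stratified splits
(training partition downsampled to balance, accuracy on a balanced test
view, so chance sits at 0.5).  Model coefficients in component space are
back-projected through the loadings to word space, ranking the words most
predictive of each group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression

from .classify import balance_by_downsampling, make_split
from .core_io import child_seed

VARIANTS = ("mDCT", "mDCT+GenderAge", "mGenderAge", "mRandomBaseline")


@dataclass
class PcRepresentation:
    """Centered PCA of the response matrix.

    ``loadings`` is words x components (orthonormal columns), ``scores`` is
    subjects x components, ``explained_variance_ratio`` is non-increasing.
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    explained_variance_ratio: np.ndarray
    mean: pd.Series

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def project(self, responses: pd.DataFrame) -> pd.DataFrame:
        centered = responses - self.mean
        return pd.DataFrame(centered.to_numpy() @ self.loadings.to_numpy(),
                            index=responses.index, columns=self.scores.columns)


def fit_pca(responses: pd.DataFrame,
            n_components: int | None = None,
            variance_target: float = 0.90) -> PcRepresentation:
    """Centered PCA keeping ``n_components`` or enough components to reach
    the cumulative explained-variance target (default 90%)."""
    n_subj, n_words = responses.shape
    if n_subj < 2 or n_words < 2:
        raise ValueError("PCA needs at least 2 subjects and 2 words")
    max_rank = min(n_subj, n_words)
    if n_components is not None and n_components > max_rank:
        raise ValueError(
            f"n_components={n_components} exceeds min(n_subjects, n_words)={max_rank}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(responses.to_numpy(dtype=float))
    if n_components is None:
        cum = np.cumsum(pca.explained_variance_ratio_)
        k = int(np.searchsorted(cum, variance_target) + 1)
        k = min(k, scores.shape[1])
        scores = scores[:, :k]
        components = pca.components_[:k]
        ratios = pca.explained_variance_ratio_[:k]
    else:
        components = pca.components_
        ratios = pca.explained_variance_ratio_
    cols = [f"PC{i + 1}" for i in range(components.shape[0])]
    return PcRepresentation(
        loadings=pd.DataFrame(components.T, index=responses.columns, columns=cols),
        scores=pd.DataFrame(scores, index=responses.index, columns=cols),
        explained_variance_ratio=np.asarray(ratios),
        mean=pd.Series(pca.mean_, index=responses.columns),
    )


def _design(variant: str, pc_scores: pd.DataFrame, demographics: pd.DataFrame
            ) -> pd.DataFrame:
    if variant in ("mDCT", "mRandomBaseline"):
        return pc_scores
    if variant == "mDCT+GenderAge":
        return pd.concat([pc_scores, demographics], axis=1)
    if variant == "mGenderAge":
        return demographics
    raise ValueError(f"unknown variant {variant!r}")


def _demographic_design(subjects: pd.DataFrame) -> pd.DataFrame:
    """One-hot gender (largest category as reference) + raw age.

    Age is z-scored with training statistics inside each fit.
    """
    subj = subjects.set_index("subject_id")
    counts = subj["gender"].value_counts()
    reference = counts.index[0]
    levels = [g for g in counts.index if g != reference]
    out = pd.DataFrame(index=subj.index)
    out["age"] = subj["age"].astype(float)
    for g in levels:
        out[f"gender_{g}"] = (subj["gender"] == g).astype(float)
    return out


@dataclass
class ReplicationResult:
    """Bootstrap accuracy per variant plus word-level back-projection."""

    metrics: pd.DataFrame          # variant x (mean, sd, ci_low, ci_high, n_boot)
    accuracies: pd.DataFrame       # run x variant
    pca: PcRepresentation
    coefficients: dict[str, np.ndarray]  # PC/feature-space coefs per DCT variant


def fit_variants(responses: pd.DataFrame, subjects: pd.DataFrame,
                 n_boot: int = 100, seed: int = 0,
                 n_components: int | None = None,
                 variance_target: float = 0.90) -> ReplicationResult:
    """Bootstrap the four logistic variants on re-drawn stratified splits."""
    subjects = subjects[subjects["subject_id"].isin(responses.index)].reset_index(drop=True)
    responses = responses.loc[subjects["subject_id"]]
    pca = fit_pca(responses, n_components=n_components,
                  variance_target=variance_target)
    demo = _demographic_design(subjects)
    degenerate = [c for c in demo.columns if demo[c].nunique() < 2]
    if degenerate:
        raise ValueError(f"degenerate predictor column(s): {degenerate}")
    y = subjects.set_index("subject_id")["group"]

    acc_rows = []
    coef_store: dict[str, np.ndarray] = {}
    for b in range(n_boot):
        run_seed = child_seed(seed, "replication", b)
        split = make_split(subjects, run_seed)
        train_bal = balance_by_downsampling(
            split.train_ids, y, child_seed(run_seed, "bal"))
        test_bal = balance_by_downsampling(
            split.test_ids, y, child_seed(run_seed, "test_bal"))
        row = {"run": b}
        for variant in VARIANTS:
            X = _design(variant, pca.scores, demo)
            Xtr, Xte = X.loc[train_bal].copy(), X.loc[test_bal].copy()
            if "age" in X.columns:
                mu, sd = Xtr["age"].mean(), Xtr["age"].std(ddof=0) or 1.0
                Xtr["age"] = (Xtr["age"] - mu) / sd
                Xte["age"] = (Xte["age"] - mu) / sd
            ytr = y.loc[train_bal].to_numpy()
            if variant == "mRandomBaseline":
                rng = np.random.default_rng(child_seed(run_seed, "shuffle"))
                ytr = rng.permutation(ytr)
            clf = LogisticRegression(max_iter=2000)
            clf.fit(Xtr.to_numpy(), ytr)
            row[variant] = float(
                (clf.predict(Xte.to_numpy()) == y.loc[test_bal].to_numpy()).mean())
            if b == 0 and variant in ("mDCT", "mDCT+GenderAge"):
                coef_store[variant] = clf.coef_.ravel().copy()
        acc_rows.append(row)

    acc = pd.DataFrame(acc_rows).set_index("run")
    metrics = pd.DataFrame({
        "mean_accuracy": acc.mean(),
        "sd": acc.std(ddof=1),
        "ci_low": acc.quantile(0.025),
        "ci_high": acc.quantile(0.975),
    })
    metrics["n_boot"] = n_boot
    metrics.index.name = "variant"
    return ReplicationResult(metrics=metrics, accuracies=acc, pca=pca,
                             coefficients=coef_store)


def top_predictive_words(pca: PcRepresentation, coefficients: np.ndarray,
                         k: int = 10) -> tuple[pd.Series, pd.Series]:
    """Back-project PC-space coefficients to word space and rank words.

    Word weights are ``loadings . coefficients`` (using only the PC block of
    the coefficient vector), so the word-space linear predictor reproduces
    the PC-space predictor exactly for every subject.  Returns
    ``(toward_depression, toward_control)`` — each a Series of the k
    largest-magnitude words in that direction.
    """
    n_pc = pca.n_components
    pc_coefs = np.asarray(coefficients)[:n_pc]
    weights = pd.Series(pca.loadings.to_numpy() @ pc_coefs,
                        index=pca.loadings.index, name="weight")
    if k > len(weights):
        raise ValueError(f"k={k} exceeds vocabulary size {len(weights)}")
    toward_dep = weights.sort_values(ascending=False).head(k)
    toward_ctrl = weights.sort_values(ascending=True).head(k)
    return toward_dep, toward_ctrl
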