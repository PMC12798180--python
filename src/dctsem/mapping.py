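"""Extrapolating Binder scores for unrated words from embedding vectors.

Most DCT items have no human Binder ratings, so scores are predicted from
word embeddings: several regression families are trained to map an
embedding vector to all 65 Binder dimensions (words that appear in the task
are excluded from training to avoid leakage), each candidate is scored by
mean R² across the 65 dimensions on a held-out split of the rated words,
and the best candidate predicts scores for the task items.

The default roster holds six candidates: ordinary linear regression, ridge
regression, k-nearest-neighbor regression, a boosted-tree multi-output
model, and 2- and 3-layer feed-forward networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.metrics import r2_score
from sklearn.model_selection import train_test_split
from sklearn.multioutput import MultiOutputRegressor
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from xgboost import XGBRegressor

from .core_io import child_seed
from .features import BINDER_FEATURES

MIN_TRAINING_WORDS = 20


def read_embeddings(path: str | Path) -> pd.DataFrame:
    """Read the common text dialect: one word per line, then its vector."""
    words, vectors = [], []
    dim = None
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split()
            if not parts:
                continue
            word, values = parts[0], parts[1:]
            if dim is None:
                dim = len(values)
            elif len(values) != dim:
                raise ValueError(
                    f"line {line_no}: vector of length {len(values)}, expected {dim}")
            words.append(word)
            vectors.append(np.asarray(values, dtype=float))
    return pd.DataFrame(np.vstack(vectors), index=pd.Index(words, name="word"))


def default_roster(seed: int) -> dict[str, Callable[[], object]]:
    """Six candidate families for the embedding -> Binder mapping."""
    return {
        "linear": lambda: LinearRegression(),
        "ridge": lambda: Ridge(alpha=1.0, random_state=child_seed(seed, "ridge")),
        "knn": lambda: KNeighborsRegressor(n_neighbors=5),
        "boosted_trees": lambda: MultiOutputRegressor(XGBRegressor(
            n_estimators=50, max_depth=3, learning_rate=0.2,
            tree_method="hist", n_jobs=1,
            random_state=child_seed(seed, "boost"))),
        "nn2": lambda: MLPRegressor(
            hidden_layer_sizes=(128, 64), activation="relu", max_iter=400,
            random_state=child_seed(seed, "nn2")),
        "nn3": lambda: MLPRegressor(
            hidden_layer_sizes=(128, 64, 32), activation="relu", max_iter=400,
            random_state=child_seed(seed, "nn3")),
    }


@dataclass
class MappingResult:
    """Outcome of the roster comparison.

    ``mean_r2`` maps candidate name to held-out mean R² over the 65
    dimensions; ``selected`` is the argmax; ``model`` is the winning
    estimator refit on all training words; ``training_words`` records the
    exact words seen during fitting (for the leakage audit).
    """

    mean_r2: dict[str, float]
    selected: str
    model: object
    training_words: list[str]

    def audit_exclusion(self, exclude_items: Sequence[str]) -> None:
        overlap = set(self.training_words) & set(exclude_items)
        if overlap:
            raise AssertionError(f"excluded items leaked into training: {sorted(overlap)[:5]}")


def fit_mapping_candidates(embeddings: pd.DataFrame, norm_table: pd.DataFrame,
                           exclude_items: Sequence[str],
                           roster: Mapping[str, Callable[[], object]] | None = None,
                           seed: int = 0, holdout_frac: float = 0.2) -> MappingResult:
    """Train each roster candidate and select the best by held-out mean R².

    ``norm_table`` holds the rated words (rows) x 65 Binder dimensions;
    rows named in ``exclude_items`` are removed before any fitting.  The
    remaining words are split 80/20 (seeded); candidates are scored on the
    20% and the winner is refit on all retained words.
    """
    roster = dict(roster) if roster is not None else default_roster(seed)
    if not roster:
        raise ValueError("candidate roster is empty")
    keep = [w for w in norm_table.index if w not in set(exclude_items)]
    if len(keep) < MIN_TRAINING_WORDS:
        raise ValueError(
            f"only {len(keep)} training words after exclusion "
            f"(need >= {MIN_TRAINING_WORDS})")
    table = norm_table.loc[keep]
    missing = [w for w in keep if w not in embeddings.index]
    if missing:
        raise ValueError(f"words without embeddings: {missing[:5]}")
    X = embeddings.loc[keep].to_numpy(dtype=float)
    Y = table.to_numpy(dtype=float)

    idx_train, idx_val = train_test_split(
        np.arange(len(keep)), test_size=holdout_frac,
        random_state=child_seed(seed, "mapping_split"))
    scores: dict[str, float] = {}
    for name, make in roster.items():
        est = make()
        est.fit(X[idx_train], Y[idx_train])
        pred = est.predict(X[idx_val])
        scores[name] = float(r2_score(Y[idx_val], pred, multioutput="uniform_average"))
        if not np.isfinite(scores[name]):
            raise ValueError(f"non-finite validation R2 for candidate {name!r}")
    selected = max(scores, key=lambda k: (scores[k], -list(scores).index(k)))
    final = roster[selected]()
    final.fit(X, Y)
    return MappingResult(mean_r2=scores, selected=selected, model=final,
                         training_words=list(keep))


def predict_binder_scores(result: MappingResult, words: Sequence[str],
                          embeddings: pd.DataFrame) -> pd.DataFrame:
    """Predict a 65-dimensional Binder vector for each word, order preserved."""
    missing = [w for w in words if w not in embeddings.index]
    if missing:
        raise ValueError(f"words without embeddings: {missing}")
    X = embeddings.loc[list(words)].to_numpy(dtype=float)
    pred = np.asarray(result.model.predict(X), dtype=float)
    return pd.DataFrame(pred, index=pd.Index(list(words), name="item_id"),
                        columns=list(BINDER_FEATURES))


def synthetic_embedding_fixture(n_words: int = 200, dim: int = 50, seed: int = 0,
                                noise_sd: float = 0.0
                                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic embeddings plus norms generated by a planted linear map.

    A stand-in for rated-word data at desk scale: Gaussian embedding vectors
    and a norms table constructed as ``norms = E . W + noise`` for a fixed
    random W, so a linear candidate can recover the mapping exactly when
    ``noise_sd`` is 0.  Returns (embeddings, norm_table).
    """
    rng = np.random.default_rng(child_seed(seed, "emb_fixture"))
    words = [f"w{i:04d}" for i in range(n_words)]
    E = rng.normal(size=(n_words, dim))
    W = rng.normal(scale=0.5, size=(dim, len(BINDER_FEATURES)))
    Y = 3.0 + E @ W
    if noise_sd > 0:
        Y = Y + rng.normal(scale=noise_sd, size=Y.shape)
    embeddings = pd.DataFrame(E, index=pd.Index(words, name="word"))
    norms = pd.DataFrame(Y, index=pd.Index(words, name="word"),
                         columns=list(BINDER_FEATURES))
    return embeddings, norms
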