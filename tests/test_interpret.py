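import numpy as np
import pandas as pd
import pytest

from dctsem import classify as clf
from dctsem import interpret as interp

from test_classify import separable_profiles, single_stratum_subjects


@pytest.fixture(scope="module")
def fitted_tree():
    subjects = single_stratum_subjects(200)
    profiles = separable_profiles(subjects, gap=4.0)
    split = clf.make_split(subjects, seed=0)
    model = clf.tune_and_train(
        "tree_ensemble", profiles, subjects, split,
        grids={"tree_ensemble": {"n_estimators": [30], "learning_rate": [0.2],
                                 "max_depth": [4], "reg_alpha": [0.01],
                                 "reg_lambda": [0.001]}}, seed=0)
    return model, profiles, subjects, split


class TestFeatureEffects:
    def test_local_additivity_to_model_margin(self, fitted_tree):
        model, profiles, _, split = fitted_tree
        contribs, margins = interp.shap_contributions(
            model, profiles.loc[split.test_ids])
        # 1e-6 at unit scale; scaled by margin magnitude where it exceeds
        # float32 representation precision
        tol = 1e-6 * max(1.0, float(np.abs(margins).max()))
        assert np.abs(contribs.sum(axis=1) - margins).max() < tol

    def test_planted_feature_has_largest_effect(self, fitted_tree):
        """Labels are driven by feature f0 alone: it must dominate and its
        high values must push toward depression (positive effect)."""
        model, profiles, _, split = fitted_tree
        effects = interp.compute_feature_effects(model, profiles.loc[split.test_ids])
        assert effects["effect"].abs().idxmax() == "f0"
        assert effects.loc["f0", "effect"] > 0

    def test_constant_feature_has_zero_effect(self):
        subjects = single_stratum_subjects(120)
        profiles = separable_profiles(subjects, gap=4.0)
        profiles["f64"] = 2.5  # constant
        split = clf.make_split(subjects, seed=1)
        model = clf.tune_and_train(
            "tree_ensemble", profiles, subjects, split,
            grids={"tree_ensemble": {"n_estimators": [20], "learning_rate": [0.2],
                                     "max_depth": [3], "reg_alpha": [0.01],
                                     "reg_lambda": [0.001]}}, seed=1)
        effects = interp.compute_feature_effects(model, profiles.loc[split.test_ids])
        assert effects.loc["f64", "effect"] == 0.0
        assert effects.loc["f64", "mean_abs_shap"] == 0.0

    def test_non_tree_model_is_rejected(self, fitted_tree):
        _, profiles, subjects, split = fitted_tree
        ridge = clf.tune_and_train("ridge", profiles, subjects, split,
                                   grids={"ridge": {"C": [1.0]}}, seed=0)
        with pytest.raises(TypeError, match="tree"):
            interp.shap_contributions(ridge, profiles.loc[split.test_ids])


class TestBootstrap:
    def test_cardinality_and_determinism(self, fitted_tree):
        model, profiles, subjects, _ = fitted_tree
        s1, e1 = interp.bootstrap_run(profiles, subjects, model.params,
                                      n_runs=10, seed=4)
        s2, e2 = interp.bootstrap_run(profiles, subjects, model.params,
                                      n_runs=10, seed=4)
        assert len(s1) == 10 and e1.shape == (10, 65)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(e1, e2)
        assert (s1["status"] == "ok").all()
        assert s1["seed"].is_unique

    def test_failed_runs_recorded_not_dropped(self, fitted_tree):
        model, profiles, subjects, _ = fitted_tree
        # a singleton stratum makes every split draw fail
        broken = subjects.copy()
        broken.loc[0, "language"] = "Russian"
        summary, effects = interp.bootstrap_run(profiles, broken, model.params,
                                                n_runs=3, seed=0)
        assert len(summary) == 3
        assert (summary["status"] == "failed").all()
        assert summary["error"].str.len().gt(0).all()

    def test_rejects_single_run(self, fitted_tree):
        model, profiles, subjects, _ = fitted_tree
        with pytest.raises(ValueError):
            interp.bootstrap_run(profiles, subjects, model.params, n_runs=1, seed=0)


class TestEffectCorrelation:
    def test_self_and_negation(self):
        rng = np.random.default_rng(0)
        eff = pd.Series(rng.normal(size=65), index=[f"f{i}" for i in range(65)])
        assert interp.correlate_effects(eff, eff) == pytest.approx(1.0)
        assert interp.correlate_effects(eff, -eff) == pytest.approx(-1.0)

    def test_zero_variance_reported_absent(self):
        flat = pd.Series(np.zeros(10), index=[f"f{i}" for i in range(10)])
        other = pd.Series(np.arange(10.0), index=flat.index)
        assert np.isnan(interp.correlate_effects(flat, other))

    def test_pairwise_matrix_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(1)
        idx = [f"f{i}" for i in range(20)]
        tables = {k: pd.Series(rng.normal(size=20), index=idx)
                  for k in ("full", "de", "it")}
        M = interp.pairwise_effect_correlations(tables)
        assert np.allclose(M, M.T)
        assert np.allclose(np.diag(M), 1.0)

    def test_shared_planted_structure_correlates_positively(self):
        rng = np.random.default_rng(2)
        idx = [f"f{i}" for i in range(65)]
        planted = np.zeros(65)
        planted[:10] = [1, 1, 1, 1, 1, -1, -1, -1, -1, -1]
        a = pd.Series(planted + 0.3 * rng.normal(size=65), index=idx)
        b = pd.Series(planted + 0.3 * rng.normal(size=65), index=idx)
        assert interp.correlate_effects(a, b) > 0


class TestFeatureClustering:
    def test_two_block_fixture_separates_at_top_split(self):
        """Features split into +1 and -1 blocks across scopes: the top merge
        joins the two blocks, so each block occupies contiguous leaves."""
        features = [f"f{i}" for i in range(10)]
        block = np.array([1.0] * 5 + [-1.0] * 5)
        rng = np.random.default_rng(3)
        M = pd.DataFrame([block + 0.05 * rng.normal(size=10) for _ in range(4)],
                         columns=features)
        order, linkage = interp.cluster_features(M)
        signs = [1 if f in features[:5] else -1 for f in order]
        flips = sum(a != b for a, b in zip(signs, signs[1:]))
        assert flips == 1  # contiguous blocks
        assert linkage is not None

    def test_identical_effects_are_adjacent_leaves(self):
        features = ["a", "b", "c"]
        M = pd.DataFrame([[0.0, 5.0, 0.0], [0.1, 5.0, 0.1]], columns=features)
        order, _ = interp.cluster_features(M)
        # a and c (identical-ish) must be adjacent, b apart
        assert abs(order.index("a") - order.index("c")) == 1

    def test_single_feature_is_trivial(self):
        M = pd.DataFrame({"only": [0.2, 0.4]})
        order, linkage = interp.cluster_features(M)
        assert order == ["only"] and linkage is None

    def test_single_scope_rejected(self):
        M = pd.DataFrame({"a": [0.1], "b": [0.2]})
        with pytest.raises(ValueError):
            interp.cluster_features(M)


def test_effect_summaries_consistent_with_distributions(fitted_tree):
    model, profiles, subjects, _ = fitted_tree
    _, effects = interp.bootstrap_run(profiles, subjects, model.params,
                                      n_runs=8, seed=6)
    table = interp.summarize_effects(effects)
    assert len(table) == 65
    assert (table["q2.5"] <= table["median"]).all()
    assert (table["median"] <= table["q97.5"]).all()
    f = effects.columns[0]
    assert table.loc[f, "mean"] == pytest.approx(effects[f].mean())
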