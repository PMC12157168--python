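import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from formubo.attribution import (
    global_shap,
    permutation_importance,
    select_features,
    shap_dependence,
    shap_exact,
    shap_sampled,
    wrapper_elimination,
)
from formubo.design import DesignSpace, FeatureSpec
from formubo.models import LinearModelSpec, TreeEnsembleSpec, fit_model
from formubo.synthetic import generate_dataset, reduced_landscape, sample_design
from tests.conftest import make_dataset


class _Additive:
    def __init__(self, coeffs, names=None):
        self.coeffs = np.asarray(coeffs, dtype=float)
        self.feature_names = names or [f"x{i}" for i in range(len(coeffs))]

    def predict(self, X):
        X = X[self.feature_names].to_numpy(dtype=float) if isinstance(X, pd.DataFrame) \
            else np.asarray(X, dtype=float)
        return X @ self.coeffs


def permutation_enumeration_oracle(model, x, B):
    """Average marginal contribution over all M! orderings — the definition."""
    M = len(x)
    phi = np.zeros(M)
    base = model.predict(B).mean()
    for perm in itertools.permutations(range(M)):
        z = B.copy()
        prev = base
        for i in perm:
            z = z.copy()
            z[:, i] = x[i]
            v = model.predict(z).mean()
            phi[i] += v - prev
            prev = v
    return phi / math.factorial(M)


class TestShapExact:
    def test_additive_model_closed_form(self):
        rng = np.random.default_rng(0)
        coeffs = np.array([2.0, -1.0, 0.5, 0.0])
        model = _Additive(coeffs)
        B = rng.random((40, 4))
        x = rng.random(4)
        exp = shap_exact(model, x, B)
        np.testing.assert_allclose(exp.phi, coeffs * (x - B.mean(axis=0)), atol=1e-8)

    def test_zero_coefficient_feature_gets_zero_phi(self):
        model = _Additive([1.0, 0.0])
        B = np.random.default_rng(1).random((20, 2))
        exp = shap_exact(model, np.array([0.3, 0.9]), B)
        assert exp.phi[1] == pytest.approx(0.0, abs=1e-12)

    def test_efficiency_to_1e6(self):
        rng = np.random.default_rng(2)
        X, y = rng.random((40, 3)), rng.normal(size=40)
        model = fit_model(TreeEnsembleSpec.extra_trees(seed=0, n_estimators=10), X, y)
        B = X[:15]
        for x in X[:5]:
            exp = shap_exact(model, x, B)
            assert exp.prediction == pytest.approx(float(model.predict(x[None, :])[0]),
                                                   abs=1e-6)

    @pytest.mark.parametrize("m_features", [3, 5])
    def test_matches_permutation_enumeration_oracle(self, m_features):
        rng = np.random.default_rng(4)
        X = rng.random((30, m_features))
        y = rng.normal(size=30)
        for model in (fit_model(TreeEnsembleSpec.extra_trees(seed=1, n_estimators=8), X, y),
                      fit_model(LinearModelSpec(), X, y)):
            x = rng.random(m_features)
            B = X[:8]
            exp = shap_exact(model, x, B)
            oracle = permutation_enumeration_oracle(model, x, B)
            np.testing.assert_allclose(exp.phi, oracle, atol=1e-8)

    def test_symmetric_features_get_equal_phi(self):
        model = _Additive([1.5, 1.5])
        B = np.tile(np.array([[0.2, 0.2], [0.6, 0.6]]), (3, 1))
        exp = shap_exact(model, np.array([0.8, 0.8]), B)
        assert exp.phi[0] == pytest.approx(exp.phi[1], abs=1e-6)

    def test_refuses_more_than_14_features(self):
        model = _Additive(np.ones(15))
        with pytest.raises(ValueError, match="shap_sampled"):
            shap_exact(model, np.zeros(15), np.zeros((3, 15)))


class TestShapSampled:
    def test_agrees_with_exact_on_m10_fixture(self):
        rng = np.random.default_rng(5)
        X, y = rng.random((60, 10)), rng.normal(size=60)
        model = fit_model(TreeEnsembleSpec.extra_trees(seed=2, n_estimators=10), X, y)
        B = X[:20]
        x = X[0]
        exact = shap_exact(model, x, B)
        sampled = shap_sampled(model, x, B, n_permutations=2000, seed=0)
        tol = 0.05 * np.abs(exact.phi).max()
        np.testing.assert_allclose(sampled.phi, exact.phi, atol=tol)

    def test_same_seed_identical_output(self):
        model = _Additive([1.0, -2.0, 0.5])
        B = np.random.default_rng(6).random((10, 3))
        x = np.array([0.1, 0.5, 0.9])
        a = shap_sampled(model, x, B, n_permutations=16, seed=3)
        b = shap_sampled(model, x, B, n_permutations=16, seed=3)
        np.testing.assert_array_equal(a.phi, b.phi)

    def test_single_permutation_obeys_efficiency_exactly(self):
        rng = np.random.default_rng(7)
        X, y = rng.random((30, 4)), rng.normal(size=30)
        model = fit_model(TreeEnsembleSpec.extra_trees(seed=3, n_estimators=5), X, y)
        exp = shap_sampled(model, X[0], X[:10], n_permutations=1, seed=1)
        assert exp.prediction == pytest.approx(float(model.predict(X[:1])[0]), abs=1e-9)

    def test_invalid_permutation_count(self):
        with pytest.raises(ValueError):
            shap_sampled(_Additive([1.0]), np.zeros(1), np.zeros((2, 1)), n_permutations=0)


class TestGlobalShap:
    def test_single_read_feature_tops_ranking(self):
        model = _Additive([3.0, 0.0, 0.0])
        X = np.random.default_rng(8).random((25, 3))
        ranking = global_shap(model, X, mode="exact")
        assert ranking.ordering[0] == "x0"
        assert ranking.mean_abs_phi[["x1", "x2"]].max() == pytest.approx(0.0, abs=1e-10)

    def test_duplicate_rows_do_not_change_ranking(self):
        rng = np.random.default_rng(9)
        model = _Additive([2.0, -1.0])
        X = rng.random((15, 2))
        r1 = global_shap(model, X, background=X, mode="exact")
        r2 = global_shap(model, np.vstack([X, X]), background=X, mode="exact")
        assert r1.ordering == r2.ordering
        np.testing.assert_allclose(r1.mean_abs_phi.to_numpy(),
                                   r2.mean_abs_phi.to_numpy(), rtol=1e-9)


class TestShapDependence:
    @pytest.fixture(scope="class")
    def landscape_fit(self):
        land = reduced_landscape()
        design = sample_design(land.space, 150, "latin", seed=0)
        ds = generate_dataset(land.oracle(0), design, replicates=1, seed=0,
                              response_name="titer_loss", space=land.space)
        names = land.space.names
        model = fit_model(TreeEnsembleSpec.gradient_boosted(seed=0),
                          ds.frame[names], ds.y, feature_names=names)
        return land, ds, model

    def test_monotone_effect_has_high_spearman(self, landscape_fit):
        land, ds, model = landscape_fit
        dep = shap_dependence(model, ds, None, "excipient_a", mode="exact")
        rho = spearmanr(dep["value"], dep["phi"]).statistic
        assert rho >= 0.8

    def test_saturating_effect_flat_beyond_knee(self, landscape_fit):
        """Beyond the spiked-rHSA knee the dependence is a plateau: phi range
        there under 20% of the total phi range, and its level differs from
        the sub-knee mean."""
        land, ds, model = landscape_fit
        dep = shap_dependence(model, ds, None, "spiked_rhsa", mode="exact")
        knee = land.params.spiked_knee
        above = dep[dep["value"] > 1.2 * knee]["phi"]
        below = dep[dep["value"] < 0.8 * knee]["phi"]
        total_range = dep["phi"].max() - dep["phi"].min()
        assert (above.max() - above.min()) < 0.2 * total_range
        assert abs(above.mean() - below.mean()) > 0.1 * total_range

    def test_unknown_feature_rejected(self, landscape_fit):
        _, ds, model = landscape_fit
        with pytest.raises(ValueError):
            shap_dependence(model, ds, None, "ghost")


class TestSelectFeatures:
    def _ranking(self, values):
        s = pd.Series(values).sort_values(ascending=False)
        from formubo.attribution import GlobalShapRanking

        return GlobalShapRanking(mean_abs_phi=s, phi_matrix=np.zeros((1, len(s))),
                                 feature_names=list(values), instance_index=np.array([0]))

    def test_equal_importance_keeps_all(self):
        r = self._ranking({"a": 1.0, "b": 1.0, "c": 1.0})
        assert select_features(r, 0.05) == ["a", "b", "c"]

    def test_threshold_near_one_keeps_only_top(self):
        r = self._ranking({"a": 1.0, "b": 0.5, "c": 0.2})
        assert select_features(r, 0.99) == ["a"]

    def test_never_empty(self):
        r = self._ranking({"a": 0.0, "b": 0.0})
        assert len(select_features(r, 0.5)) >= 1

    def test_designed_features_outrank_nulls_on_synthetic_screen(self):
        """On the 19-feature screen, every designed effect outranks every
        null feature (the separation behind the 19->9 pruning)."""
        from formubo.benchmarks import feature_recovery_trial

        hits = sum(feature_recovery_trial(seed)["rank_separated"] for seed in range(3))
        assert hits >= 2


class TestWrapper:
    @pytest.fixture(scope="class")
    def screen(self):
        land = reduced_landscape()
        design = sample_design(land.space, 150, "latin", seed=1)
        ds = generate_dataset(land.oracle(1), design, replicates=1, seed=1,
                              response_name="titer_loss", space=land.space)
        return land, ds

    def test_group_removal_equals_joint_member_removal(self, screen):
        land, ds = screen
        spec = TreeEnsembleSpec.extra_trees(seed=0)
        rep = wrapper_elimination(spec, ds, groups=[["residual_rhsa", "spiked_rhsa"]], seed=0)
        from formubo.evaluation import kfold_cv

        remaining = [n for n in land.space.names
                     if n not in ("residual_rhsa", "spiked_rhsa")]
        manual = kfold_cv(spec, ds, k=5, seed=0, feature_names=remaining)
        assert rep.rows.iloc[0]["r2"] == pytest.approx(manual.r2, rel=1e-12)

    def test_identical_folds_across_rows(self, screen):
        _, ds = screen
        rep = wrapper_elimination(TreeEnsembleSpec.extra_trees(seed=0), ds, seed=0)
        assert rep.baseline.seed == 0 and (rep.rows["delta_r2"].diff().dropna() <= 1e-12).all()

    def test_removing_all_features_rejected(self, screen):
        land, ds = screen
        with pytest.raises(ValueError, match="all features"):
            wrapper_elimination(TreeEnsembleSpec.extra_trees(seed=0), ds,
                                groups=[list(land.space.names)], seed=0)

    def test_null_feature_removal_barely_moves_r2(self):
        from formubo.synthetic import screening_landscape

        land = screening_landscape()
        design = sample_design(land.space, 100, "latin", seed=2)
        ds = generate_dataset(land.oracle(2), design, replicates=1, seed=2,
                              response_name="titer_loss", space=land.space)
        rep = wrapper_elimination(TreeEnsembleSpec.extra_trees(seed=0), ds,
                                  groups=[["null_1"]], seed=0)
        assert abs(rep.rows.iloc[0]["delta_r2"]) <= 0.05


class TestPermutationImportance:
    def test_unread_feature_degrades_exactly_zero(self):
        model = _Additive([1.0, 0.0])
        rng = np.random.default_rng(10)
        space = DesignSpace([FeatureSpec("x0", 0, 1), FeatureSpec("x1", 0, 1)])
        X = rng.random((40, 2))
        ds = make_dataset(space, X, X[:, 0])
        rep = permutation_importance(model, ds, n_repeats=5, seed=0)
        row = rep.rows[rep.rows["feature"] == "x1"].iloc[0]
        assert row["mean_degradation"] == 0.0 and row["sd_degradation"] == 0.0

    def test_dominant_feature_degrades_most(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            space = DesignSpace([FeatureSpec("x0", 0, 1), FeatureSpec("x1", 0, 1)])
            X = rng.random((80, 2))
            y = 3.0 * X[:, 0] + 0.3 * X[:, 1] + rng.normal(0, 0.1, 80)
            ds = make_dataset(space, X, y)
            model = fit_model(LinearModelSpec(), X, y, feature_names=["x0", "x1"])
            rep = permutation_importance(model, ds, n_repeats=5, seed=seed)
            hits += rep.rows.iloc[0]["feature"] == "x0"
        assert hits >= 9

    def test_same_seed_identical_report(self, small_dataset):
        model = fit_model(TreeEnsembleSpec.extra_trees(seed=0),
                          small_dataset.X(), small_dataset.y,
                          feature_names=small_dataset.design_space.names)
        r1 = permutation_importance(model, small_dataset, n_repeats=3, seed=2)
        r2 = permutation_importance(model, small_dataset, n_repeats=3, seed=2)
        pd.testing.assert_frame_equal(r1.rows, r2.rows)
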