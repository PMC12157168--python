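import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from formubo.synthetic import (
    TgMixtureParams,
    TiterLandscapeParams,
    screening_landscape,
    tg_mixture,
    generate_dataset,
    reduced_landscape,
    sample_design,
    tg_truth,
    titer_loss_truth,
)


def _ref(land, **over):
    """Reference formulation: every effect at its zero-contribution value."""
    base = {n: 0.0 for n in land.space.names}
    if land.params.quadratic_feature is not None:
        name, opt, _ = land.params.quadratic_feature
        base[name] = opt
    base.update(over)
    return base


class TestTiterTruth:
    def test_baseline_at_reference_zero(self):
        land = reduced_landscape()
        f = _ref(land)
        assert float(titer_loss_truth(land.params, f)) == pytest.approx(
            land.params.baseline_loss)

    def test_residual_plateau_beyond_knee(self):
        land = reduced_landscape()
        knee = land.params.residual_knee
        at_knee = float(titer_loss_truth(land.params, _ref(land, residual_rhsa=knee)))
        past_knee = float(titer_loss_truth(land.params, _ref(land, residual_rhsa=2 * knee)))
        assert at_knee == pytest.approx(past_knee)

    def test_residual_effect_magnitude_exact(self):
        land = reduced_landscape()
        knee = land.params.residual_knee
        at_zero = float(titer_loss_truth(land.params, _ref(land)))
        at_knee = float(titer_loss_truth(land.params, _ref(land, residual_rhsa=knee)))
        assert at_zero - at_knee == pytest.approx(land.params.residual_effect)

    def test_spiked_plateau_beyond_knee(self):
        land = reduced_landscape()
        knee = land.params.spiked_knee
        a = float(titer_loss_truth(land.params, _ref(land, spiked_rhsa=knee)))
        b = float(titer_loss_truth(land.params, _ref(land, spiked_rhsa=2 * knee)))
        assert a == pytest.approx(b)

    def test_missing_feature_rejected(self):
        land = reduced_landscape()
        with pytest.raises(KeyError):
            titer_loss_truth(land.params, {"residual_rhsa": 0.1})

    @settings(deadline=None, max_examples=40)
    @given(st.floats(0.0, 0.55), st.floats(0.01, 0.05))
    def test_monotone_nonincreasing_in_residual(self, c, dc):
        land = reduced_landscape()
        lo = float(titer_loss_truth(land.params, _ref(land, residual_rhsa=c)))
        hi = float(titer_loss_truth(land.params, _ref(land, residual_rhsa=c + dc)))
        assert hi <= lo + 1e-12

    @settings(deadline=None, max_examples=40)
    @given(st.floats(0.0, 4.5), st.floats(0.01, 0.4))
    def test_monotone_nondecreasing_in_spiked(self, c, dc):
        land = reduced_landscape()
        lo = float(titer_loss_truth(land.params, _ref(land, spiked_rhsa=c)))
        hi = float(titer_loss_truth(land.params, _ref(land, spiked_rhsa=c + dc)))
        assert hi >= lo - 1e-12

    def test_loss_clipped_at_zero(self):
        land = reduced_landscape()
        f = _ref(land, residual_rhsa=0.4, excipient_b=1.0, excipient_d=1.0)
        assert float(titer_loss_truth(land.params, f)) >= 0.0

    def test_true_minimum_is_attained_and_never_undercut(self):
        """The analytic minimum is attained at the coordinate-wise optimum and
        lower-bounds a dense random search (separable landscape)."""
        land = reduced_landscape()
        argmin = _ref(land, residual_rhsa=land.params.residual_knee,
                      excipient_b=1.0, excipient_d=1.0)
        at_argmin = float(titer_loss_truth(land.params, argmin))
        assert at_argmin == pytest.approx(land.true_minimum(), abs=1e-12)
        rng = np.random.default_rng(0)
        names = land.space.names
        b = land.space.bounds()
        X = b[:, 0] + rng.random((20000, len(names))) * (b[:, 1] - b[:, 0])
        losses = titer_loss_truth(land.params, {n: X[:, i] for i, n in enumerate(names)})
        assert losses.min() >= land.true_minimum() - 1e-12

    def test_screening_landscape_has_19_features_9_designed_10_null(self):
        land = screening_landscape()
        assert len(land.space) == 19
        assert len(land.designed_features) == 9
        assert len(land.null_features) == 10

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            TiterLandscapeParams(noise_sd=-0.1)
        with pytest.raises(ValueError):
            TiterLandscapeParams(residual_knee=0.0)


class TestTgTruth:
    def test_pure_pvp_returns_component_value(self):
        mix = tg_mixture()
        f = {n: 0.0 for n in mix.space.names}
        f["pvp10"] = 30.0
        assert float(tg_truth(mix.params, f)) == pytest.approx(-26.0)

    def test_equal_component_tg_is_weight_invariant(self):
        params = TgMixtureParams(components=(("a", -30.0, 0.0, 50.0),
                                             ("b", -30.0, 0.0, 50.0)))
        for wa in (1.0, 10.0, 42.0):
            assert float(tg_truth(params, {"a": wa, "b": 5.0})) == pytest.approx(-30.0)

    def test_equal_mass_binary_matches_harmonic_mean_oracle(self):
        """Fox rule for an equal-mass binary reduces to the harmonic mean of
        the component temperatures in kelvin."""
        params = TgMixtureParams(components=(("a", -26.0, 0.0, 50.0),
                                             ("b", -44.0, 0.0, 50.0)))
        t1, t2 = -26.0 + 273.15, -44.0 + 273.15
        expected = 2.0 * t1 * t2 / (t1 + t2) - 273.15
        got = float(tg_truth(params, {"a": 10.0, "b": 10.0}))
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(-35.34, abs=0.01)  # frozen regression value

    def test_all_zero_concentrations_undefined(self):
        mix = tg_mixture()
        f = {n: 0.0 for n in mix.space.names}
        with pytest.raises(ValueError, match="undefined mixture"):
            tg_truth(mix.params, f)

    def test_shifting_mass_to_higher_tg_component_raises_tg(self):
        params = TgMixtureParams(components=(("lo", -60.0, 0.0, 50.0),
                                             ("hi", -20.0, 0.0, 50.0)))
        vals = [float(tg_truth(params, {"lo": 20.0 - w, "hi": w})) for w in (0.0, 5.0, 10.0, 19.0)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_component_tg_bounds_validated(self):
        with pytest.raises(ValueError):
            TgMixtureParams(components=(("bad", 5.0, 0.0, 1.0),))


class TestSampleDesign:
    def test_in_bounds_rows(self):
        land = reduced_landscape()
        d = sample_design(land.space, 10, "uniform", seed=0)
        assert len(d) == 10
        for f in land.space.features:
            assert (d[f.name] >= f.lower).all() and (d[f.name] <= f.upper).all()

    def test_latin_stratifies_each_dimension(self):
        land = reduced_landscape()
        d = sample_design(land.space, 10, "latin", seed=1)
        for f in land.space.features:
            u = (d[f.name] - f.lower) / (f.upper - f.lower)
            deciles = np.floor(u * 10).astype(int)
            assert sorted(deciles) == list(range(10))

    def test_same_seed_identical_design(self):
        land = reduced_landscape()
        d1 = sample_design(land.space, 15, "latin", seed=2)
        d2 = sample_design(land.space, 15, "latin", seed=2)
        pd.testing.assert_frame_equal(d1, d2)

    def test_invalid_args(self):
        land = reduced_landscape()
        with pytest.raises(ValueError):
            sample_design(land.space, 0, "latin")
        with pytest.raises(ValueError):
            sample_design(land.space, 5, "sobolish")


class TestGenerateDataset:
    def test_zero_noise_duplicates_identical(self):
        land = reduced_landscape(noise_sd=0.0)
        design = sample_design(land.space, 20, "latin", seed=3)
        ds = generate_dataset(land.oracle(3), design, replicates=2, seed=3,
                              response_name="titer_loss", space=land.space)
        assert len(ds) == 40
        piv = ds.frame.pivot_table(index=list(land.space.names),
                                   columns="replicate_id", values="titer_loss")
        np.testing.assert_allclose(piv[1], piv[2], rtol=1e-12)

    def test_noise_sd_within_chi_square_bounds(self):
        """400 noisy measurements at sd 0.1: sample sd of (observed - truth)
        in [0.085, 0.115] (99% chi-square coverage)."""
        land = reduced_landscape(noise_sd=0.1)
        design = sample_design(land.space, 200, "latin", seed=4)
        ds = generate_dataset(land.oracle(4), design, replicates=2, seed=4,
                              response_name="titer_loss", space=land.space)
        truth = land.truth_frame(ds.frame[land.space.names])
        resid = ds.y - truth
        assert 0.085 <= resid.std() <= 0.115

    def test_replicate_means_beat_single_replicates(self):
        land = reduced_landscape(noise_sd=0.15)
        design = sample_design(land.space, 150, "latin", seed=5)
        ds = generate_dataset(land.oracle(5), design, replicates=2, seed=5,
                              response_name="titer_loss", space=land.space)
        truth = land.truth_frame(design)
        frame = ds.frame
        singles = frame[frame["replicate_id"] == 1]["titer_loss"].to_numpy()
        means = frame.groupby(list(land.space.names), sort=False)["titer_loss"].mean().to_numpy()
        rmse_single = np.sqrt(np.mean((singles - truth) ** 2))
        rmse_mean = np.sqrt(np.mean((means - truth) ** 2))
        assert rmse_mean < rmse_single

    def test_same_replicate_seed_reproduces_measurement(self):
        land = reduced_landscape()
        design = sample_design(land.space, 5, "latin", seed=6)
        oracle = land.oracle(6)
        m1 = oracle.query(design, replicates=2)
        m2 = oracle.query(design, replicates=2)
        np.testing.assert_allclose(m1["response"], m2["response"], rtol=1e-15)

    def test_source_tag_synthetic(self):
        land = reduced_landscape()
        design = sample_design(land.space, 4, "latin", seed=7)
        ds = generate_dataset(land.oracle(7), design, replicates=1, seed=7,
                              response_name="titer_loss", space=land.space)
        assert (ds.frame["source_tag"] == "synthetic").all()
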