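"""Tests for MLR fitting, splitting and the validation statistics."""

import numpy as np
import pytest

import dicblend as db
from dicblend.calibration import split_indices
from dicblend.errors import SingularDesignError


def normal_equations(X, y):
    """Independent OLS oracle: solve (A'A) beta = A'y directly."""
    A = np.column_stack([np.ones(len(X)), X])
    return np.linalg.solve(A.T @ A, A.T @ y)


class TestSplit:
    def test_systematic_41_grid_gives_33_8(self, primary_dataset):
        cal, test = db.split_dataset(primary_dataset)
        assert (len(cal), len(test)) == (33, 8)
        assert 0.0 in cal.fractions and 1.0 in cal.fractions
        assert 0.0 not in test.fractions and 1.0 not in test.fractions

    def test_partition_disjoint_and_exhaustive(self, primary_dataset):
        cal, test = split_indices(primary_dataset.fractions)
        assert len(np.intersect1d(cal, test)) == 0
        assert sorted(np.concatenate([cal, test])) == list(range(41))

    def test_test_samples_every_fifth_sorted_position(self):
        fractions = np.linspace(0, 1, 41)
        _, test = split_indices(fractions)
        assert list(test) == [i for i in range(41) if i % 5 == 2]

    def test_five_samples_single_test(self):
        cal, test = split_indices(np.linspace(0, 1, 5))
        assert (len(cal), len(test)) == (4, 1)

    def test_random_scheme_seed_determinism(self, primary_dataset):
        a = split_indices(primary_dataset.fractions, scheme="random", seed=9)
        b = split_indices(primary_dataset.fractions, scheme="random", seed=9)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_cal_fraction_bounds(self, bad):
        with pytest.raises(ValueError, match="cal_fraction"):
            split_indices(np.linspace(0, 1, 41), cal_fraction=bad)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="at least 5"):
            split_indices(np.array([0.0, 0.5, 1.0]))


class TestFitPredict:
    def test_exact_linear_recovery(self, rng):
        X = rng.uniform(0, 255, (20, 3))
        beta = np.array([0.01, -0.02, 0.005])
        y = 0.3 + X @ beta
        model = db.fit_mlr(X, y)
        assert model.intercept == pytest.approx(0.3, abs=1e-9)
        np.testing.assert_allclose(model.coefficients, beta, atol=1e-10)
        np.testing.assert_allclose(db.predict(model, X), y, atol=1e-10)

    def test_single_descriptor_interpolates_two_points(self):
        X = np.array([[0.0], [2.0]])
        y = np.array([1.0, 5.0])
        model = db.fit_mlr(X, y)
        assert model.intercept == pytest.approx(1.0)
        assert model.coefficients[0] == pytest.approx(2.0)

    def test_matches_normal_equations_on_random_designs(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            X = rng.normal(size=(33, 3)) * rng.uniform(1, 100)
            y = rng.normal(size=33)
            model = db.fit_mlr(X, y)
            beta = normal_equations(X, y)
            assert model.intercept == pytest.approx(beta[0], abs=1e-10)
            np.testing.assert_allclose(model.coefficients, beta[1:], atol=1e-10)

    def test_rank_deficient_design_raises(self, rng):
        col = rng.normal(size=10)
        X = np.column_stack([col, 2 * col, rng.normal(size=10)])
        with pytest.raises(SingularDesignError):
            db.fit_mlr(X, rng.normal(size=10))

    def test_too_few_samples_raises(self, rng):
        with pytest.raises(ValueError, match="at least"):
            db.fit_mlr(rng.normal(size=(3, 3)), rng.normal(size=3))

    def test_constant_model_predicts_intercept(self):
        model = db.MLRModel("RGB", "none", intercept=0.5, coefficients=(0, 0, 0))
        np.testing.assert_array_equal(
            db.predict(model, np.ones((4, 3))), [0.5] * 4
        )

    def test_arity_mismatch_raises(self):
        model = db.MLRModel("GB", "none", intercept=0.0, coefficients=(1, 1))
        with pytest.raises(ValueError, match="arity"):
            db.predict(model, np.ones((4, 3)))

    def test_model_json_round_trip(self, tmp_path):
        model = db.MLRModel(
            "RB", "blanks_ratio", intercept=0.12, coefficients=(0.5, -0.25),
            primary_blank=db.PrimaryBlankMean((210.5, 200.25, 190.125), n=41),
            training_meta={"scheme": "systematic", "n_cal": 33},
        )
        path = tmp_path / "model.json"
        model.save(path)
        loaded = db.MLRModel.load(path)
        assert loaded.descriptor_set == model.descriptor_set
        assert loaded.correction == model.correction
        assert loaded.intercept == model.intercept
        np.testing.assert_array_equal(loaded.coefficients, model.coefficients)
        np.testing.assert_array_equal(
            loaded.primary_blank.mean_rgb, model.primary_blank.mean_rgb
        )
        assert loaded.training_meta == model.training_meta


class TestRmseR2:
    def test_perfect_prediction(self):
        out = db.rmse_and_r2([0, 0.5, 1], [0, 0.5, 1])
        assert out == {"rmse": 0.0, "r2": pytest.approx(1.0)}

    def test_pure_bias_keeps_correlation(self):
        out = db.rmse_and_r2([0, 0.5, 1], [0.5, 1.0, 1.5])
        assert out["rmse"] == pytest.approx(0.5)
        assert out["r2"] == pytest.approx(1.0)

    def test_affine_shrunk_predictions(self):
        out = db.rmse_and_r2([0, 0.5, 1], [0.1, 0.5, 0.9])
        assert out["rmse"] == pytest.approx(np.sqrt(0.02 / 3), abs=1e-9)
        assert out["r2"] == pytest.approx(1.0)

    def test_constant_observed_raises(self):
        with pytest.raises(ValueError, match="constant"):
            db.rmse_and_r2([1, 1, 1], [0, 1, 2])

    def test_order_invariance(self, rng):
        obs = rng.uniform(0, 1, 20)
        pred = obs + rng.normal(0, 0.1, 20)
        perm = rng.permutation(20)
        a = db.rmse_and_r2(obs, pred)
        b = db.rmse_and_r2(obs[perm], pred[perm])
        assert a["rmse"] == pytest.approx(b["rmse"])
        assert a["r2"] == pytest.approx(b["r2"])


def brute_force_r2m(obs, pred):
    """Independent oracle: explicit through-origin fit of predicted on observed."""
    obs, pred = np.asarray(obs, float), np.asarray(pred, float)
    r2 = np.corrcoef(obs, pred)[0, 1] ** 2
    k = np.sum(obs * pred) / np.sum(obs**2)
    r0_2 = 1 - np.sum((pred - k * obs) ** 2) / np.sum((pred - pred.mean()) ** 2)
    return r2 * (1 - np.sqrt(abs(r2 - r0_2)))


class TestR2m:
    def test_perfect_prediction_gives_one(self):
        assert db.r2m([0, 0.5, 1], [0, 0.5, 1]) == pytest.approx(1.0)

    def test_worked_example_against_oracle(self):
        obs, pred = [0, 0.5, 1], [0.1, 0.5, 0.9]
        value = db.r2m(obs, pred)
        assert value == pytest.approx(brute_force_r2m(obs, pred), abs=1e-12)
        # k = 0.92, r0^2 = 0.9625 -> r2m = 1 - sqrt(0.0375)
        assert value == pytest.approx(1 - np.sqrt(0.0375), abs=1e-12)
        assert value == pytest.approx(0.806, abs=5e-4)

    def test_exact_proportional_predictions_keep_r2m_at_one(self):
        # pred = c * obs fits the through-origin line exactly in both
        # directions, so r2m (implementation and oracle alike) stays 1;
        # the statistic penalises bias, not a pure gain without scatter
        obs = np.linspace(0, 1, 41)
        for c in (0.5, 0.8, 1.25, 2.0):
            assert db.r2m(obs, c * obs) == pytest.approx(
                brute_force_r2m(obs, c * obs), abs=1e-12
            )
            assert db.r2m(obs, c * obs) == pytest.approx(1.0, abs=1e-7)

    @pytest.mark.parametrize("bias", [-0.2, 0.05, 0.1, 0.3])
    def test_additive_bias_strictly_decreases_r2m(self, bias):
        obs = np.linspace(0, 1, 41)
        assert db.r2m(obs, obs + bias) < db.r2m(obs, obs) == pytest.approx(1.0)

    def test_reverse_direction_variant(self):
        obs = np.linspace(0, 1, 41)
        pred = 0.8 * obs + 0.05
        forward = db.r2m(obs, pred)
        reverse = db.r2m(obs, pred, direction="obs_on_pred")
        assert forward != pytest.approx(reverse)
        assert db.r2m(pred, obs) == pytest.approx(reverse)

    def test_order_invariance(self, rng):
        obs = rng.uniform(0, 1, 15)
        pred = 0.9 * obs + rng.normal(0, 0.05, 15)
        perm = rng.permutation(15)
        assert db.r2m(obs, pred) == pytest.approx(db.r2m(obs[perm], pred[perm]))

    def test_clamped_at_zero_for_incongruent_predictions(self):
        obs = np.linspace(0, 1, 20)
        assert db.r2m(obs, obs + 5.0) == 0.0


class TestYRandomization:
    def test_r2p_worked_values(self):
        assert round(db.r2p(0.99, 0.12), 2) == 0.93
        assert round(db.r2p(0.92, 0.05), 2) == 0.89
        assert round(db.r2p(0.93, 0.12), 2) == 0.87

    def test_r2p_clamped_when_randomized_matches_calibration(self):
        assert db.r2p(0.5, 0.6) == 0.0
        assert db.r2p(0.5, 0.5) == 0.0

    def test_chance_level_r2_near_p_over_n_minus_1(self, rng):
        # E[R2] for p regressors on random labels is p/(n-1) = 3/32
        X = rng.normal(size=(33, 3))
        y = np.linspace(0, 1, 33)
        out = db.y_randomization(X, y, n_perm=200, seed=1)
        assert out["r2_mean"] == pytest.approx(3 / 32, abs=0.03)

    def test_randomized_rmse_matches_grid_prediction(self, rng):
        # on the 33-point grid: sd(y) * sqrt((n - p - 1)/n) ~ 0.279
        X = rng.normal(size=(33, 3))
        y = np.linspace(0, 1, 33)
        out = db.y_randomization(X, y, n_perm=100, seed=2)
        assert out["rmse_mean"] == pytest.approx(0.28, abs=0.02)

    def test_seed_determinism(self, rng):
        X = rng.normal(size=(33, 3))
        y = np.linspace(0, 1, 33)
        assert db.y_randomization(X, y, seed=7) == db.y_randomization(X, y, seed=7)

    def test_n_perm_minimum(self, rng):
        with pytest.raises(ValueError, match="n_perm"):
            db.y_randomization(rng.normal(size=(33, 3)), np.linspace(0, 1, 33), n_perm=5)


class TestCrossValidate:
    def test_noiseless_linear_data_survives_deletion(self, rng):
        X = rng.uniform(0, 255, (20, 3))
        y = 0.1 + X @ np.array([0.002, 0.001, -0.003])
        out = db.cross_validate(X, y)
        assert out["rmse"] < 1e-9
        assert out["r2"] == pytest.approx(1.0)

    def test_three_samples_single_descriptor(self):
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array([0.0, 0.5, 1.0])
        out = db.cross_validate(X, y)
        assert out["rmse"] < 1e-9

    def test_cv_rmse_at_least_calibration_rmse(self, primary_dataset):
        cal, _ = db.split_dataset(primary_dataset)
        X = cal.sample_rgb
        y = cal.fractions
        model = db.fit_mlr(X, y)
        cal_rmse = db.rmse_and_r2(y, db.predict(model, X))["rmse"]
        assert db.cross_validate(X, y)["rmse"] >= cal_rmse

    def test_kfold_seed_determinism(self, rng):
        X = rng.normal(size=(30, 3))
        y = rng.uniform(0, 1, 30)
        a = db.cross_validate(X, y, scheme="kfold", seed=3)
        b = db.cross_validate(X, y, scheme="kfold", seed=3)
        assert a == b


class TestEvaluatePrimary:
    def test_noiseless_data_fits_exactly(self, noiseless_scene, quiet_condition):
        # small distinct absorbances: three exponential channels cancel the
        # curvature and the linear model is exact to ~1e-9
        so = db.OpticalOil("SO", (0.05, 0.03, 0.015))
        evoo = db.OpticalOil("EVOO", (0.005, 0.002, 0.004))
        scene = noiseless_scene.replace(oils=(so, evoo))
        ds = db.generate_blend_dataset(scene, quiet_condition, seed=0)
        _, report = db.evaluate_primary(ds, "RGB", "none", seed=0)
        assert report.calibration["r2"] == pytest.approx(1.0, abs=1e-12)
        assert report.calibration["rmse"] < 1e-6
        # parameter recovery on the hold-out fractions
        assert report.external["rmse"] < 1e-4

    def test_default_noisy_primary_external_r2_above_0p9(self, primary_dataset):
        _, report = db.evaluate_primary(primary_dataset, "RGB", "none", seed=7)
        assert report.external["r2"] > 0.9

    def test_full_descriptor_by_correction_grid_shape(self, primary_dataset):
        reports = {}
        for dset in db.DescriptorSet:
            for corr in db.CorrectionMethod:
                _, report = db.evaluate_primary(
                    primary_dataset, dset, corr, seed=1, n_perm=10
                )
                reports[(dset.value, corr.value)] = report
        assert len(reports) == 16
        for report in reports.values():
            frame = report.to_frame()
            assert set(frame["stage"]) == {
                "calibration", "y_randomization", "cross_validation", "external",
            }

    def test_model_carries_correction_and_primary_blank(self, primary_dataset):
        model, _ = db.evaluate_primary(primary_dataset, "GB", "blanks_ratio", seed=1, n_perm=10)
        assert model.correction == db.CorrectionMethod.BLANKS_RATIO
        assert model.primary_blank is not None
        assert model.primary_blank.n == 41
        np.testing.assert_allclose(
            model.primary_blank.mean_rgb,
            db.primary_blank_mean(primary_dataset).mean_rgb,
        )
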