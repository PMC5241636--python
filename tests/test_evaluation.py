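import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import chainpk as cp
from chainpk import chain as chain_mod
from chainpk.evaluation import comparison_report, error_measures, improvement, loocv

from conftest import make_chain_dataset


def brute_force_measures(Y, Yhat):
    """Loop-based recomputation of per-target RMSE/MAE/MAPE and the whole
    values (mean across targets) with sample-SD dispersion."""
    l, n = Y.shape
    rmse, mae, mape = [], [], []
    for j in range(n):
        se = ae = ape = 0.0
        for i in range(l):
            d = Yhat[i][j] - Y[i][j]
            se += d * d
            ae += abs(d)
            ape += abs(d) / abs(Y[i][j])
        rmse.append(math.sqrt(se / l))
        mae.append(ae / l)
        mape.append(ape / l)

    def sd(vals):
        mu = sum(vals) / len(vals)
        return math.sqrt(sum((v - mu) ** 2 for v in vals) / (len(vals) - 1))

    return rmse, mae, mape, sd


class TestErrorMeasures:
    def test_perfect_prediction_is_zero(self):
        Y = np.arange(1.0, 19.0).reshape(2, 9)
        rep = error_measures(Y, Y)
        assert rep.rmse == rep.mae == rep.mape == 0.0
        assert rep.rmse_sd == rep.mae_sd == rep.mape_sd == 0.0
        assert rep.l == 2 and rep.n == 9

    def test_two_sample_single_target_arithmetic(self):
        rep = error_measures([[10.0], [20.0]], [[12.0], [16.0]])
        assert rep.rmse == pytest.approx(math.sqrt(10.0))
        assert rep.mae == pytest.approx(3.0)
        assert rep.mape == pytest.approx(0.2)

    @given(
        Y=arrays(float, (5, 9), elements=st.floats(0.5, 100, allow_nan=False)),
        E=arrays(float, (5, 9), elements=st.floats(-10, 10, allow_nan=False)),
    )
    def test_matches_brute_force_and_rmse_dominates_mae(self, Y, E):
        Yhat = Y + E
        rep = error_measures(Y, Yhat)
        rmse, mae, mape, sd = brute_force_measures(Y, Yhat)
        np.testing.assert_allclose(rep.per_target_rmse, rmse, rtol=1e-10)
        np.testing.assert_allclose(rep.per_target_mae, mae, rtol=1e-10)
        np.testing.assert_allclose(rep.per_target_mape, mape, rtol=1e-10)
        assert rep.rmse == pytest.approx(np.mean(rmse))
        assert rep.mae == pytest.approx(np.mean(mae))
        assert rep.mape == pytest.approx(np.mean(mape))
        assert rep.rmse_sd == pytest.approx(sd(rmse))
        # quadratic mean dominates arithmetic mean of absolute errors
        assert np.all(rep.per_target_rmse >= rep.per_target_mae - 1e-12)

    def test_zero_true_value_raises_for_mape(self):
        Y = np.array([[0.0, 1.0]])
        with pytest.raises(cp.UndefinedMAPEError):
            error_measures(Y, Y + 1.0, include_mape=True)
        rep = error_measures(Y, Y + 1.0, include_mape="auto")
        assert rep.mape is None and rep.mae == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            error_measures(np.ones((2, 3)), np.ones((3, 2)))


class TestImprovement:
    def test_published_worked_examples(self):
        # LR whole-RMSE of berberine: ST 66.88, MT 60.92, RMT 55.52
        assert improvement(66.88, 60.92) == pytest.approx(8.91, abs=0.005)
        assert improvement(55.52, 60.92) == pytest.approx(-9.73, abs=0.005)

    def test_no_change_is_zero(self):
        assert improvement(3.7, 3.7) == 0.0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            improvement(0.0, 1.0)


class TestLOOCV:
    def test_constant_noise_free_data_is_learned_exactly(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0.2, 2.0, (6, 3))
        Y = np.tile(np.linspace(1, 9, 9), (6, 1))  # same curve for every sample
        data = cp.ConcentrationDataset("rut", X, Y, cp.standard_time_grid())
        rep = loocv(data, cp.RegressorSpec("LR"), "ST")
        assert rep.rmse < 1e-8 and rep.mae < 1e-8

    def test_each_sample_held_out_exactly_once(self, monkeypatch, small_dataset):
        seen_sizes = []
        real_fit = chain_mod.regressors.fit

        def spy(spec, X, y, seed=0):
            seen_sizes.append(len(X))
            return real_fit(spec, X, y, seed)

        monkeypatch.setattr(chain_mod.regressors, "fit", spy)
        m, n = small_dataset.n_samples, small_dataset.n_targets
        loocv(small_dataset, cp.RegressorSpec("LR"), "ST")
        assert len(seen_sizes) == m * n
        assert set(seen_sizes) == {m - 1}

    def test_three_samples_make_three_folds(self):
        rng = np.random.default_rng(3)
        data = cp.ConcentrationDataset(
            "evo", rng.uniform(0, 1, (3, 3)), rng.uniform(1, 2, (3, 9)),
            cp.standard_time_grid(),
        )
        rep = loocv(data, cp.RegressorSpec("LR"), "ST")
        assert rep.l == 3

    def test_memorizing_regressor_still_errs_on_held_out_samples(self, monkeypatch, small_dataset):
        """A 1-nearest-neighbour memorizer would score zero if any held-out
        sample leaked into training; positive LOOCV error rules that out."""

        class OneNN:
            def __init__(self, X, y):
                self.X, self.y = np.asarray(X, float), np.asarray(y, float)
                self.n_features = self.X.shape[1]
                self.spec = cp.RegressorSpec("LR")

            def predict(self, X):
                X = np.asarray(X, float)
                d = ((X[:, None, :] - self.X[None]) ** 2).sum(-1)
                return self.y[np.argmin(d, axis=1)]

        monkeypatch.setattr(chain_mod.regressors, "fit", lambda spec, X, y, seed=0: OneNN(X, y))
        rep = loocv(small_dataset, cp.RegressorSpec("LR"), "ST")
        assert rep.rmse > 0.1  # memorization cannot reach the held-out sample

    def test_chain_structured_data_is_exact_under_mt(self):
        data = make_chain_dataset(latent_scale=0.0)
        rep = loocv(data, cp.RegressorSpec("LR"), "MT")
        assert rep.rmse < 1e-8

    def test_latent_component_defeats_feature_only_regression(self):
        data = make_chain_dataset(latent_scale=1.0)
        rep = loocv(data, cp.RegressorSpec("LR"), "ST")
        assert rep.rmse > 0.01


class TestComparisonReport:
    def test_cells_shapes_and_determinism(self, tmp_path, small_dataset):
        datasets = {"ber": small_dataset}
        specs = [cp.RegressorSpec("LR")]
        out_a, out_b = tmp_path / "a", tmp_path / "b"
        errors, imps = comparison_report(datasets, specs, ["ST", "MT"], seed=4, out_dir=out_a)
        comparison_report(datasets, specs, ["ST", "MT"], seed=4, out_dir=out_b)
        # one improvement row per measure (MAPE defined: all-positive herbs)
        assert list(imps["vs"].unique()) == ["ST"]
        assert len(imps) == 3
        st_rmse = errors.query("mode == 'ST' and measure == 'RMSE'")["whole"].iloc[0]
        mt_rmse = errors.query("mode == 'MT' and measure == 'RMSE'")["whole"].iloc[0]
        expected = improvement(st_rmse, mt_rmse)
        got = imps.query("measure == 'RMSE'")["percent"].iloc[0]
        assert got == pytest.approx(expected)
        for name in ("errors.csv", "improvements.csv"):
            assert (out_a / name).read_bytes() == (out_b / name).read_bytes()

    def test_rmt_adds_second_comparison(self, small_dataset):
        _, imps = comparison_report(
            {"ber": small_dataset}, [cp.RegressorSpec("LR")], ["ST", "MT", "RMT"], seed=4
        )
        assert len(imps) == 6
        assert set(imps["vs"]) == {"ST", "RMT"}

    def test_empty_inputs_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            comparison_report({}, [cp.RegressorSpec("LR")])
        with pytest.raises(ValueError):
            comparison_report({"ber": small_dataset}, [])
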