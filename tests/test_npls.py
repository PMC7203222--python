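"""Tri-PLS1 model: exact recovery, oracle equivalence, coefficient maps."""

import numpy as np
import pandas as pd
import pytest

from eemlearn.eem_data import ResponseTable
from eemlearn.npls import (
    NPLSRegressor,
    RankDeficiencyWarning,
    fit_npls,
    inverse_log10_transform,
    load_model,
    log10_transform,
    save_model,
)

from conftest import nipals_pls1


def rank_r_tensor(rng, n=20, J=12, K=9, R=1):
    """Noiseless tri-linear tensor of rank R with y exactly linear in the
    component concentrations."""
    C = rng.uniform(0.5, 2.0, size=(n, R))
    U = rng.normal(size=(R, J))
    V = rng.normal(size=(R, K))
    X = np.einsum("ir,rj,rk->ijk", C, U, V)
    coef = rng.uniform(0.5, 1.5, size=R)
    y = 1.0 + C @ coef
    return X, y, C


class TestExactRecovery:
    def test_rank1_training_residual_zero(self):
        rng = np.random.default_rng(0)
        X, y, C = rank_r_tensor(rng, R=1)
        model = NPLSRegressor(1).fit(X, y)
        np.testing.assert_allclose(model.fitted_values(), y, atol=1e-10)

    @pytest.mark.parametrize("R", [1, 2, 3])
    def test_rank_r_training_r2(self, R):
        rng = np.random.default_rng(R)
        X, y, _ = rank_r_tensor(rng, n=24, R=R)
        model = NPLSRegressor(R).fit(X, y)
        resid = y - model.fitted_values()
        r2 = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
        assert r2 >= 1 - 1e-6

    def test_rank1_weights_match_generators(self):
        rng = np.random.default_rng(5)
        C = rng.uniform(0.5, 2.0, size=(15, 1))
        u = rng.normal(size=12)
        v = rng.normal(size=9)
        X = np.einsum("ir,j,k->ijk", C, u, v)
        y = C[:, 0]
        model = NPLSRegressor(1).fit(X, y)
        uu = u / np.linalg.norm(u)
        vv = v / np.linalg.norm(v)
        assert (
            np.allclose(model.em_weights_[0], uu, atol=1e-8)
            or np.allclose(model.em_weights_[0], -uu, atol=1e-8)
        )
        assert (
            np.allclose(np.abs(model.ex_weights_[0]), np.abs(vv), atol=1e-8)
        )

    def test_heldout_rank1_predictions_exact(self):
        rng = np.random.default_rng(1)
        X, y, _ = rank_r_tensor(rng, n=30, R=1)
        model = NPLSRegressor(1).fit(X[:20], y[:20])
        np.testing.assert_allclose(model.predict(X[20:]), y[20:], atol=1e-8)


class TestPLS1Oracle:
    def test_single_excitation_column_equals_pls1(self):
        """With K=1 the tri-linear model collapses to single-block PLS1;
        fitted values and held-out predictions must agree with an
        independent NIPALS implementation."""
        rng = np.random.default_rng(1234)
        for trial in range(20):
            n, J, F = 15, 9, 3
            X = rng.normal(size=(n + 5, J, 1))
            beta = rng.normal(size=J)
            y = X[:, :, 0] @ beta + 0.1 * rng.normal(size=n + 5)
            model = NPLSRegressor(F).fit(X[:n], y[:n])
            _, fitted, predict = nipals_pls1(X[:n, :, 0], y[:n], F)
            np.testing.assert_allclose(model.fitted_values(), fitted, atol=1e-6)
            np.testing.assert_allclose(
                model.predict(X[n:]), predict(X[n:, :, 0]), atol=1e-6
            )

    def test_shuffled_response_has_no_predictive_power(self):
        rng = np.random.default_rng(99)
        X, y, _ = rank_r_tensor(rng, n=40, J=10, K=8, R=2)
        y_shuffled = rng.permutation(y)
        # simple 4-fold cross-validated R^2 against the shuffled response
        from eemlearn.validation import run_double_cv

        report = run_double_cv(X, y_shuffled, seed=7, max_lvs=4)
        assert report.pooled["r2_val"] <= 0.2


class TestPredict:
    def test_training_predictions_are_fitted_values(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(18, 7, 5))
        y = rng.normal(size=18)
        model = NPLSRegressor(4).fit(X, y)
        np.testing.assert_array_equal(model.predict(X), model.fitted_values())

    def test_mean_sample_predicts_y_center(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 6, 4))
        y = rng.normal(size=15)
        model = NPLSRegressor(2).fit(X, y)
        mean_sample = X.mean(axis=0)[None]
        assert model.predict(mean_sample)[0] == pytest.approx(y.mean(), abs=1e-10)

    def test_grid_mismatch_raises(self):
        rng = np.random.default_rng(4)
        model = NPLSRegressor(1).fit(rng.normal(size=(10, 6, 4)), rng.normal(size=10))
        with pytest.raises(ValueError, match="grid mismatch"):
            model.predict(rng.normal(size=(2, 5, 4)))

    def test_sporadic_missing_in_new_data_warns_and_zero_fills(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 6, 4))
        y = rng.normal(size=12)
        model = NPLSRegressor(1).fit(X, y)
        Xnew = X[:1].copy()
        Xnew[0, 2, 2] = np.nan
        with pytest.warns(UserWarning, match="missing cells inside the modelled"):
            got = model.predict(Xnew)
        Xfill = X[:1].copy()
        Xfill[0, 2, 2] = model.x_mean_[2, 2]  # 0 after centering
        np.testing.assert_allclose(got, model.predict(Xfill), atol=1e-12)


class TestModelStructure:
    def test_unit_norm_weights_and_deterministic_sign(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 8, 5))
        y = rng.normal(size=20)
        a = NPLSRegressor(3).fit(X, y)
        b = NPLSRegressor(3).fit(X.copy(), y.copy())
        for f in range(3):
            assert np.linalg.norm(a.em_weights_[f]) == pytest.approx(1.0)
            assert np.linalg.norm(a.ex_weights_[f]) == pytest.approx(1.0)
            pivot = np.argmax(np.abs(a.em_weights_[f]))
            assert a.em_weights_[f][pivot] > 0
        # repeated fits bit-identical
        np.testing.assert_array_equal(a.scores_, b.scores_)
        np.testing.assert_array_equal(a.em_weights_, b.em_weights_)

    def test_training_rmse_nonincreasing_in_f(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(25, 9, 6))
        y = rng.normal(size=25)
        rmses = []
        for F in range(1, 7):
            m = NPLSRegressor(F).fit(X, y)
            rmses.append(float(np.sqrt(np.mean((y - m.fitted_values()) ** 2))))
        assert all(a >= b - 1e-10 for a, b in zip(rmses, rmses[1:]))

    def test_excess_components_truncate_with_warning(self):
        rng = np.random.default_rng(8)
        X, y, _ = rank_r_tensor(rng, n=12, R=1)
        with pytest.warns(RankDeficiencyWarning):
            model = NPLSRegressor(5).fit(X, y)
        assert model.n_components_ < 5

    def test_constant_y_rejected(self):
        rng = np.random.default_rng(9)
        with pytest.raises(ValueError, match="constant"):
            NPLSRegressor(1).fit(rng.normal(size=(8, 4, 3)), np.ones(8))

    def test_missing_band_excluded_from_model(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(15, 6, 4))
        y = X[:, 0, 0] * 2.0 + 1.0
        Xm = X.copy()
        Xm[:, 3, 2] = np.nan  # band missing in every sample
        model = NPLSRegressor(2).fit(Xm, y)
        assert not model.included_mask_[3, 2]
        assert np.isnan(model.coefficient_map().values[3, 2])


class TestCoefficientMap:
    def test_single_lv_closed_form(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(14, 7, 5))
        y = rng.normal(size=14)
        model = NPLSRegressor(1).fit(X, y)
        cmap = model.coefficient_map()
        expected = model.inner_coef_[0] * np.outer(
            model.em_weights_[0], model.ex_weights_[0]
        )
        np.testing.assert_allclose(cmap.values, expected, atol=1e-12)

    @pytest.mark.parametrize("F", [1, 3])
    def test_map_matches_predict_on_random_samples(self, F):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(20, 8, 6))
        y = rng.normal(size=20)
        model = NPLSRegressor(F).fit(X, y)
        cmap = model.coefficient_map()
        Xnew = rng.normal(size=(10, 8, 6))
        np.testing.assert_allclose(cmap.predict(Xnew), model.predict(Xnew), atol=1e-8)

    def test_finite_difference_probe_matches_map(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(16, 6, 5))
        y = rng.normal(size=16)
        model = NPLSRegressor(3).fit(X, y)
        cmap = model.coefficient_map()
        base = X.mean(axis=0)
        eps = 1e-5
        for (j, k) in [(0, 0), (2, 3), (5, 4)]:
            hi = base.copy()
            hi[j, k] += eps
            lo = base.copy()
            lo[j, k] -= eps
            fd = (model.predict(hi[None])[0] - model.predict(lo[None])[0]) / (2 * eps)
            assert fd == pytest.approx(cmap.values[j, k], rel=1e-6, abs=1e-10)

    def test_map_inner_product_invariant_on_training_slices(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(15, 7, 4))
        y = rng.normal(size=15)
        model = NPLSRegressor(2).fit(X, y)
        cmap = model.coefficient_map()
        np.testing.assert_allclose(
            cmap.predict(X), model.fitted_values(), rtol=1e-8, atol=1e-10
        )


class TestLog10Transform:
    def _table(self):
        df = pd.DataFrame(
            {"cell_concentration": [100.0, 1.0, 1e6]}, index=["a", "b", "c"]
        )
        return ResponseTable(data=df)

    def test_values_and_flags(self):
        out = log10_transform(self._table(), ["cell_concentration"])
        np.testing.assert_allclose(
            out.data["cell_concentration"], [2.0, 0.0, 6.0]
        )
        assert out.log10_applied["cell_concentration"]

    def test_round_trip(self):
        df = pd.DataFrame({"v": [0.5, 3.7, 1e6]}, index=["a", "b", "c"])
        t = ResponseTable(data=df)
        back = inverse_log10_transform(log10_transform(t, ["v"]), ["v"])
        np.testing.assert_allclose(back.data["v"], [0.5, 3.7, 1e6], rtol=1e-12)
        assert not back.log10_applied["v"]

    def test_nonpositive_named_in_error(self):
        df = pd.DataFrame({"v": [1.0, -2.0]}, index=["a", "bad_sample"])
        with pytest.raises(ValueError, match="bad_sample"):
            log10_transform(ResponseTable(data=df), ["v"])


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, tmp_path):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(18, 7, 5))
        X[:, 1, 1] = np.nan
        y = rng.normal(size=18)
        model = fit_npls(X, y, 3)
        p = tmp_path / "model.json"
        save_model(model, p)
        back = load_model(p)
        Xnew = rng.normal(size=(5, 7, 5))
        np.testing.assert_allclose(back.predict(Xnew), model.predict(Xnew), rtol=1e-12)
        np.testing.assert_allclose(
            back.coefficient_map().values[model.included_mask_],
            model.coefficient_map().values[model.included_mask_],
            rtol=1e-10,
        )
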