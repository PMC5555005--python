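import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boostprobe import ComponentwiseBoosting, Dataset
from boostprobe.boosting import fit_base_learner, select_best

from _naive import naive_boost_path


class TestBaseLearner:
    def test_exact_linear_relation(self, rng):
        xj = rng.normal(size=20)
        xj -= xj.mean()
        assert fit_base_learner(xj, 2.0 * xj) == pytest.approx(2.0)

    def test_orthogonal_gradient_gives_zero(self):
        xj = np.array([-1.0, 0.0, 1.0])
        u = np.array([1.0, 7.0, 1.0])  # orthogonal to xj
        assert fit_base_learner(xj, u) == pytest.approx(0.0)

    def test_one_variable_ols(self):
        # single-covariate OLS slope: <x,u>/<x,x> = 5/2
        assert fit_base_learner(np.array([-1.0, 0.0, 1.0]),
                                np.array([0.0, 1.0, 5.0])) == pytest.approx(2.5)

    def test_zero_variance_column_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            fit_base_learner(np.zeros(5), np.ones(5))


class TestSelectBest:
    def test_exact_column_wins(self, rng):
        Xc = rng.normal(size=(30, 4))
        Xc -= Xc.mean(axis=0)
        j, b = select_best(Xc, Xc[:, 2].copy())
        assert j == 2
        assert b == pytest.approx(1.0)

    def test_tie_broken_by_smaller_index(self, rng):
        col = rng.normal(size=25)
        Xc = np.column_stack([rng.normal(size=25), col, col])
        Xc -= Xc.mean(axis=0)
        j, _ = select_best(Xc, Xc[:, 1].copy())
        assert j == 1

    def test_matches_exhaustive_sse(self, rng):
        Xc = rng.normal(size=(5, 3))
        Xc -= Xc.mean(axis=0)
        u = rng.normal(size=5)
        sse = []
        for j in range(3):
            b = (Xc[:, j] @ u) / (Xc[:, j] @ Xc[:, j])
            sse.append(np.sum((u - b * Xc[:, j]) ** 2))
        j, _ = select_best(Xc, u)
        assert j == int(np.argmin(sse))

    def test_all_unusable_raises(self):
        with pytest.raises(ValueError, match="no usable"):
            select_best(np.zeros((4, 2)), np.ones(4))


class TestGaussianClosedForms:
    """The p=1 path has a closed form: coef_m = beta_ols * (1-(1-nu)^m)."""

    @pytest.mark.parametrize("nu,m", [(1.0, 1), (0.1, 1), (0.1, 17), (0.3, 40)])
    def test_single_covariate_geometric_recursion(self, rng, nu, m):
        x = rng.normal(size=40)
        y = 1.0 + 2.0 * x + rng.normal(size=40)
        xc = x - x.mean()
        beta_ols = (xc @ y) / (xc @ xc)
        res = ComponentwiseBoosting(y, x[:, None]).fit(nu=nu, m_stop=m)
        expected = beta_ols * (1.0 - (1.0 - nu) ** m)
        assert res.coef[0] == pytest.approx(expected, abs=1e-10)

    def test_full_rank_convergence_to_ols(self, gaussian_data):
        d = gaussian_data
        res = ComponentwiseBoosting(d.y, d.X).fit(nu=0.1, m_stop=50_000)
        Xd = np.column_stack([np.ones(d.n), d.X])
        ols = np.linalg.lstsq(Xd, d.y, rcond=None)[0]
        np.testing.assert_allclose(res.coef, ols[1:], atol=1e-6)
        # intercept = offset - centers @ coef on the original scale
        assert res.offset - res.centers @ res.coef == pytest.approx(ols[0], abs=1e-6)

    def test_predictions_approach_ols_fit(self, gaussian_data):
        d = gaussian_data
        res = ComponentwiseBoosting(d.y, d.X).fit(nu=0.1, m_stop=50_000)
        Xd = np.column_stack([np.ones(d.n), d.X])
        fitted = Xd @ np.linalg.lstsq(Xd, d.y, rcond=None)[0]
        np.testing.assert_allclose(res.predict(d.X), fitted, atol=1e-5)


class TestPathAgainstNaiveOracle:
    @pytest.mark.parametrize("family,seed", [
        ("gaussian", 0), ("gaussian", 7), ("binomial", 1), ("binomial", 9),
    ])
    def test_path_matches_loop_reimplementation(self, family, seed):
        rng = np.random.default_rng(seed)
        n, p, m = 30, 5, 60
        X = rng.normal(size=(n, p))
        eta = X @ np.array([1.5, -1.0, 0.0, 0.0, 0.4])
        if family == "binomial":
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            if y.mean() in (0, 1):
                y[0] = 1 - y[0]
        else:
            y = eta + rng.normal(size=n)
        offset, path, coef = naive_boost_path(X, y, family, nu=0.1, m=m)
        res = ComponentwiseBoosting(y, X, family=family).fit(nu=0.1, m_stop=m)
        assert res.offset == pytest.approx(offset, abs=1e-12)
        assert [int(j) for j in res.sel_idx] == [j for j, _ in path]
        np.testing.assert_allclose(res.sel_coef, [b for _, b in path],
                                   rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(res.coef, coef, rtol=1e-10, atol=1e-12)


class TestPathInvariants:
    @pytest.mark.parametrize("family", ["gaussian", "binomial"])
    def test_training_loss_monotone(self, family, gaussian_data, binomial_data):
        d = gaussian_data if family == "gaussian" else binomial_data
        model = ComponentwiseBoosting(d.y, d.X, family=family)
        res = model.fit(nu=0.1, m_stop=150)
        losses = []
        for m in range(0, res.m_stop + 1):
            f = res.truncate(m).fittedvalues
            losses.append(float(np.sum(model.family.loss(d.y, f))))
        assert all(l2 <= l1 + 1e-9 for l1, l2 in zip(losses, losses[1:]))

    def test_coef_consistent_with_path_replay(self, binomial_data):
        d = binomial_data
        res = ComponentwiseBoosting(d.y, d.X, family="binomial").fit(m_stop=80)
        replay = np.zeros(d.p)
        for j, b in zip(res.sel_idx, res.sel_coef):
            replay[j] += res.nu * b
        np.testing.assert_array_equal(replay, res.coef)
        # nonzero coefficients <-> appearance in the path
        assert set(np.nonzero(res.coef)[0]) == set(res.sel_idx.tolist())

    def test_gaussian_gradient_equals_residual_along_path(self, gaussian_data):
        d = gaussian_data
        res = ComponentwiseBoosting(d.y, d.X).fit(nu=0.1, m_stop=40)
        for m in (1, 5, 40):
            prev = res.truncate(m - 1)
            u = d.y - prev.fittedvalues
            np.testing.assert_array_equal(
                u, res.model.family.negative_gradient(d.y, prev.fittedvalues)
            )

    def test_deterministic_path(self, binomial_data):
        d = binomial_data
        r1 = ComponentwiseBoosting(d.y, d.X, family="binomial").fit(m_stop=100)
        r2 = ComponentwiseBoosting(d.y, d.X, family="binomial").fit(m_stop=100)
        np.testing.assert_array_equal(r1.sel_idx, r2.sel_idx)
        np.testing.assert_array_equal(r1.coef, r2.coef)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), m=st.integers(1, 50))
    def test_selected_count_bounded_by_iterations(self, seed, m):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(20, 6))
        y = rng.normal(size=20)
        res = ComponentwiseBoosting(y, X).fit(nu=0.1, m_stop=m)
        assert res.m_stop == m
        assert 1 <= len(res.selected()) <= m


class TestModelInterface:
    def test_invalid_nu_and_m(self, gaussian_data):
        model = ComponentwiseBoosting(gaussian_data.y, gaussian_data.X)
        with pytest.raises(ValueError):
            model.fit(nu=0.0)
        with pytest.raises(ValueError):
            model.fit(nu=1.5)
        with pytest.raises(ValueError):
            model.fit(m_stop=0)

    def test_zero_variance_column_never_selected(self, rng):
        X = rng.normal(size=(40, 3))
        X[:, 1] = 7.0  # constant
        y = X[:, 0] + rng.normal(scale=0.1, size=40)
        res = ComponentwiseBoosting(y, X).fit(m_stop=200)
        assert 1 not in res.selected()
        assert res.coef[1] == 0.0

    def test_stop_callback_pre_update(self, gaussian_data):
        d = gaussian_data
        res = ComponentwiseBoosting(d.y, d.X).fit(
            m_stop=100, stop=lambda j, m: m == 4
        )
        assert res.m_stop == 3  # iteration 4 discarded

    def test_m_stop_one_single_path_entry(self, gaussian_data):
        res = ComponentwiseBoosting(gaussian_data.y, gaussian_data.X).fit(
            nu=0.1, m_stop=1
        )
        assert res.m_stop == 1 and len(res.path()) == 1

    def test_predict_shape_validation(self, gaussian_data):
        res = ComponentwiseBoosting(gaussian_data.y, gaussian_data.X).fit(m_stop=5)
        with pytest.raises(ValueError, match="columns"):
            res.predict(np.ones((3, 2)))

    def test_constant_fit_predicts_offset(self, gaussian_data):
        d = gaussian_data
        res = ComponentwiseBoosting(d.y, d.X).fit(m_stop=3, stop=lambda j, m: True)
        assert res.m_stop == 0
        np.testing.assert_allclose(res.predict(d.X), res.offset)

    def test_from_dataframe_and_summary(self, gaussian_data):
        df = gaussian_data.to_dataframe(outcome="resp")
        model = ComponentwiseBoosting.from_dataframe(df, outcome="resp")
        res = model.fit(m_stop=30)
        assert model.names == ["x1", "x2", "x3", "x4"]
        text = res.summary()
        assert "gaussian" in text and "m_stop" in text
        assert isinstance(res.params, pd.Series)
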