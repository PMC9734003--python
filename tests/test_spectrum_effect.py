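"""GRA, NIPALS PLS1, VIP and the intersection screening rule.

The PLS1 fit is cross-checked against two independent routes: a SIMPLS
implementation written here from the published algorithm, and
scikit-learn's PLSRegression.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specfx import (
    EffectSimTruth,
    GRAConfig,
    SpectrumEffectInput,
    gra,
    loo_rmse,
    plsr_nipals,
    printed_gra_grades,
    select_active,
    simulate_spectrum_effect,
    vip,
    zscore,
    zscore_matrix,
)


def _inp(X, y):
    df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(
        np.asarray(X), columns=[f"X{j + 1}" for j in range(np.asarray(X).shape[1])]
    )
    return SpectrumEffectInput(df, np.asarray(y, float))


def simpls_pls1(X, y, n_components):
    """SIMPLS (de Jong 1993) for a univariate response, on autoscaled data.

    Independent oracle: returns training predictions on the original scale.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    xm, xs = X.mean(0), X.std(0, ddof=1)
    ym, ys = y.mean(), y.std(ddof=1)
    Xs = (X - xm) / xs
    ys_ = (y - ym) / ys
    S = Xs.T @ ys_
    R = np.zeros((X.shape[1], n_components))
    T = np.zeros((X.shape[0], n_components))
    V = np.zeros((X.shape[1], n_components))
    q = np.zeros(n_components)
    for a in range(n_components):
        r = S.copy()
        t = Xs @ r
        t -= t.mean()
        norm_t = np.linalg.norm(t)
        t /= norm_t
        r /= norm_t
        p = Xs.T @ t
        q[a] = ys_ @ t
        v = p.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ p)
        v /= np.linalg.norm(v)
        S -= v * (v @ S)
        R[:, a], T[:, a], V[:, a] = r, t, v
    beta = R @ q
    return ym + ys * (Xs @ beta)


class TestZscore:
    def test_symmetric_triplet(self):
        assert np.allclose(zscore([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])

    @settings(deadline=None, max_examples=50)
    @given(a=st.floats(0.01, 100.0), b=st.floats(-50.0, 50.0), seed=st.integers(0, 500))
    def test_invariant_under_positive_affine_maps(self, a, b, seed):
        x = np.random.default_rng(seed).random(8)
        assert np.allclose(zscore(a * x + b), zscore(x), atol=1e-8)

    def test_constant_series_rejected_and_dropped(self):
        with pytest.raises(ValueError, match="constant"):
            zscore([5.0, 5.0, 5.0])
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 4.0, 4.0]})
        with pytest.warns(UserWarning, match="constant"):
            Z = zscore_matrix(X)
        assert list(Z.columns) == ["a"]


class TestGRA:
    def test_identical_series_grade_one(self):
        y = np.array([0.1, 0.9, 0.4, 0.7])
        res = gra(_inp(np.column_stack([y, y[::-1]]), y), GRAConfig(normalisation="none"))
        assert res.grades["X1"] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("rho,expected", [(0.5, 5.0 / 9.0), (1.0, 2.0 / 3.0)])
    def test_hand_computed_grades(self, rho, expected):
        # y=(0,.5,1) vs x=(1,.5,0): Delta=(1,0,1); rho=0.5 -> xi=(1/3,1,1/3)
        X = np.array([[1.0], [0.5], [0.0]])
        y = np.array([0.0, 0.5, 1.0])
        res = gra(_inp(X, y), GRAConfig(rho=rho, normalisation="none"))
        assert res.grades["X1"] == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 1000))
    def test_grades_bounded_and_monotone_in_rho(self, seed):
        rng = np.random.default_rng(seed)
        X, y = rng.random((6, 4)) + 0.1, rng.random(6)
        inp = _inp(X, y)
        prev = None
        for rho in (0.1, 0.3, 0.5, 0.8, 1.0):
            g = gra(inp, GRAConfig(rho=rho)).grades
            assert ((g > 0) & (g <= 1)).all()
            if prev is not None:
                assert (g >= prev - 1e-12).all()
            prev = g

    def test_zscore_normalisation_gives_affine_invariance(self, rng):
        X = pd.DataFrame(rng.random((8, 3)) + 0.5, columns=["X1", "X2", "X3"])
        y = rng.random(8)
        base = gra(_inp(X, y)).grades
        X2 = X.copy()
        X2["X2"] = 37.5 * X2["X2"] + 4.0  # e.g. a calibration-curve transform
        again = gra(_inp(X2, y)).grades
        assert np.allclose(base.to_numpy(), again.to_numpy(), atol=1e-10)

    def test_ranks_are_permutation_ordered_by_grade(self, rng):
        X, y = rng.random((7, 5)), rng.random(7)
        res = gra(_inp(X, y))
        assert sorted(res.ranks) == [1, 2, 3, 4, 5]
        ordered = res.grades.loc[res.ranks.sort_values().index]
        assert (ordered.diff().dropna() <= 1e-15).all()

    def test_all_columns_identical_to_y_warns(self):
        y = np.array([0.2, 0.5, 0.9])
        with pytest.warns(UserWarning, match="identical"):
            res = gra(_inp(y[:, None], y), GRAConfig(normalisation="none"))
        assert res.grades["X1"] == pytest.approx(1.0)

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError, match="rho"):
            GRAConfig(rho=0.0)


class TestPLSR:
    def test_single_predictor_matches_simple_ols(self, rng):
        x = rng.random(12)
        y = 3.0 * x + rng.normal(0, 0.1, 12)
        model = plsr_nipals(_inp(x[:, None], y), n_components=1)
        slope, intercept = np.polyfit(x, y, 1)
        pred = model.predict(pd.DataFrame({"X1": x}))
        assert np.allclose(pred, slope * x + intercept, atol=1e-10)

    def test_full_rank_fit_equals_ols(self, rng):
        X = rng.random((10, 5))
        y = rng.random(10)
        inp = _inp(X, y)
        model = plsr_nipals(inp, n_components=5)
        A = np.column_stack([np.ones(10), X])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        assert np.allclose(model.predict(inp.X), A @ beta, atol=1e-8)

    def test_exactly_linear_response_fit_to_machine_precision(self, rng):
        X = rng.random((9, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0]) + 0.7
        inp = _inp(X, y)
        model = plsr_nipals(inp, n_components=4)
        assert np.linalg.norm(model.predict(inp.X) - y) < 1e-8

    def test_score_vectors_orthogonal(self, rng):
        X, y = rng.random((12, 6)), rng.random(12)
        model = plsr_nipals(_inp(X, y), n_components=4)
        G = model.T.T @ model.T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    @pytest.mark.parametrize("n_components", [1, 2, 3])
    def test_matches_independent_simpls_oracle(self, n_components):
        rng = np.random.default_rng(99)
        for _ in range(5):
            X, y = rng.random((10, 5)), rng.random(10)
            inp = _inp(X, y)
            ours = plsr_nipals(inp, n_components=n_components).predict(inp.X)
            oracle = simpls_pls1(X, y, n_components)
            assert np.allclose(ours, oracle, atol=1e-6)

    def test_matches_sklearn_cross_check(self, rng):
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        X, y = rng.random((12, 6)), rng.random(12)
        inp = _inp(X, y)
        ours = plsr_nipals(inp, n_components=2).predict(inp.X)
        ref = sklearn_pls.PLSRegression(n_components=2, scale=True).fit(X, y)
        assert np.allclose(ours, ref.predict(X).ravel(), atol=1e-8)

    def test_rejects_invalid_component_counts_and_constant_response(self, rng):
        X = rng.random((5, 3))
        with pytest.raises(ValueError, match="n_components"):
            plsr_nipals(_inp(X, rng.random(5)), n_components=5)
        with pytest.raises(ValueError, match="constant response"):
            plsr_nipals(_inp(X, np.ones(5)), n_components=1)

    def test_loo_rmse_near_zero_for_noiseless_line(self, rng):
        x = np.linspace(0, 1, 10)
        inp = _inp(x[:, None], 2.0 * x + 1.0)
        assert loo_rmse(inp, 1) < 1e-10


class TestVIP:
    def test_sum_of_squares_equals_predictor_count(self, rng):
        X, y = rng.random((10, 7)), rng.random(10)
        model = plsr_nipals(_inp(X, y), n_components=3)
        v = vip(model)
        assert (v**2).sum() == pytest.approx(7.0, abs=1e-9)

    def test_irrelevant_orthogonal_predictor_scores_zero(self):
        # one component: w ~ X'y, so a predictor orthogonal to y gets weight 0
        y = np.array([-3.0, -1.0, 1.0, 3.0])
        x2 = np.array([1.0, -1.0, -1.0, 1.0])  # orthogonal to y
        X = np.column_stack([y, x2])
        model = plsr_nipals(_inp(X, y), n_components=1)
        v = vip(model)
        assert v["X1"] == pytest.approx(np.sqrt(2.0), abs=1e-9)
        assert v["X2"] == pytest.approx(0.0, abs=1e-9)

    def test_identical_predictors_share_unit_vip(self, rng):
        x = rng.random(8)
        X = np.column_stack([x, x, x])
        y = 2.0 * x + 1.0
        model = plsr_nipals(_inp(X, y), n_components=1)
        assert np.allclose(vip(model).to_numpy(), 1.0, atol=1e-9)


class TestSelectActive:
    def test_zero_thresholds_select_everything_positive(self, rng):
        ids = ["X1", "X2", "X3"]
        g = pd.Series([0.5, 0.6, 0.7], index=ids)
        c = pd.Series([0.1, 0.2, 0.3], index=ids)
        v = pd.Series([0.5, 0.5, 0.5], index=ids)
        res = select_active(g, c, v, g_thr=0.0, v_thr=0.0)
        assert res.selected == ids

    def test_published_grade_filter_keeps_eight_peaks(self):
        grades = printed_gra_grades()
        ones = pd.Series(1.5, index=grades.index)
        res = select_active(grades, ones, ones)
        assert set(res.selected) == {"X4", "X15", "X14", "X8", "X6", "X5", "X9", "X16"}

    def test_sign_failure_lands_in_two_of_three_tier(self):
        ids = ["X1", "X2"]
        g = pd.Series([0.9, 0.9], index=ids)
        c = pd.Series([1.0, -1.0], index=ids)
        v = pd.Series([1.5, 1.5], index=ids)
        res = select_active(g, c, v)
        assert res.selected == ["X1"]
        assert res.two_of_three == ["X2"]

    def test_misaligned_indices_rejected(self):
        g = pd.Series([0.9], index=["X1"])
        c = pd.Series([1.0], index=["X2"])
        with pytest.raises(ValueError, match="peak index"):
            select_active(g, c, g)


class TestPlantedRecovery:
    def test_small_screen_recovers_planted_actives(self):
        truth = EffectSimTruth(("X2", "X5", "X9"), (1.0, 1.0, 1.0), noise_sd=0.1, seed=4)
        matrix, y = simulate_spectrum_effect(15, 12, truth)
        model = plsr_nipals(SpectrumEffectInput(matrix.areas, y), n_components=2)
        top3 = set(vip(model).nlargest(3).index)
        assert top3 == set(truth.active_peak_ids)
        assert (model.coef_std[list(truth.active_peak_ids)] > 0).all()
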