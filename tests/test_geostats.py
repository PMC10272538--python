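"""Variography and kriging: oracles, exactness, and published ratio checks."""

import numpy as np
import pytest

from traitkrige import published as pub
from traitkrige.geostats import (EmpiricalVariogram, VariogramFit, classify_nsr,
                                 empirical_variogram, fit_variogram, model_curve,
                                 ordinary_kriging, regression_kriging)
from traitkrige.synthetic import spatial_field


# ------------------------------------------------------- empirical variogram

def test_variogram_constant_field_zero_everywhere(rng):
    coords = rng.uniform(0, 50, (40, 2))
    emp = empirical_variogram(coords, np.full(40, 7.0))
    assert np.all(emp.gamma == 0)


def test_variogram_two_points_hand_value():
    emp = empirical_variogram(np.array([[0.0, 0.0], [1.0, 0.0]]),
                              np.array([0.0, 2.0]), n_lags=1, max_lag=2.0)
    # gamma = (1 / (2*1)) * (0-2)^2 = 2
    assert emp.gamma[0] == pytest.approx(2.0)
    assert emp.counts[0] == 1


def test_variogram_matches_brute_force_pair_enumeration(rng):
    coords = rng.uniform(0, 100, (30, 2))
    values = rng.normal(size=30)
    n_lags, max_lag = 8, 60.0
    emp = empirical_variogram(coords, values, n_lags=n_lags, max_lag=max_lag)
    width = max_lag / n_lags
    sums = np.zeros(n_lags)
    counts = np.zeros(n_lags, dtype=int)
    for i in range(30):
        for j in range(i + 1, 30):
            d = float(np.hypot(*(coords[i] - coords[j])))
            if d == 0 or d > max_lag:
                continue
            b = min(int(d / width), n_lags - 1)
            sums[b] += (values[i] - values[j]) ** 2
            counts[b] += 1
    keep = counts > 0
    np.testing.assert_allclose(emp.gamma, sums[keep] / (2 * counts[keep]),
                               atol=1e-12)
    np.testing.assert_array_equal(emp.counts, counts[keep])


def test_variogram_rejects_coincident_points():
    with pytest.raises(ValueError):
        empirical_variogram(np.zeros((5, 2)), np.arange(5.0))


# ------------------------------------------------------------- model curves

@pytest.mark.parametrize("form", ["linear", "spherical", "exponential", "gaussian"])
def test_model_curve_nugget_at_origin(form):
    assert model_curve(form, 0.3, 0.7, 25.0, 0.0) == pytest.approx(0.3)


def test_model_curve_known_points():
    assert model_curve("spherical", 0.1, 0.9, 20.0, 20.0) == pytest.approx(1.0)
    assert model_curve("exponential", 0.1, 0.9, 20.0, 20.0) == pytest.approx(
        0.1 + 0.9 * (1 - np.exp(-3)))
    # beyond the range the spherical and linear forms sit at the sill
    assert model_curve("spherical", 0.1, 0.9, 20.0, 50.0) == pytest.approx(1.0)
    assert model_curve("linear", 0.1, 0.9, 20.0, 50.0) == pytest.approx(1.0)


def test_model_curve_unknown_form():
    with pytest.raises(ValueError):
        model_curve("cubic", 0, 1, 10, 5.0)


# ----------------------------------------------------------------- fitting

@pytest.mark.parametrize("form", ["spherical", "exponential", "gaussian"])
def test_fit_recovers_noise_free_curve(form):
    h = np.linspace(3, 60, 10)
    g = model_curve(form, 0.2, 0.8, 30.0, h)
    emp = EmpiricalVariogram(h, g, np.full(10, 50), 60.0, 6.0)
    fit = fit_variogram(emp)
    assert fit.form == form
    assert fit.nugget == pytest.approx(0.2, rel=0.01, abs=1e-3)
    assert fit.sill == pytest.approx(1.0, rel=0.01)
    assert fit.range_ == pytest.approx(30.0, rel=0.01)


def test_fit_requires_enough_bins():
    h = np.array([1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        fit_variogram(EmpiricalVariogram(h, h, np.ones(3), 3.0, 1.0))


# ---------------------------------------------------- nugget-sill ratio

@pytest.mark.parametrize("case", pub.NSR_EXAMPLES)
def test_published_nugget_sill_ratios(case):
    ratio, cls = classify_nsr(case["c0"], case["sill"])
    assert ratio == pytest.approx(case["ratio"], abs=0.1)
    assert cls == case["class"]


def test_classify_nsr_rule_boundaries():
    assert classify_nsr(0.0, 1.0) == (0.0, "strong")
    assert classify_nsr(0.8, 1.0) == (80.0, "weak")
    assert classify_nsr(0.5, 1.0)[1] == "moderate"
    with pytest.raises(ValueError):
        classify_nsr(0.1, 0.0)


# ------------------------------------------------------------------ kriging

def fit_for(form="exponential", c0=0.0, c=1.0, a=30.0):
    return VariogramFit(form, c0, c, a, 1.0, 0.0)


def test_ok_exact_at_sample_locations(rng):
    coords = rng.uniform(0, 100, (25, 2))
    values = rng.normal(size=25)
    preds, var = ordinary_kriging(coords, values, fit_for(), coords)
    np.testing.assert_allclose(preds, values, atol=1e-8)
    np.testing.assert_allclose(var, 0.0, atol=1e-8)


def test_ok_symmetric_cluster_predicts_mean():
    ang = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    coords = 10 * np.column_stack([np.cos(ang), np.sin(ang)])
    values = np.arange(8.0)
    preds, _ = ordinary_kriging(coords, values, fit_for(), [[0.0, 0.0]])
    assert preds[0] == pytest.approx(values.mean())


def test_ok_weights_sum_to_one_and_matches_dense_oracle(rng):
    """Independent oracle: assemble and solve the OK system densely."""
    from scipy.spatial.distance import cdist

    coords = rng.uniform(0, 100, (20, 2))
    values = rng.normal(size=20)
    targets = rng.uniform(0, 100, (7, 2))
    fit = fit_for(c0=0.1, c=0.9, a=25.0)
    preds, _ = ordinary_kriging(coords, values, fit, targets)

    for t, target in enumerate(targets):
        n = len(coords)
        A = np.zeros((n + 1, n + 1))
        D = cdist(coords, coords)
        G = fit(D)
        G[D == 0] = 0.0
        A[:n, :n] = G
        A[n, :n] = A[:n, n] = 1.0
        b = np.zeros(n + 1)
        d0 = cdist([target], coords).ravel()
        g0 = fit(d0)
        g0[d0 == 0] = 0.0
        b[:n] = g0
        b[n] = 1.0
        sol = np.linalg.lstsq(A, b, rcond=None)[0]
        assert sol[:n].sum() == pytest.approx(1.0, abs=1e-10)
        assert preds[t] == pytest.approx(float(sol[:n] @ values), abs=1e-8)


def test_ok_rejects_duplicate_coordinates():
    coords = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
    with pytest.raises(ValueError, match="duplicate"):
        ordinary_kriging(coords, np.arange(3.0), fit_for(), [[0.5, 0.5]])


# -------------------------------------------------------- regression kriging

def test_rk_zero_residuals_returns_trend(rng):
    coords = rng.uniform(0, 100, (30, 2))
    trend = rng.normal(size=30)
    with pytest.warns(UserWarning, match="zero"):
        rk = regression_kriging(trend, coords, np.zeros(30), coords)
    np.testing.assert_array_equal(rk.prediction, rk.trend)


def test_rk_constant_trend_equals_ok(rng):
    """Shift invariance: constant trend + OK of anomalies == OK of raw values."""
    coords = rng.uniform(0, 100, (40, 2))
    values = spatial_field(coords, "exponential", 0.05, 0.95, 30.0, 5)
    targets = rng.uniform(0, 100, (15, 2))
    c = 3.7
    rk = regression_kriging(np.full(15, c), coords, values - c, targets)
    ok_preds, _ = ordinary_kriging(coords, values, rk.residual_fit, targets)
    np.testing.assert_allclose(rk.prediction, ok_preds, atol=1e-8)


def test_rk_improves_on_trend_only():
    """Trend + kriged residuals beats the bare trend on a planted surface."""
    wins = 0
    for seed in range(10):
        rng = np.random.default_rng(200 + seed)
        coords = rng.uniform(0, 100, (120, 2))
        trend_true = 0.05 * coords[:, 0] + 0.02 * coords[:, 1]
        resid = spatial_field(coords, "exponential", 0.05, 0.45, 40.0, rng)
        z = trend_true + resid
        # fit the trend on half the points, predict everywhere
        half = rng.permutation(120)[:60]
        beta = np.linalg.lstsq(
            np.column_stack([np.ones(60), coords[half]]), z[half], rcond=None)[0]
        trend_hat = beta[0] + coords @ beta[1:]
        rk = regression_kriging(trend_hat, coords[half], z[half] - trend_hat[half],
                                coords)
        rmse_trend = np.sqrt(np.mean((trend_hat - z) ** 2))
        rmse_rk = np.sqrt(np.mean((rk.prediction - z) ** 2))
        wins += rmse_rk < rmse_trend
    assert wins >= 8
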