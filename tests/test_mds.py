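"""Factor model, Norm values, grouping and MDS selection."""

import numpy as np
import pandas as pd
import pytest

from conftest import block_trait_table
from traitkrige import published as pub
from traitkrige.mds import (FactorModel, bartlett, build_mds, cumulative_contribution,
                            fit_factor_model, group_traits, kmo, norm_values,
                            select_mds, RESIDUAL)


def table_from_corr(R, n, seed=0, cols=None):
    """Sample a table whose empirical correlation converges to R."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, len(R))) @ np.linalg.cholesky(np.asarray(R)).T
    cols = cols or [f"v{i}" for i in range(len(R))]
    df = pd.DataFrame(X, columns=cols)
    df.insert(0, "plot", "A")
    df.insert(1, "subplot", np.arange(len(df)))
    df.insert(2, "x", 0.0)
    df.insert(3, "y", 0.0)
    return df


# ---------------------------------------------------------------- KMO/Bartlett

def test_kmo_two_variables_is_half():
    # with p=2 the partial correlation equals the correlation, so KMO = 0.5
    df = table_from_corr([[1, 0.6], [0.6, 1]], 50, seed=1)
    assert kmo(df) == pytest.approx(0.5, abs=1e-12)


def test_kmo_matches_regression_residual_oracle():
    """Anti-image partials equal correlations of full-regression residuals."""
    R = np.array([[1, .5, .3, .2, .1], [.5, 1, .4, .25, .15],
                  [.3, .4, 1, .35, .2], [.2, .25, .35, 1, .3],
                  [.1, .15, .2, .3, 1]])
    df = table_from_corr(R, 400, seed=2)
    cols = [c for c in df.columns if c.startswith("v")]
    X = df[cols].to_numpy()
    Xc = X - X.mean(0)
    Re = np.corrcoef(X, rowvar=False)
    p = len(cols)
    r2 = p2 = 0.0
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            r2 += Re[i, j] ** 2
            others = [k for k in range(p) if k not in (i, j)]
            Z = Xc[:, others]
            beta_i = np.linalg.lstsq(Z, Xc[:, i], rcond=None)[0]
            beta_j = np.linalg.lstsq(Z, Xc[:, j], rcond=None)[0]
            ri, rj = Xc[:, i] - Z @ beta_i, Xc[:, j] - Z @ beta_j
            p2 += np.corrcoef(ri, rj)[0, 1] ** 2
    assert kmo(df) == pytest.approx(r2 / (r2 + p2), abs=1e-8)


def test_kmo_strong_single_factor_exceeds_070():
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        f = rng.standard_normal(300)
        X = 0.9 * f[:, None] + np.sqrt(1 - 0.81) * rng.standard_normal((300, 6))
        df = pd.DataFrame(X, columns=[f"v{i}" for i in range(6)])
        df.insert(0, "plot", "A"); df.insert(1, "subplot", range(300))
        df.insert(2, "x", 0.0); df.insert(3, "y", 0.0)
        hits += kmo(df) > 0.7
    assert hits == 20


def test_kmo_bounds_and_constant_column_error():
    df = table_from_corr([[1, .4], [.4, 1]], 30, seed=3)
    assert 0.0 <= kmo(df) <= 1.0
    df["v0"] = 1.0
    with pytest.raises(ValueError, match="v0"):
        kmo(df)


def test_bartlett_matches_direct_formula_and_is_nonnegative():
    df = table_from_corr(np.full((4, 4), 0.5) + 0.5 * np.eye(4), 100, seed=4)
    chi2, df_, p = bartlett(df)
    cols = [c for c in df.columns if c.startswith("v")]
    R = df[cols].corr().to_numpy()
    n, k = len(df), len(cols)
    expected = -(n - 1 - (2 * k + 5) / 6) * np.log(np.linalg.det(R))
    assert chi2 == pytest.approx(expected, rel=1e-10)
    assert df_ == k * (k - 1) // 2
    assert chi2 >= 0 and 0 <= p <= 1


def test_bartlett_near_identity_correlation_small_statistic():
    # orthogonalised columns -> R ~ I -> statistic ~ 0, p ~ 1
    rng = np.random.default_rng(5)
    X = rng.standard_normal((60, 4))
    Q, _ = np.linalg.qr(X - X.mean(0))   # zero-mean orthogonal columns -> R = I
    df = pd.DataFrame(Q, columns=list("abcd"))
    df.insert(0, "plot", "A"); df.insert(1, "subplot", range(60))
    df.insert(2, "x", 0.0); df.insert(3, "y", 0.0)
    chi2, _, p = bartlett(df)
    assert chi2 == pytest.approx(0.0, abs=1e-8)
    assert p == pytest.approx(1.0, abs=1e-8)


def test_bartlett_insufficient_rows():
    df = table_from_corr([[1, .5], [.5, 1]], 2, seed=6)
    with pytest.raises(ValueError):
        bartlett(df)


# ---------------------------------------------------------------- factor model

def test_factor_model_trace_identity_and_block_structure():
    table = block_trait_table(seed=0)
    model = fit_factor_model(table, check_adequacy=False)
    p = len(model.traits)
    assert model.eigenvalues_all.sum() == pytest.approx(p, abs=1e-8)
    assert np.all(np.diff(model.cumulative) >= -1e-12)
    # five planted blocks -> five retained components with clean structure
    assert model.n_components == 5
    for i, trait in enumerate(model.traits[:15]):
        loads = np.abs(model.loadings[i])
        assert loads.max() > 0.8
        assert np.sort(loads)[-2] < 0.3   # no cross-loading


def test_factor_model_warns_on_null_data():
    rng = np.random.default_rng(8)
    df = pd.DataFrame(rng.standard_normal((2000, 16)),
                      columns=[f"v{i}" for i in range(16)])
    df.insert(0, "plot", "A"); df.insert(1, "subplot", range(2000))
    df.insert(2, "x", 0.0); df.insert(3, "y", 0.0)
    with pytest.warns(UserWarning, match="near 1"):
        fit_factor_model(df, check_adequacy=False)


# ----------------------------------------------------------------- Norm values

def test_norm_single_component_closed_form():
    assert norm_values(np.array([[0.8]]), np.array([2.5])) == \
        pytest.approx(0.8 * np.sqrt(2.5))


def test_norm_matches_double_loop_oracle():
    rng = np.random.default_rng(9)
    U = rng.uniform(-1, 1, (10, 4))
    lam = rng.uniform(1, 4, 4)
    expected = [np.sqrt(sum(U[i, k] ** 2 * lam[k] for k in range(4)))
                for i in range(10)]
    np.testing.assert_allclose(norm_values(U, lam), expected, atol=1e-10)


@pytest.mark.parametrize("trait, expected", [
    ("SLA", 1.620), ("LWC", 1.446), ("LDW", 1.753), ("H", 0.590),
])
def test_norm_reproduces_published_woody_values(trait, expected):
    n = norm_values(pub.WOODY_LOADINGS.loc[trait].to_numpy(), pub.WOODY_EIGENVALUES)
    assert n == pytest.approx(expected, abs=0.005)


def test_norm_reproduces_published_herbaceous_values():
    n = norm_values(pub.HERB_LOADINGS.loc["LFW"].to_numpy(), pub.HERB_EIGENVALUES)
    assert n == pytest.approx(2.307, abs=0.005)


def test_cumulative_contribution_running_sum():
    cum = cumulative_contribution(pub.WOODY_CONTRIBUTIONS)
    assert cum[-1] == pytest.approx(pub.WOODY_CUMULATIVE_PRINTED, abs=0.01)


# ------------------------------------------------------------ grouping & MDS

def published_model(loadings, eigenvalues):
    return FactorModel(list(loadings.index), loadings.to_numpy(), eigenvalues,
                       eigenvalues)


def test_grouping_is_partition_for_random_loadings():
    rng = np.random.default_rng(10)
    for _ in range(10):
        U = rng.uniform(-1, 1, (12, 4))
        model = FactorModel([f"t{i}" for i in range(12)], U,
                            rng.uniform(1, 3, 4), rng.uniform(1, 3, 4))
        groups = group_traits(model)
        seen = [t for g in groups for t in g.traits]
        assert sorted(seen) == sorted(model.traits)


def test_grouping_all_weak_loadings_single_residual_group():
    model = FactorModel(["a", "b", "c"], np.full((3, 2), 0.2),
                        np.array([1.5, 1.2]), np.array([1.5, 1.2]))
    groups = group_traits(model)
    assert len(groups) == 1 and groups[0].pc == RESIDUAL


def test_published_woody_grouping_and_selection():
    model = published_model(pub.WOODY_LOADINGS, pub.WOODY_EIGENVALUES)
    corr = pub.narrated_correlation(pub.WOODY_LOADINGS)
    groups = group_traits(model, corr=corr)
    assert len(groups) == 7
    residual = [g for g in groups if g.pc == RESIDUAL][0]
    assert set(residual.traits) == {"LC", "LN", "LP", "H", "LL"}
    sel = select_mds(groups, corr)
    assert set(sel.retained) == pub.WOODY_MDS_PUBLISHED


def test_published_herbaceous_grouping_and_selection():
    model = published_model(pub.HERB_LOADINGS, pub.HERB_EIGENVALUES)
    corr = pub.narrated_correlation(pub.HERB_LOADINGS)
    groups = group_traits(model, corr=corr)
    assert len(groups) == 6
    sel = select_mds(groups, corr)
    assert set(sel.retained) == pub.HERB_MDS_PUBLISHED


def test_singleton_group_auto_retained():
    model = published_model(pub.WOODY_LOADINGS, pub.WOODY_EIGENVALUES)
    corr = pub.narrated_correlation(pub.WOODY_LOADINGS)
    groups = group_traits(model, corr=corr)
    dbh_group = [g for g in groups if g.traits == ["DBH"]]
    assert dbh_group
    sel = select_mds(dbh_group, corr)
    assert sel.retained == ["DBH"]


def test_planted_blocks_recover_one_trait_each():
    """MDS selection keeps exactly one trait from every planted factor block."""
    hits = 0
    for seed in range(20):
        table = block_trait_table(seed=seed)
        _, _, sel = build_mds(table, check_adequacy=False)
        per_block = [sum(1 for t in sel.retained if t != "Tw" and int(t[1:]) // 3 == b)
                     for b in range(5)]
        hits += per_block == [1] * 5
    assert hits >= 18
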