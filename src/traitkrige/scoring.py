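"""Functional trait evaluation indices (FTEI) and MDS-vs-TDS cross-validation.

Each trait in a data set gets a score in (0, 1]:

* linear — S = x / x_max for positive traits (more is better) or
  S = x_min / x for negative traits;
* non-linear — S = a / (1 + (x/x_m)^b) with a = 1 and slope b = -2.5 for
  positive traits, +2.5 for negative ones (x_m is the trait mean).

Scores combine into FTEI_A (plain average) or FTEI_W (weighted sum with
weights from the factor model's component variances). The minimum data set
is validated by regressing the total-data-set FTEI on the MDS FTEI across
subplots for all four method pairs {W, A} x {linear, non-linear}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mds import FactorModel, MDSSelection, TraitGroup, RESIDUAL, trait_columns

SLOPE_POSITIVE = -2.5
SLOPE_NEGATIVE = 2.5


@dataclass
class ScoringSpec:
    """Per-trait scoring directions and non-linear slope settings."""

    directions: dict = field(default_factory=dict)   # trait -> "positive"|"negative"
    method: str = "linear"                           # "linear" | "nonlinear"
    a: float = 1.0

    def direction(self, trait: str) -> str:
        d = self.directions.get(trait, "positive")
        if d not in ("positive", "negative"):
            raise ValueError(f"direction for {trait} must be positive|negative")
        return d

    def slope(self, trait: str) -> float:
        return SLOPE_POSITIVE if self.direction(trait) == "positive" else SLOPE_NEGATIVE


def linear_score(x, x_min: float, x_max: float, direction: str = "positive"):
    """Eqs. S = x/x_max (positive trait) or x_min/x (negative trait)."""
    x = np.asarray(x, dtype=float)
    if direction == "positive":
        if x_max == 0:
            raise ZeroDivisionError("x_max is zero")
        s = x / x_max
    elif direction == "negative":
        if np.any(x == 0):
            raise ZeroDivisionError("negative-direction score divides by x")
        s = x_min / x
    else:
        raise ValueError("direction must be positive|negative")
    return s if s.shape else float(s)


def nonlinear_score(x, x_m: float, a: float = 1.0, b: float = SLOPE_POSITIVE):
    """Sigmoid score a / (1 + (x/x_m)^b)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0) or x_m <= 0:
        raise ValueError("non-linear score requires x, x_m > 0")
    s = a / (1.0 + (x / x_m) ** b)
    return s if s.shape else float(s)


def ftei(scores, weights=None):
    """FTEI_A (mean of scores) or FTEI_W (weighted sum) per subplot.

    ``scores`` is (n_subplots, n_traits) or a 1-D per-trait vector.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if weights is None:
        out = scores.mean(axis=1)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape[0] != scores.shape[1]:
            raise ValueError("weights/scores length mismatch")
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-9):
            raise ValueError("weights must be non-negative and sum to 1")
        out = scores @ w
    return out if len(out) > 1 else float(out[0])


def score_table(trait_table: pd.DataFrame, traits, spec: ScoringSpec) -> pd.DataFrame:
    """Score every trait column over all subplots (pooled min/max/mean)."""
    out = {}
    for t in traits:
        x = trait_table[t].to_numpy(dtype=float)
        if spec.method == "linear":
            out[t] = linear_score(x, x.min(), x.max(), spec.direction(t))
        elif spec.method == "nonlinear":
            out[t] = nonlinear_score(x, x.mean(), spec.a, spec.slope(t))
        else:
            raise ValueError("method must be linear|nonlinear")
    return pd.DataFrame(out, index=trait_table.index)


def eigenvalue_weights(model: FactorModel, groups: list[TraitGroup], traits) -> np.ndarray:
    """Component-variance weights W_i for FTEI_W.

    Each trait's weight is the variance of its defining component divided by
    the total over the selected traits; a residual-group trait uses the
    component where its |loading| is largest.
    """
    pc_of = {}
    for g in groups:
        for t in g.traits:
            pc_of[t] = g.pc
    raw = []
    for t in traits:
        pc = pc_of.get(t, RESIDUAL)
        if pc == RESIDUAL:
            i = model.traits.index(t)
            pc = int(np.argmax(np.abs(model.loadings[i])))
        raw.append(model.eigenvalues[pc])
    raw = np.asarray(raw, dtype=float)
    return raw / raw.sum()


@dataclass
class CrossValResult:
    r2: dict            # method label -> R^2
    pvalues: dict
    slopes: dict
    ftei_table: pd.DataFrame


def crossval_mds_vs_tds(trait_table: pd.DataFrame, model: FactorModel,
                        groups: list[TraitGroup], selection: MDSSelection,
                        spec: ScoringSpec | None = None) -> CrossValResult:
    """Regress TDS FTEI on MDS FTEI for {W, A} x {linear, non-linear}.

    The TDS weighting mirrors the MDS rule using the same factor model's
    component variances.
    """
    if len(trait_table) < 3:
        raise ValueError("need at least 3 subplots")
    spec = spec or ScoringSpec()
    tds_traits = trait_columns(trait_table)
    mds_traits = list(selection.retained)

    r2, pv, slopes = {}, {}, {}
    cols = {}
    for method in ("linear", "nonlinear"):
        mspec = ScoringSpec(spec.directions, method, spec.a)
        s_mds = score_table(trait_table, mds_traits, mspec).to_numpy()
        s_tds = score_table(trait_table, tds_traits, mspec).to_numpy()
        w_mds = eigenvalue_weights(model, groups, mds_traits)
        w_tds = eigenvalue_weights(model, groups, tds_traits)
        variants = {
            f"FTEI_W-{'L' if method == 'linear' else 'NL'}":
                (np.atleast_1d(ftei(s_mds, w_mds)), np.atleast_1d(ftei(s_tds, w_tds))),
            f"FTEI_A-{'L' if method == 'linear' else 'NL'}":
                (np.atleast_1d(ftei(s_mds)), np.atleast_1d(ftei(s_tds))),
        }
        for label, (x, y) in variants.items():
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                raise ValueError(f"zero-variance FTEI for {label}")
            res = stats.linregress(x, y)
            r2[label] = float(res.rvalue ** 2)
            pv[label] = float(res.pvalue)
            slopes[label] = float(res.slope)
            cols[f"MDS_{label}"] = x
            cols[f"TDS_{label}"] = y
    table = pd.DataFrame(cols, index=trait_table.index)
    return CrossValResult(r2, pv, slopes, table)
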