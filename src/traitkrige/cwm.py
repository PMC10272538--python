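"""Community-weighted means and pre-analysis screening.

CWM of a trait in a subplot is the abundance-weighted average over the
species present: CWM = sum(A_i * trait_i) / sum(A_i). Also provides the
normality screen with Box-Cox fallback applied before variography, and
one-way ANOVA with Tukey-HSD compact letter display for comparing plots.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

INDEX_COLS = ("plot", "subplot", "x", "y")


def compute_cwm(observations: pd.DataFrame, traits=None) -> pd.DataFrame:
    """Per-subplot community-weighted means of trait columns.

    ``observations`` holds one row per species record with columns
    plot, subplot, x, y, abundance and one column per trait. Subplots whose
    total abundance is zero are excluded (flagged by warning), never set to
    zero.
    """
    obs = observations
    if traits is None:
        skip = set(INDEX_COLS) | {"species", "life_form", "abundance"}
        traits = [c for c in obs.columns if c not in skip]
    if (obs["abundance"] < 0).any():
        raise ValueError("abundances must be non-negative")

    out = []
    for key, grp in obs.groupby(["plot", "subplot"], sort=True):
        total = grp["abundance"].sum()
        if total <= 0:
            warnings.warn(f"subplot {key} has zero total abundance; excluded")
            continue
        w = grp["abundance"].to_numpy() / total
        row = {"plot": key[0], "subplot": key[1],
               "x": grp["x"].iloc[0], "y": grp["y"].iloc[0]}
        for t in traits:
            row[t] = float(w @ grp[t].to_numpy())
        out.append(row)
    if not out:
        raise ValueError("no subplot with positive total abundance")
    return pd.DataFrame(out)


def boxcox_if_needed(values, alpha: float = 0.05):
    """Shapiro–Wilk screen; Box-Cox transform (ML lambda) only on rejection.

    Returns ``(values, None)`` when normality is not rejected at ``alpha``,
    else ``(transformed, lambda)``. Raises on non-positive input rather than
    shifting silently — shift the data explicitly and rerun.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ValueError("Box-Cox requires strictly positive values; "
                         "shift the variable explicitly before calling")
    if np.ptp(values) == 0:
        raise ValueError("constant vector: normality test undefined")
    _, p = stats.shapiro(values)
    if p >= alpha:
        return values, None
    transformed, lam = stats.boxcox(values)
    _, p2 = stats.shapiro(transformed)
    if p2 < alpha:
        warnings.warn(f"Box-Cox output still non-normal (p={p2:.3g})")
    return transformed, float(lam)


def anova_letters(values_by_plot: dict, alpha: float = 0.05):
    """One-way ANOVA plus Tukey-HSD compact letter display across plots.

    Plots not significantly different share a letter; letters are assigned
    in descending order of group mean starting from "a". Returns
    ``(letters: dict plot->str, anova_p: float)``.
    """
    names = list(values_by_plot)
    groups = [np.asarray(values_by_plot[k], dtype=float) for k in names]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 plots with >= 2 values each")
    if all(np.ptp(g) == 0 for g in groups):
        raise ValueError("zero within-group variance everywhere: ANOVA undefined")

    _, anova_p = stats.f_oneway(*groups)
    k = len(groups)
    sig = np.zeros((k, k), dtype=bool)
    if k == 2:
        _, p = stats.ttest_ind(groups[0], groups[1])
        sig[0, 1] = sig[1, 0] = p < alpha
    else:
        res = stats.tukey_hsd(*groups)
        for i in range(k):
            for j in range(i + 1, k):
                sig[i, j] = sig[j, i] = res.pvalue[i, j] < alpha

    # insert-and-absorb compact letter display on mean-sorted groups
    order = np.argsort([-g.mean() for g in groups])
    letter_sets: list[set[int]] = []   # each letter = set of group indices sharing it
    for gi in order:
        placed = False
        for s in letter_sets:
            if not any(sig[gi, other] for other in s):
                s.add(gi)
                placed = True
        if not placed:
            letter_sets.append({gi})
    # drop letter sets fully contained in another (absorption)
    letter_sets = [s for i, s in enumerate(letter_sets)
                   if not any(s < t for j, t in enumerate(letter_sets) if i != j)]
    letters = {name: "" for name in names}
    for li, s in enumerate(letter_sets):
        ch = chr(ord("a") + li)
        for gi in s:
            letters[names[gi]] += ch
    letters = {name: "".join(sorted(v)) for name, v in letters.items()}
    return letters, float(anova_p)


def anova_report(trait_table: pd.DataFrame, traits, alpha: float = 0.05) -> pd.DataFrame:
    """Per-trait plot comparison table (mean per plot with its letter code)."""
    rows = []
    for t in traits:
        by_plot = {p: g[t].to_numpy() for p, g in trait_table.groupby("plot")}
        letters, p = anova_letters(by_plot, alpha=alpha)
        row = {"trait": t, "anova_p": p}
        for plot, vals in by_plot.items():
            row[plot] = f"{np.mean(vals):.3f} {letters[plot]}"
        rows.append(row)
    return pd.DataFrame(rows)
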