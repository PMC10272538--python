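"""Composite ecosystem-function indices for C, N and P cycling.

EF = (1/n) * sum_i g(r_i(f_i)) — each member indicator is made positive
(r), min–max normalised to [0, 1] across subplots (g), and averaged with
equal weight. Default indicator sets: C = plant/soil organic carbon;
N = soil nitrate, ammonium and total N plus leaf total N; P = soil
available and total P plus leaf total P.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .synthetic import CHEMISTRY_INDICATORS


def compute_ef(chemistry: pd.DataFrame, indicators: dict | None = None,
               groupby_plot: bool = False) -> pd.DataFrame:
    """Per-subplot EF value per function (columns C, N, P).

    ``indicators`` maps function name -> tuple of chemistry columns
    (defaults to the standard C/N/P sets). Normalisation is global across
    the whole table by default; ``groupby_plot`` switches to per-plot.
    """
    indicators = indicators or CHEMISTRY_INDICATORS
    out = chemistry[[c for c in ("plot", "subplot", "x", "y") if c in chemistry]].copy()

    def minmax(col: pd.Series, name: str) -> pd.Series:
        lo, hi = col.min(), col.max()
        if hi == lo:
            raise ValueError(f"indicator {name!r} is constant; min-max undefined")
        return (col - lo) / (hi - lo)

    for fn, cols in indicators.items():
        if not cols:
            raise ValueError(f"function {fn} has no indicators")
        normed = []
        for c in cols:
            if c not in chemistry:
                raise KeyError(f"indicator column {c!r} missing from chemistry table")
            v = chemistry[c].astype(float)
            if not np.isfinite(v).all():
                raise ValueError(f"indicator {c!r} has non-finite values")
            if (v < 0).any():
                warnings.warn(f"indicator {c!r} has negative values; using |value|")
                v = v.abs()
            if groupby_plot:
                n = v.groupby(chemistry["plot"]).transform(lambda s: minmax(s, c))
            else:
                n = minmax(v, c)
            normed.append(n)
        out[fn] = pd.concat(normed, axis=1).mean(axis=1)
    return out
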