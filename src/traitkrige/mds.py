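"""Minimum-data-set construction from trait CWM tables.

Workflow: sampling-adequacy tests (KMO, Bartlett sphericity) -> principal
factor model on the trait correlation matrix (components with eigenvalue
>= 1 retained, varimax rotation optional but on by default) -> per-trait
Norm value, the combined loading across retained components,

    N_i = sqrt( sum_k U_ik^2 * lambda_k ),

-> grouping of traits by the component where |loading| >= 0.5 (traits
clearing the threshold nowhere form a residual group; double-loaders go to
the group they correlate with least) -> retention: within each group keep
traits whose Norm is within 10% of the group maximum, then resolve
candidate pairs by correlation (|r| >= 0.5 keeps only the higher-Norm
trait, coefficient of variation breaking ties; |r| < 0.5 keeps both).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cwm import INDEX_COLS

RESIDUAL = "residual"


def trait_columns(trait_table: pd.DataFrame) -> list[str]:
    skip = set(INDEX_COLS) | {"species", "life_form", "abundance"}
    return [c for c in trait_table.columns if c not in skip]


def _corr_matrix(trait_table: pd.DataFrame) -> tuple[np.ndarray, list[str], int]:
    cols = trait_columns(trait_table)
    X = trait_table[cols].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    for name, s in zip(cols, sd):
        if s == 0:
            raise ValueError(f"trait column {name!r} is constant")
    return np.corrcoef(X, rowvar=False), cols, len(X)


def kmo(trait_table: pd.DataFrame) -> float:
    """Overall Kaiser–Meyer–Olkin measure of sampling adequacy.

    KMO = sum(r^2) / (sum(r^2) + sum(p^2)) over off-diagonal entries, where
    p are the anti-image partial correlations -S_ij/sqrt(S_ii S_jj) with
    S the inverse correlation matrix.
    """
    if len(trait_table) < 3:
        raise ValueError("need at least 3 subplots for KMO")
    R, cols, _ = _corr_matrix(trait_table)
    try:
        S = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        warnings.warn("correlation matrix singular; using pseudo-inverse")
        S = np.linalg.pinv(R)
    d = np.sqrt(np.outer(np.diag(S), np.diag(S)))
    partial = -S / d
    off = ~np.eye(len(R), dtype=bool)
    r2 = np.sum(R[off] ** 2)
    p2 = np.sum(partial[off] ** 2)
    return float(r2 / (r2 + p2))


def bartlett(trait_table: pd.DataFrame):
    """Bartlett's test of sphericity: (chi2, df, p)."""
    R, cols, n = _corr_matrix(trait_table)
    p = len(cols)
    if n < 3:
        raise ValueError("need at least 3 subplots for Bartlett's test")
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("correlation matrix has non-positive determinant")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    return float(chi2), int(df), float(stats.chi2.sf(chi2, df))


def varimax(loadings: np.ndarray, max_iter: int = 200, tol: float = 1e-8) -> np.ndarray:
    """Orthogonal varimax rotation of a loading matrix (Kaiser, unnormalised)."""
    p, k = loadings.shape
    if k < 2:
        return L
    rot = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        lam = loadings @ rot
        u, s, vt = np.linalg.svd(
            loadings.T @ (lam ** 3 - lam @ np.diag(np.sum(lam ** 2, axis=0)) / p))
        rot = u @ vt
        var_new = s.sum()
        if var_new - var_old < tol:
            break
        var_old = var_new
    return loadings @ rot


@dataclass
class FactorModel:
    """Retained-component factor model of a trait correlation matrix."""

    traits: list
    loadings: np.ndarray            # traits x retained components
    eigenvalues: np.ndarray         # variance per retained component
    eigenvalues_all: np.ndarray     # full spectrum of the correlation matrix
    contributions: np.ndarray = field(init=False)   # % of total variance
    cumulative: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        p = len(self.traits)
        self.contributions = 100.0 * np.asarray(self.eigenvalues) / p
        self.cumulative = cumulative_contribution(self.contributions)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def cumulative_contribution(rates) -> np.ndarray:
    """Running sum of per-component variance-contribution rates (%)."""
    return np.cumsum(np.asarray(rates, dtype=float))


def fit_factor_model(trait_table: pd.DataFrame, rotate: bool = True,
                     min_kmo: float = 0.5, max_bartlett_p: float = 0.05,
                     check_adequacy: bool = True) -> FactorModel:
    """Principal factor model with eigenvalue >= 1 retention.

    Eigen-decomposes the CWM correlation matrix, retains components with
    eigenvalue >= 1, optionally varimax-rotates the retained loadings, and
    applies a deterministic sign convention (largest-|loading| entry of each
    component made positive). After rotation the reported per-component
    variance is the column sum of squared loadings.
    """
    if check_adequacy:
        k = kmo(trait_table)
        _, _, bp = bartlett(trait_table)
        if k < min_kmo or bp > max_bartlett_p:
            raise ValueError(f"data unsuitable for factor analysis "
                             f"(KMO={k:.3f}, Bartlett p={bp:.3g})")
    R, cols, _ = _corr_matrix(trait_table)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    retained = eigval >= 1.0
    if not retained.any():
        raise ValueError("no component with eigenvalue >= 1")
    near_one = np.sum(np.abs(eigval - 1.0) < 0.15)
    if near_one >= len(cols) / 2:
        warnings.warn("many eigenvalues near 1: retained-component count unstable")

    L = eigvec[:, retained] * np.sqrt(eigval[retained])
    if rotate:
        L = varimax(L)
    comp_var = np.sum(L ** 2, axis=0)
    order2 = np.argsort(comp_var)[::-1]
    L, comp_var = L[:, order2], comp_var[order2]
    # sign convention: dominant loading of each component positive
    for j in range(L.shape[1]):
        i = np.argmax(np.abs(L[:, j]))
        if L[i, j] < 0:
            L[:, j] = -L[:, j]
    return FactorModel(cols, L, comp_var, eigval)


def norm_values(loadings, eigenvalues, traits=None):
    """Norm value per trait: sqrt(sum over retained PCs of U^2 * lambda)."""
    U = np.asarray(loadings, dtype=float)
    lam = np.asarray(eigenvalues, dtype=float)
    if U.ndim == 1:
        U = U[None, :]
    if U.shape[1] != len(lam):
        raise ValueError("loadings/eigenvalue dimension mismatch")
    norms = np.sqrt((U ** 2) @ lam)
    if traits is not None:
        return pd.Series(norms, index=list(traits))
    return norms if len(norms) > 1 else float(norms[0])


@dataclass
class TraitGroup:
    index: int
    traits: list
    pc: object          # defining component index, or "residual"
    norms: dict


@dataclass
class MDSSelection:
    retained: list
    trace: list         # per-group dicts describing each decision


def group_traits(model: FactorModel, loading_threshold: float = 0.5,
                 corr: pd.DataFrame | None = None) -> list[TraitGroup]:
    """Partition traits into component groups plus one residual group.

    A trait joins the component where its |loading| clears the threshold.
    A trait clearing it on two components joins the group whose other
    members it correlates with least (mean |r|), which needs ``corr``; with
    no correlation matrix the larger |loading| decides, with a warning.
    Traits clearing the threshold nowhere form the residual group.
    """
    norms = norm_values(model.loadings, model.eigenvalues, model.traits)
    assignment: dict[str, object] = {}
    hits_by_pc: dict[int, list[str]] = {}
    multi = []
    for i, trait in enumerate(model.traits):
        hits = [j for j in range(model.n_components)
                if abs(model.loadings[i, j]) >= loading_threshold]
        if not hits:
            assignment[trait] = RESIDUAL
        elif len(hits) == 1:
            assignment[trait] = hits[0]
            hits_by_pc.setdefault(hits[0], []).append(trait)
        else:
            multi.append((trait, hits))
    for trait, hits in multi:
        i = model.traits.index(trait)
        if corr is not None:
            def mean_abs_r(pc):
                others = [t for t in hits_by_pc.get(pc, []) if t != trait]
                if not others:
                    return 0.0
                return float(np.mean([abs(corr.loc[trait, o]) for o in others]))
            best = min(hits, key=mean_abs_r)
        else:
            warnings.warn(f"trait {trait} loads on several components and no "
                          "correlation matrix given; assigning by |loading|")
            best = max(hits, key=lambda j: abs(model.loadings[i, j]))
        assignment[trait] = best
        hits_by_pc.setdefault(best, []).append(trait)

    groups = []
    gi = 1
    for pc in sorted({v for v in assignment.values() if v != RESIDUAL}):
        members = [t for t in model.traits if assignment[t] == pc]
        groups.append(TraitGroup(gi, members, pc, {t: float(norms[t]) for t in members}))
        gi += 1
    residual = [t for t in model.traits if assignment[t] == RESIDUAL]
    if residual:
        groups.append(TraitGroup(gi, residual, RESIDUAL,
                                 {t: float(norms[t]) for t in residual}))
    return groups


def select_mds(groups: list[TraitGroup], corr: pd.DataFrame,
               cv: pd.Series | None = None, norm_window: float = 0.10,
               corr_threshold: float = 0.5) -> MDSSelection:
    """Apply the Norm-window and correlation retention rules per group.

    ``corr`` is the Pearson correlation matrix of trait CWMs (DataFrame
    indexed by trait); ``cv`` optional per-trait coefficients of variation
    used to break Norm ties.
    """
    retained, trace = [], []
    for g in groups:
        if not g.traits:
            raise ValueError(f"group {g.index} is empty")
        nmax = max(g.norms.values())
        candidates = [t for t in g.traits if g.norms[t] >= (1 - norm_window) * nmax]
        candidates.sort(key=lambda t: -g.norms[t])
        entry = {"group": g.index, "pc": g.pc, "candidates": list(candidates),
                 "decisions": []}
        if len(candidates) == 1:
            keep = candidates
            entry["decisions"].append(f"single candidate {candidates[0]}")
        else:
            top = candidates[0]
            keep = [top]
            for other in candidates[1:]:
                r = float(corr.loc[top, other])
                if abs(r) >= corr_threshold:
                    winner = top
                    if g.norms[top] == g.norms[other] and cv is not None:
                        winner = top if cv[top] >= cv[other] else other
                    entry["decisions"].append(
                        f"|r({top},{other})|={abs(r):.2f}>= {corr_threshold}: keep {winner}")
                    if winner not in keep:
                        keep = [winner]
                else:
                    keep.append(other)
                    entry["decisions"].append(
                        f"|r({top},{other})|={abs(r):.2f}< {corr_threshold}: keep both")
        entry["retained"] = list(keep)
        retained.extend(keep)
        trace.append(entry)
    return MDSSelection(retained, trace)


def cwm_correlation(trait_table: pd.DataFrame) -> pd.DataFrame:
    cols = trait_columns(trait_table)
    return trait_table[cols].corr()


def cwm_cv(trait_table: pd.DataFrame) -> pd.Series:
    cols = trait_columns(trait_table)
    X = trait_table[cols]
    return X.std(ddof=1) / X.mean()


def build_mds(trait_table: pd.DataFrame, rotate: bool = True,
              loading_threshold: float = 0.5, norm_window: float = 0.10,
              corr_threshold: float = 0.5, check_adequacy: bool = True):
    """Full pipeline: factor model -> groups -> selection.

    Returns ``(model, groups, selection)``.
    """
    model = fit_factor_model(trait_table, rotate=rotate, check_adequacy=check_adequacy)
    corr = cwm_correlation(trait_table)
    groups = group_traits(model, loading_threshold, corr=corr)
    selection = select_mds(groups, corr, cv=cwm_cv(trait_table),
                           norm_window=norm_window, corr_threshold=corr_threshold)
    return model, groups, selection
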