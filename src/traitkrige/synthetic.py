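"""Synthetic study-shaped data with known ground truth.

Emulates the sampling design of a riparian-to-desert transect survey: three
100 m x 100 m plots, each divided into a 10 x 10 grid of 10 m x 10 m
subplots, with

* per-subplot community-weighted means (CWMs) of 16 functional traits drawn
  from a latent factor model (so a minimum data set is recoverable by
  construction), rescaled to positive, trait-typical ranges; and
* per-subplot soil/plant C-N-P chemistry indicators built as a linear trend
  in designated traits plus a zero-mean Gaussian random field whose
  semivariogram parameters (nugget, structural variance, effective range)
  are known exactly.

Every quantity is deterministic given the config seed, which gives each
downstream stage (factor analysis, trait selection, trend models, variogram
fitting, kriging) a parameter-recovery test against planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geostats import model_curve

WOODY_TRAITS = ("LC", "LN", "LP", "SLA", "SLW", "LA", "LDMC", "LWC",
                "LFW", "LDW", "DBH", "H", "LT", "LL", "LW", "WLR")
HERB_TRAITS = tuple(t if t != "DBH" else "SBD" for t in WOODY_TRAITS)

CHEMISTRY_INDICATORS = {
    "C": ("plant_organic_C", "soil_organic_C"),
    "N": ("soil_nitrate_N", "soil_ammonium_N", "soil_total_N", "leaf_total_N"),
    "P": ("soil_available_P", "soil_total_P", "leaf_total_P"),
}

# Trait blocks sharing one latent factor, mirroring the correlation structure
# typical of desert plant communities: leaf-mass traits co-vary, SLA/SLW are
# near-reciprocal, LDMC/LWC complementary, leaf shape (LW, WLR) coupled, and
# stem size (DBH) and leaf thickness each load alone.  LC/LN/LP/H/LL carry
# only weak loadings so that they form a residual group.
DEFAULT_LOADING_SPEC = {
    "LA": (0, 0.93), "LFW": (0, 0.95), "LDW": (0, 0.95),
    "SLA": (1, -0.95), "SLW": (1, 0.94),
    "LDMC": (2, -0.96), "LWC": (2, 0.96),
    "LW": (3, 0.97), "WLR": (3, 0.96),
    "DBH": (4, 0.95),
    "LT": (5, 0.94),
    "LC": (0, 0.15), "LN": (1, 0.12), "LP": (2, 0.15),
    "H": (4, 0.34), "LL": (0, 0.2),
}

# Positive marginal scales (centre, spread) per trait in field-typical units.
DEFAULT_TRAIT_SCALES = {
    "LC": (430.0, 25.0), "LN": (18.0, 2.5), "LP": (1.4, 0.2),
    "SLA": (90.0, 15.0), "SLW": (0.012, 0.002), "LA": (6.0, 1.2),
    "LDMC": (0.35, 0.05), "LWC": (0.62, 0.05), "LFW": (0.5, 0.1),
    "LDW": (0.18, 0.035), "DBH": (8.0, 1.5), "SBD": (0.5, 0.1),
    "H": (2.5, 0.5), "LT": (0.5, 0.08), "LL": (3.5, 0.6),
    "LW": (0.8, 0.15), "WLR": (0.25, 0.04),
}

# Default linear trend: each chemistry indicator responds to two or three
# standardized trait CWMs (traits that a minimum data set should contain).
DEFAULT_TREND = {
    "plant_organic_C": {"LDW": 0.6, "SLA": -0.3},
    "soil_organic_C": {"LDW": 0.5, "LWC": 0.3},
    "soil_nitrate_N": {"LWC": 0.5, "SLA": 0.3},
    "soil_ammonium_N": {"LWC": 0.4, "LDW": 0.3},
    "soil_total_N": {"LWC": 0.4, "SLA": 0.3, "LDW": 0.2},
    "leaf_total_N": {"SLA": 0.6, "LWC": 0.2},
    "soil_available_P": {"LDW": 0.4, "LW": 0.3},
    "soil_total_P": {"LDW": 0.4, "LWC": 0.3},
    "leaf_total_P": {"SLA": 0.5, "LW": 0.2},
}

#: Chemistry residual variogram truth: strong spatial autocorrelation
#: (nugget 10% of sill) with an effective range of 30 m, exponential form.
DEFAULT_VARIOGRAM_TRUTH = {"form": "exponential", "c0": 0.1, "c": 0.9, "range": 30.0}


@dataclass
class SyntheticConfig:
    """Ground-truth parameters for one synthetic survey realisation."""

    n_plots: int = 3
    grid_side: int = 10
    subplot_size: float = 10.0
    n_latent_factors: int = 6
    loading_spec: dict = field(default_factory=lambda: dict(DEFAULT_LOADING_SPEC))
    trait_scales: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_SCALES))
    noise_sd: float = 0.1
    variogram_truth: dict = field(default_factory=lambda: dict(DEFAULT_VARIOGRAM_TRUTH))
    trend_coefficients: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TREND.items()})
    chemistry_residual_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_plots < 1 or self.grid_side < 2:
            raise ValueError("need at least one plot and a 2x2 grid")
        if self.noise_sd < 0 or self.chemistry_residual_sd < 0:
            raise ValueError("variance parameters must be non-negative")
        vt = self.variogram_truth
        if vt["c0"] < 0 or vt["c"] < 0 or vt["range"] <= 0:
            raise ValueError("variogram truth requires c0, c >= 0 and range > 0")
        for trait, (k, _) in self.loading_spec.items():
            if not 0 <= k < self.n_latent_factors:
                raise ValueError(f"trait {trait} assigned to factor {k} "
                                 f"outside 0..{self.n_latent_factors - 1}")


@dataclass
class SyntheticDataset:
    """Generated tables plus the config that produced them."""

    trait_tables: dict            # life form -> CWM DataFrame
    chemistry: pd.DataFrame
    truth: SyntheticConfig

    @property
    def coords(self) -> np.ndarray:
        return self.chemistry[["x", "y"]].to_numpy()


def subplot_centers(grid_side: int, subplot_size: float) -> np.ndarray:
    """Plot-relative subplot centre coordinates, row-major over the grid."""
    half = subplot_size / 2.0
    cols, rows = np.meshgrid(np.arange(grid_side), np.arange(grid_side))
    x = half + subplot_size * cols.ravel()
    y = half + subplot_size * rows.ravel()
    return np.column_stack([x, y])


def spatial_field(coords, form: str, c0: float, c: float, range_param: float,
                  rng) -> np.ndarray:
    """Draw a zero-mean Gaussian field whose semivariogram is the given model.

    Covariance is sill minus semivariance: ``cov(h) = c*rho(h)`` off the
    diagonal with full variance ``c0 + c`` at h = 0 (the nugget appears as
    spatially unstructured variance). Sampling is by Cholesky factorisation,
    exact at the desk scales used here (<= a few hundred points); a small
    jitter is added once if the matrix is numerically non-PD.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if len(np.unique(coords, axis=0)) != n:
        raise ValueError("coordinates must be distinct")
    if c0 < 0 or c < 0 or range_param <= 0:
        raise ValueError("require c0, c >= 0 and range > 0")

    from scipy.spatial.distance import squareform, pdist
    d = squareform(pdist(coords))
    sill = c0 + c
    cov = sill - model_curve(form, c0, c, range_param, d)
    np.fill_diagonal(cov, sill)
    if sill == 0:
        return np.zeros(n)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        try:
            chol = np.linalg.cholesky(cov + 1e-8 * sill * np.eye(n))
        except np.linalg.LinAlgError as exc:
            raise ValueError("implied covariance is not positive definite "
                             f"for form={form!r}: {exc}") from exc
    return chol @ rng.standard_normal(n)


def _trait_block(cfg: SyntheticConfig, traits, n, rng) -> pd.DataFrame:
    """Latent-factor CWMs for one life form on n subplots."""
    scores = rng.standard_normal((n, cfg.n_latent_factors))
    data = {}
    for trait in traits:
        spec_key = trait if trait in cfg.loading_spec else ("DBH" if trait == "SBD" else trait)
        k, u = cfg.loading_spec[spec_key]
        z = u * scores[:, k] + cfg.noise_sd * rng.standard_normal(n)
        centre, spread = cfg.trait_scales[trait]
        vals = centre + spread * z
        data[trait] = np.maximum(vals, 0.01 * centre)  # traits are positive quantities
    return pd.DataFrame(data)


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate one full synthetic survey (trait CWMs + chemistry)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    centers = subplot_centers(config.grid_side, config.subplot_size)
    n_sub = len(centers)

    index = pd.DataFrame({
        "plot": np.repeat([chr(ord("A") + i) for i in range(config.n_plots)], n_sub),
        "subplot": np.tile(np.arange(1, n_sub + 1), config.n_plots),
        "x": np.tile(centers[:, 0], config.n_plots),
        "y": np.tile(centers[:, 1], config.n_plots),
    })

    trait_tables = {}
    for life_form, traits in (("woody", WOODY_TRAITS), ("herbaceous", HERB_TRAITS)):
        block = _trait_block(config, traits, len(index), rng)
        trait_tables[life_form] = pd.concat([index.copy(), block], axis=1)

    # Chemistry: trend in standardized woody-trait CWMs + per-plot GRF residual.
    woody = trait_tables["woody"]
    z = (woody[list(WOODY_TRAITS)] - woody[list(WOODY_TRAITS)].mean()) / woody[list(WOODY_TRAITS)].std(ddof=0)
    vt = config.variogram_truth
    chem = index.copy()
    for indicator, coefs in config.trend_coefficients.items():
        trend = np.zeros(len(index))
        for trait, b in coefs.items():
            trend += b * z[trait].to_numpy()
        resid = np.concatenate([
            spatial_field(centers, vt["form"], vt["c0"], vt["c"], vt["range"], rng)
            for _ in range(config.n_plots)
        ])
        # shift to a positive concentration-like scale
        chem[indicator] = 5.0 + trend + config.chemistry_residual_sd * resid
    return SyntheticDataset(trait_tables, chem, config)


def generate_observations(dataset: SyntheticDataset, life_form: str = "woody",
                          species_per_subplot: int = 3, seed: int = 0) -> pd.DataFrame:
    """Disaggregate CWMs into pseudo-species observation records.

    Each subplot's CWM is split across ``species_per_subplot`` species with
    random abundances and trait offsets constrained so the abundance-weighted
    mean reproduces the planted CWM exactly; aggregating these records with
    the CWM operation is therefore a round trip.
    """
    rng = np.random.default_rng(seed)
    table = dataset.trait_tables[life_form]
    traits = [c for c in table.columns if c not in ("plot", "subplot", "x", "y")]
    rows = []
    for _, row in table.iterrows():
        abund = rng.integers(1, 10, size=species_per_subplot).astype(float)
        w = abund / abund.sum()
        offsets = {}
        for trait in traits:
            d = rng.normal(0, 0.05 * max(row[trait], 1e-9), size=species_per_subplot)
            d -= (w * d).sum()  # weighted-mean zero
            offsets[trait] = row[trait] + d
        for s in range(species_per_subplot):
            rec = {"plot": row["plot"], "subplot": int(row["subplot"]),
                   "x": row["x"], "y": row["y"],
                   "species": f"sp{s + 1}", "life_form": life_form,
                   "abundance": abund[s]}
            for trait in traits:
                rec[trait] = offsets[trait][s]
            rows.append(rec)
    return pd.DataFrame(rows)
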