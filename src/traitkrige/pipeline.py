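"""End-to-end orchestration: simulate/load -> CWM -> MDS -> FTEI -> EF ->
trend models -> variography and kriging -> manifest.

Each stage writes delimited-text outputs into the run directory and the
final manifest records config hash, seeds, row counts and SHA-256 of every
output so a rerun with the same config is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cwm as cwm_mod
from . import ecofunction, geostats, predictors, scoring
from . import mds as mds_mod
from . import synthetic

log = logging.getLogger("traitkrige")

STAGES = ("simulate", "aggregate", "mds", "score", "ef", "predict", "krige", "report")


@dataclass
class PipelineConfig:
    """Declarative run configuration with the analysis constants surfaced.

    Defaults follow the standard protocol: 0.5 loading cut, 10% Norm
    window, 0.5 correlation threshold, +-2.5 non-linear slopes, 25/75
    nugget-sill cuts, 70/30 split, 100-tree forest, 4x5 network.
    """

    seed: int = 0
    life_form: str = "woody"
    out_dir: str = "runs/default"
    observations_path: str | None = None    # None -> synthetic
    chemistry_path: str | None = None
    synthetic: dict = field(default_factory=dict)
    loading_threshold: float = 0.5
    norm_window: float = 0.10
    corr_threshold: float = 0.5
    rotate: bool = True
    scoring_directions: dict = field(default_factory=dict)
    model_kinds: tuple = ("pls", "rf", "bpnn")
    functions: tuple = ("C", "N", "P")
    train_fraction: float = 0.70
    n_lags: int = 10

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, manifest: dict, stage: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")
    manifest["outputs"].setdefault(stage, []).append(
        {"path": path.name, "rows": len(df), "sha256": _sha256(path)})


def factor_report(model: mds_mod.FactorModel, groups, selection) -> pd.DataFrame:
    """Loading-matrix report shaped like a published factor table."""
    pc_cols = {f"PC{j + 1}": model.loadings[:, j] for j in range(model.n_components)}
    group_of, norm_of = {}, {}
    for g in groups:
        for t in g.traits:
            group_of[t] = g.index
            norm_of[t] = g.norms[t]
    df = pd.DataFrame({"trait": model.traits, **pc_cols})
    df["group"] = [group_of[t] for t in model.traits]
    df["norm"] = [norm_of[t] for t in model.traits]
    df["mds"] = ["Enter" if t in selection.retained else "-" for t in model.traits]
    return df


def run_pipeline(config: PipelineConfig, stop_after: str | None = None) -> dict:
    """Execute the stages in order; returns the manifest dict (also on disk).

    ``stop_after`` ends the run early after the named stage (used by the
    per-stage CLI subcommands).
    """
    if stop_after is not None and stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config.hash(), "config": asdict(config),
                "seed": config.seed, "outputs": {}, "status": "incomplete"}
    stage = "start"

    def _finish(partial: bool) -> dict:
        manifest["status"] = f"complete through {stop_after}" if partial else "complete"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        return manifest

    try:
        # --- simulate (or load) -------------------------------------------
        stage = "simulate"
        if config.observations_path is None:
            scfg = synthetic.SyntheticConfig(**{**config.synthetic, "seed": config.seed})
            dataset = synthetic.generate(scfg)
            obs = synthetic.generate_observations(dataset, config.life_form,
                                                  seed=config.seed)
            chemistry = dataset.chemistry
            _write(obs, out / "observations.csv", manifest, stage)
            _write(chemistry, out / "chemistry.csv", manifest, stage)
        else:
            obs = pd.read_csv(config.observations_path)
            if config.chemistry_path is None:
                raise FileNotFoundError(
                    "chemistry table required when loading observations from file "
                    "(set chemistry_path)")
            chemistry = pd.read_csv(config.chemistry_path)
            _write(obs, out / "observations.csv", manifest, stage)
            _write(chemistry, out / "chemistry.csv", manifest, stage)
        log.info("simulate: %d observation rows, %d chemistry rows",
                 len(obs), len(chemistry))
        if stop_after == "simulate":
            return _finish(True)

        # --- aggregate ----------------------------------------------------
        stage = "aggregate"
        table = cwm_mod.compute_cwm(obs)
        _write(table, out / "cwm.csv", manifest, stage)
        log.info("aggregate: %d subplots x %d traits", len(table),
                 len(mds_mod.trait_columns(table)))
        if stop_after == "aggregate":
            return _finish(True)

        # --- mds ----------------------------------------------------------
        stage = "mds"
        model, groups, selection = mds_mod.build_mds(
            table, rotate=config.rotate, loading_threshold=config.loading_threshold,
            norm_window=config.norm_window, corr_threshold=config.corr_threshold)
        _write(factor_report(model, groups, selection), out / "factor_table.csv",
               manifest, stage)
        (out / "mds_trace.json").write_text(json.dumps(
            {"retained": selection.retained, "trace": selection.trace}, indent=2))
        manifest["outputs"][stage].append(
            {"path": "mds_trace.json", "rows": len(selection.trace),
             "sha256": _sha256(out / "mds_trace.json")})
        log.info("mds: retained %s", selection.retained)
        if stop_after == "mds":
            return _finish(True)

        # --- score --------------------------------------------------------
        stage = "score"
        spec = scoring.ScoringSpec(directions=dict(config.scoring_directions))
        cv = scoring.crossval_mds_vs_tds(table, model, groups, selection, spec)
        _write(cv.ftei_table.assign(plot=table["plot"].to_numpy(),
                                    subplot=table["subplot"].to_numpy()),
               out / "ftei.csv", manifest, stage)
        _write(pd.DataFrame({"method": list(cv.r2), "r2": list(cv.r2.values()),
                             "slope": [cv.slopes[k] for k in cv.r2],
                             "p": [cv.pvalues[k] for k in cv.r2]}),
               out / "crossval.csv", manifest, stage)
        if stop_after == "score":
            return _finish(True)

        # --- ef -----------------------------------------------------------
        stage = "ef"
        ef = ecofunction.compute_ef(chemistry)
        _write(ef, out / "ef.csv", manifest, stage)
        if stop_after == "ef":
            return _finish(True)

        # --- predict ------------------------------------------------------
        stage = "predict"
        merged = table.merge(ef[["plot", "subplot"] + list(config.functions)],
                             on=["plot", "subplot"], how="inner")
        split_spec = predictors.SplitSpec(config.train_fraction, config.seed)
        metric_rows, results = [], {}
        grid_pred = merged[["plot", "subplot", "x", "y"]].copy()
        for fn in config.functions:
            for kind in config.model_kinds:
                res = predictors.fit_predict(kind, merged, selection.retained, fn,
                                             split_spec)
                results[(fn, kind)] = res
                metric_rows.append({"function": fn, "model": kind,
                                    "rmse": res.rmse, "mae": res.mae})
                grid_pred[f"{fn}_{kind}"] = res.grid_predictions
        _write(pd.DataFrame(metric_rows), out / "prediction_metrics.csv",
               manifest, stage)
        _write(grid_pred, out / "predictions.csv", manifest, stage)
        if stop_after == "predict":
            return _finish(True)

        # --- krige --------------------------------------------------------
        stage = "krige"
        vario_rows, surface = [], merged[["plot", "subplot", "x", "y"]].copy()
        for fn in config.functions:
            surface[f"{fn}_obs"] = merged[fn].to_numpy()
        for fn in config.functions:
            ok_col = np.full(len(merged), np.nan)
            for plot, grp in merged.groupby("plot", sort=True):
                pos = np.flatnonzero((merged["plot"] == plot).to_numpy())
                coords = grp[["x", "y"]].to_numpy()
                vals = grp[fn].to_numpy()
                emp = geostats.empirical_variogram(coords, vals, n_lags=config.n_lags)
                fit = geostats.fit_variogram(emp)
                vario_rows.append({"plot": plot, "function": fn, "model": "raw",
                                   "form": fit.form, "C0": fit.nugget,
                                   "sill": fit.sill, "nsr": fit.nsr,
                                   "class": fit.autocorr_class, "range": fit.range_,
                                   "r2": fit.r2, "rss": fit.rss})
                preds, _ = geostats.ordinary_kriging(coords, vals, fit, coords)
                ok_col[pos] = preds
            surface[f"{fn}_OK"] = ok_col
        for (fn, kind), res in results.items():
            rk_col = np.full(len(merged), np.nan)
            for plot, grp in merged.groupby("plot", sort=True):
                pos = np.flatnonzero((merged["plot"] == plot).to_numpy())
                tr_pos = np.intersect1d(res.train_index, pos)
                in_plot_tr = np.isin(res.train_index, pos)
                rk = geostats.regression_kriging(
                    res.grid_predictions[pos],
                    merged.iloc[tr_pos][["x", "y"]].to_numpy(),
                    res.train_residuals[in_plot_tr],
                    grp[["x", "y"]].to_numpy(), n_lags=config.n_lags)
                rk_col[pos] = rk.prediction
                if rk.residual_fit is not None:
                    f = rk.residual_fit
                    vario_rows.append({"plot": plot, "function": fn, "model": kind,
                                       "form": f.form, "C0": f.nugget, "sill": f.sill,
                                       "nsr": f.nsr, "class": f.autocorr_class,
                                       "range": f.range_, "r2": f.r2, "rss": f.rss})
            surface[f"{fn}_{kind}_RK"] = rk_col
        _write(pd.DataFrame(vario_rows), out / "variograms.csv", manifest, stage)
        _write(surface, out / "surfaces.csv", manifest, stage)
        if stop_after == "krige":
            return _finish(True)

        # --- report -------------------------------------------------------
        stage = "report"
        manifest["stages"] = list(STAGES)
        report = pd.DataFrame(
            [{"stage": s, "n_outputs": len(manifest["outputs"].get(s, []))}
             for s in STAGES if s != "report"])
        _write(report, out / "stage_report.csv", manifest, stage)
    except Exception as exc:
        manifest["status"] = f"failed at stage {stage}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return _finish(False)
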