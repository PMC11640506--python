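"""End-to-end orchestration: simulate -> prepare -> standardize -> assess
-> evaluate, with a JSON manifest tying every artifact to its hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .amsy import (
    AMSYPriors,
    ProcessErrorConfig,
    assess,
    mean_seasonal_index,
)
from .conventional import ConventionalConfig, fit_conventional, predict_annual_index
from .evaluate import cross_validate, mann_kendall
from .prep import nominal_cpue
from .seasonal import (
    ModelData,
    SeasonalModelConfig,
    compute_cog,
    compute_index,
    fit_seasonal_model,
)
from .simulate import SimConfig, simulate_fishery
from .spatial import build_knot_mesh, make_grid

log = logging.getLogger("seastock")

INDEX_NAMES = ("spring", "summer", "autumn", "mean", "conventional")
ALL_STAGES = ("simulate", "prepare", "index", "assess", "evaluate")


@dataclass
class AMSYConfig:
    r_range: tuple[float, float] = (0.6, 1.5)
    bk_prior: tuple[float, float] = (0.4, 0.6)
    log_corr: float = 0.0
    n_samples: int = 30_000
    n_trials: int = 10
    process_cv: float = 0.1
    observation_cv: float = 0.1


@dataclass
class RunConfig:
    """Full pipeline configuration; defaults are a desk-scale run."""

    sim: SimConfig = field(default_factory=SimConfig.desk)
    n_knots: int = 15
    model: SeasonalModelConfig = field(default_factory=SeasonalModelConfig)
    conventional: ConventionalConfig = field(default_factory=ConventionalConfig)
    amsy: AMSYConfig = field(default_factory=AMSYConfig)
    eval_scheme: str = "loo"
    eval_n_samples: int = 5000
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    allow_nonconverged: bool = False
    index_draws: int = 100

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "sim" in kwargs:
            kwargs["sim"] = SimConfig(**kwargs["sim"])
        if "model" in kwargs:
            kwargs["model"] = SeasonalModelConfig(**kwargs["model"])
        if "conventional" in kwargs:
            kwargs["conventional"] = ConventionalConfig(**kwargs["conventional"])
        if "amsy" in kwargs:
            kwargs["amsy"] = AMSYConfig(**kwargs["amsy"])
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Run:
    def __init__(self, config: RunConfig, outdir: Path):
        self.config = config
        self.outdir = outdir
        outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "seed": config.seed,
            "version": __version__,
            "numpy": np.__version__,
            "config": config.to_dict(),
            "stages": {},
        }

    def save_df(self, df: pd.DataFrame, name: str) -> Path:
        path = self.outdir / name
        df.to_csv(path, index=False, float_format="%.10g")
        return path

    def save_json(self, obj, name: str) -> Path:
        path = self.outdir / name
        path.write_text(json.dumps(obj, indent=2, default=float) + "\n")
        return path

    def record(self, stage: str, paths: list[Path], t0: float, status="done") -> None:
        self.manifest["stages"][stage] = {
            "status": status,
            "wall_time_s": round(time.perf_counter() - t0, 3),
            "artifacts": {p.name: _sha256(p) for p in paths},
        }


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run the configured stages; returns (and writes) the manifest.

    Artifacts per full run: records and gridded CPUE CSVs, five index CSVs
    (three seasons, their mean, and the conventional benchmark), five
    assessment outputs, COG and trend tables, and a cross-validation
    report.  A stage failure raises with the stage name; artifacts written
    up to that point remain on disk.
    """
    run = _Run(config, Path(outdir))
    cfg = config
    stages = set(cfg.stages)
    records = truth = None
    indices: dict[str, pd.DataFrame] = {}

    try:
        if "simulate" in stages:
            t0 = time.perf_counter()
            sim_cfg = dataclasses.replace(cfg.sim, seed=cfg.seed)
            records, truth = simulate_fishery(sim_cfg)
            paths = [
                run.save_df(records, "records.csv"),
                run.save_df(truth.index_frame(), "true_index.csv"),
                run.save_df(truth.cog_frame(), "true_cog.csv"),
            ]
            run.record("simulate", paths, t0)
            log.info("simulate: %d records", len(records))

        if "prepare" in stages:
            t0 = time.perf_counter()
            if records is None:
                records = pd.read_csv(run.outdir / "records.csv")
            gridded = nominal_cpue(records, cfg.sim.cell_deg)
            run.record("prepare", [run.save_df(gridded, "gridded_cpue.csv")], t0)

        if "index" in stages:
            t0 = time.perf_counter()
            if records is None:
                records = pd.read_csv(run.outdir / "records.csv")
            paths = []

            conv_fit = fit_conventional(records, cfg.conventional)
            conv_index = predict_annual_index(conv_fit, seed=cfg.seed)
            indices["conventional"] = conv_index
            paths.append(run.save_df(conv_index, "index_conventional.csv"))

            extrap = make_grid(
                cfg.sim.lon_min, cfg.sim.lon_max, cfg.sim.lat_min,
                cfg.sim.lat_max, cfg.sim.cell_deg,
            )
            mesh = build_knot_mesh(
                records["lon"].to_numpy(), records["lat"].to_numpy(),
                extrap, cfg.n_knots, seed=cfg.seed,
            )
            data = ModelData.from_records(records, mesh)
            fit = fit_seasonal_model(data, mesh, cfg.model)
            if not fit.diagnostics.converged and not cfg.allow_nonconverged:
                raise RuntimeError(
                    "stage 'index': seasonal model did not converge "
                    f"(max gradient {fit.diagnostics.max_gradient:.2e}); "
                    "rerun with allow_nonconverged to keep going"
                )
            paths.append(
                run.save_json(fit.diagnostics.to_dict(), "seasonal_diagnostics.json")
            )
            idx = compute_index(fit, n_draws=cfg.index_draws, seed=cfg.seed)
            for season in ("spring", "summer", "autumn"):
                sdf = (
                    idx[idx["season"] == season]
                    .drop(columns="season")
                    .reset_index(drop=True)
                )
                indices[season] = sdf
                paths.append(run.save_df(sdf, f"index_{season}.csv"))
            indices["mean"] = mean_seasonal_index(
                indices["spring"], indices["summer"], indices["autumn"]
            )
            paths.append(run.save_df(indices["mean"], "index_mean.csv"))

            cog = compute_cog(fit)
            paths.append(run.save_df(cog, "cog.csv"))
            trend_rows = []
            for col, series_name in (
                ("easting_km", "cog_easting"), ("northing_km", "cog_northing"),
            ):
                res = mann_kendall(cog[col].to_numpy())
                trend_rows.append(
                    {"series_name": series_name, "tau": res.tau,
                     "p": res.p_value, "n": res.n}
                )
            paths.append(run.save_df(pd.DataFrame(trend_rows), "cog_trends.csv"))
            run.record("index", paths, t0)

        if "assess" in stages:
            t0 = time.perf_counter()
            paths = []
            ec = ProcessErrorConfig(
                n_trials=cfg.amsy.n_trials,
                process_cv=cfg.amsy.process_cv,
                observation_cv=cfg.amsy.observation_cv,
            )
            for name in INDEX_NAMES:
                index_df = indices.get(name)
                if index_df is None:
                    index_df = pd.read_csv(run.outdir / f"index_{name}.csv")
                priors = AMSYPriors(
                    index=index_df[["year", "index"]],
                    r_range=cfg.amsy.r_range,
                    bk_prior=cfg.amsy.bk_prior,
                    log_corr=cfg.amsy.log_corr,
                )
                result, ensemble = assess(
                    index_df, priors, n_samples=cfg.amsy.n_samples,
                    error_config=ec, seed=cfg.seed,
                )
                paths.append(
                    run.save_json(result.to_dict(), f"assessment_{name}.json")
                )
                paths.append(run.save_df(result.table, f"assessment_{name}.csv"))
                paths.append(
                    run.save_df(ensemble.to_frame(), f"ensemble_{name}.csv")
                )
            run.record("assess", paths, t0)
        elif stages:
            run.manifest["stages"]["assess"] = {"status": "skipped"}

        if "evaluate" in stages:
            t0 = time.perf_counter()
            rows, summaries = [], []
            for name in INDEX_NAMES:
                index_df = indices.get(name)
                if index_df is None:
                    index_df = pd.read_csv(run.outdir / f"index_{name}.csv")
                report = cross_validate(
                    index_df[["year", "index"]],
                    scheme=cfg.eval_scheme,
                    n_samples=cfg.eval_n_samples,
                    seed=cfg.seed,
                )
                tab = report.table.copy()
                tab.insert(0, "index_type", name)
                rows.append(tab)
                summaries.append({"index_type": name, **report.summary()})
            paths = [
                run.save_df(pd.concat(rows, ignore_index=True), "crossval.csv"),
                run.save_df(pd.DataFrame(summaries), "crossval_summary.csv"),
            ]
            run.record("evaluate", paths, t0)
    except Exception as err:
        run.manifest["error"] = str(err)
        run.save_json(run.manifest, "manifest.json")
        raise

    run.save_json(run.manifest, "manifest.json")
    return run.manifest


def report(manifest_path: str | Path) -> str:
    """Human-readable summary assembled purely from stored artifacts."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    if not manifest.get("stages"):
        raise ValueError("empty manifest: no stages were run")
    outdir = manifest_path.parent
    lines = [f"seastock run (seed {manifest.get('seed')})", ""]

    missing = []
    assess_stage = manifest["stages"].get("assess", {})
    if assess_stage.get("status") == "done":
        lines.append("Stock status (final year, median across viable pairs):")
        lines.append(
            f"  {'index':<14}{'kobe':<9}{'B/Bmsy':>8}{'F/Fmsy':>8}"
            f"{'P(green)':>10}{'P(red)':>8}"
        )
        for name in INDEX_NAMES:
            path = outdir / f"assessment_{name}.json"
            if not path.exists():
                missing.append(path.name)
                continue
            res = json.loads(path.read_text())
            final = res["years"][-1]
            f_med = next(
                (y["f_fmsy_med"] for y in reversed(res["years"])
                 if y["f_fmsy_med"] is not None and not pd.isna(y["f_fmsy_med"])),
                float("nan"),
            )
            lines.append(
                f"  {name:<14}{final['kobe']:<9}{final['b_bmsy_med']:>8.2f}"
                f"{f_med:>8.2f}{res['status_probs']['green']:>10.3f}"
                f"{res['status_probs']['red']:>8.3f}"
            )
        lines.append("")

    trends = outdir / "cog_trends.csv"
    if trends.exists():
        lines.append("Centre-of-gravity trends (Mann-Kendall):")
        for _, row in pd.read_csv(trends).iterrows():
            lines.append(
                f"  {row['series_name']:<14} tau={row['tau']:+.3f}  "
                f"p={row['p']:.4f}  n={int(row['n'])}"
            )
        lines.append("")

    cv = outdir / "crossval_summary.csv"
    if cv.exists():
        lines.append("Cross-validation (ARE by index type):")
        for _, row in pd.read_csv(cv).iterrows():
            lines.append(
                f"  {row['index_type']:<14} ARE={row['are']:.3f}  "
                f"RE 95% band [{row['re_lo95']:+.3f}, {row['re_hi95']:+.3f}]"
            )
    if missing:
        lines.append(f"missing artifacts: {', '.join(missing)}")
    return "\n".join(lines)
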