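"""End-to-end pipeline: fixes -> steps -> strata -> covariates -> fits -> RSS.

The pipeline is a pure function of (inputs, config, seed): rerunning with the
same configuration reproduces byte-identical outputs.  Outputs land in a run
directory under fixed names (steps.csv, strata.csv, kernel.json,
coefficients_{period}_{tier}.csv, aicc_{period}.csv, curves_{period}.csv,
manifest.json) together with a manifest recording the config, seed and row
counts at every stage.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import kernel as kern
from . import landscape as land
from . import model as mod
from . import rss as rss_mod
from . import social, tracks
from .errors import ConfigurationError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; defaults mirror the analysis protocol
    (4-h steps, 9 available steps, 200-m chain rule, dry = Jan-Jun)."""

    fixes: str = "fixes.csv"
    layers: str = "layers"
    outdir: str = "run"
    baseline_start: str = ""
    baseline_end: str = ""
    interval_hours: float = 4.0
    tolerance_minutes: float = 30.0
    n_available: int = 9
    group_threshold: float = 200.0
    dry_months: list[int] = field(default_factory=lambda: [1, 2, 3, 4, 5, 6])
    wet_months: list[int] = field(default_factory=lambda: [7, 8, 9, 10, 11, 12])
    tiers: list[str] = field(default_factory=lambda: list(mod.TIERS))
    andvi_mode: str = "slot"
    extraction: str = "nearest"
    vif_threshold: float = 4.0
    seed: int = 0
    keep_inestimable: bool = False

    def validate(self) -> None:
        overlap = set(self.dry_months) & set(self.wet_months)
        if overlap:
            raise ConfigurationError(f"dry and wet months overlap: {sorted(overlap)}")
        if set(self.dry_months) | set(self.wet_months) != set(range(1, 13)):
            raise ConfigurationError("dry + wet months must partition 1..12")
        if self.interval_hours <= 0:
            raise ConfigurationError("interval_hours must be positive")
        if self.n_available < 1:
            raise ConfigurationError("n_available must be >= 1")
        unknown = set(self.tiers) - set(mod.TIERS)
        if unknown:
            raise ConfigurationError(f"unknown tiers: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(doc) - known
        if bad:
            raise ConfigurationError(f"unknown config key(s): {sorted(bad)}")
        return cls(**doc)


def load_stack(layers_dir, baseline_start, baseline_end,
               andvi_mode: str = "slot") -> land.LandscapeStack:
    """Read raw layers (ndvi_*.asc, temperature_*.asc, elevation.asc) and
    derive the analysis covariates."""
    layers_dir = Path(layers_dir)
    ndvi = land.GridSeries.read(layers_dir, "ndvi")
    temperature = land.GridSeries.read(layers_dir, "temperature")
    elevation = land.read_ascii_grid(layers_dir / "elevation.asc")
    return land.LandscapeStack(
        andvi=land.compute_andvi(ndvi, baseline_start, baseline_end, mode=andvi_mode),
        dndvi=land.compute_dndvi(ndvi),
        elevation=elevation,
        tri=land.compute_tri(elevation),
        temperature=temperature,
        ndvi=ndvi,
    )


def prepare_strata(fixes: pd.DataFrame, stack: land.LandscapeStack,
                   config: PipelineConfig):
    """Stages up to the fitting-ready strata table.

    Returns ``(strata_with_covariates_and_moderators, steps, kernel_fits)``.
    """
    interval = pd.Timedelta(hours=config.interval_hours)
    tolerance = pd.Timedelta(minutes=config.tolerance_minutes)
    bursts = tracks.resample_to_interval(fixes, interval=interval, tolerance=tolerance)
    steps = tracks.build_steps(bursts)
    if sorted(config.dry_months) != [1, 2, 3, 4, 5, 6]:
        months = pd.DatetimeIndex(steps["t_start"]).month
        steps["period"] = np.where(np.isin(months, config.dry_months), "dry", "wet")

    fits = kern.fit_kernel(steps, per_period=True)
    parts = []
    offset = 0
    for period in sorted(fits):
        g, v = fits[period]
        sub = kern.build_strata(steps[steps["period"] == period], g, v,
                                n_available=config.n_available,
                                rng=np.random.default_rng([config.seed, 7, offset]))
        sub["stratum_id"] = sub["stratum_id"] + offset * 10 ** 7
        parts.append(sub)
        offset += 1
    strata = pd.concat(parts, ignore_index=True)

    strata = land.extract_covariates(strata, stack, method=config.extraction)
    groups = social.groups_by_bin(bursts, threshold=config.group_threshold,
                                  bin_width=interval)
    release = fixes.drop_duplicates("animal_id").set_index("animal_id")["release_date"]
    strata = social.attach_moderators(strata, groups, release, bin_width=interval)
    return strata, steps, fits


def fit_result_to_json(fit: mod.FitResult, path) -> None:
    doc = {
        "columns": list(fit.beta.index),
        "beta": fit.beta.to_numpy().tolist(),
        "cov_naive": fit.cov_naive.tolist(),
        "cov_robust": fit.cov_robust.tolist(),
        "loglik": fit.loglik, "loglik_null": fit.loglik_null,
        "k": fit.k, "n_strata": fit.n_strata, "n_clusters": fit.n_clusters,
        "converged": fit.converged, "n_iter": fit.n_iter,
        "period": fit.period, "tier": fit.tier,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def fit_result_from_json(path) -> mod.FitResult:
    with open(path) as fh:
        doc = json.load(fh)
    return mod.FitResult(
        beta=pd.Series(doc["beta"], index=doc["columns"]),
        cov_naive=np.asarray(doc["cov_naive"]),
        cov_robust=np.asarray(doc["cov_robust"]),
        loglik=doc["loglik"], loglik_null=doc["loglik_null"],
        k=doc["k"], n_strata=doc["n_strata"], n_clusters=doc["n_clusters"],
        converged=doc["converged"], n_iter=doc["n_iter"],
        period=doc["period"], tier=doc["tier"],
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the result bundle to ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    fixes = tracks.read_fixes(config.fixes)
    stack = load_stack(config.layers, config.baseline_start, config.baseline_end,
                       andvi_mode=config.andvi_mode)
    strata, steps, kernel_fits = prepare_strata(fixes, stack, config)

    tracks.write_steps(steps, outdir / "steps.csv")
    strata.to_csv(outdir / "strata.csv", index=False)
    kern.kernel_to_json(kernel_fits, outdir / "kernel.json")

    counts = {"fixes": len(fixes), "steps": len(steps), "strata_rows": len(strata),
              "strata": int(strata["stratum_id"].nunique())}
    results = {"counts": counts, "fits": {}, "selection": {}, "best": {}}

    for period in sorted(strata["period"].unique()):
        fits = {}
        for tier in config.tiers:
            design = mod.build_design(strata, period, tier,
                                      keep_inestimable=config.keep_inestimable)
            if tier == "M4":
                mod.vif(design.X, design.columns, threshold=config.vif_threshold)
            fit = mod.fit_clogit(design)
            fits[tier] = fit
            rss_mod.rss_table(fit).to_csv(
                outdir / f"coefficients_{period}_{tier}.csv", index=False)
            fit_result_to_json(fit, outdir / f"fit_{period}_{tier}.json")
        comparison = mod.select_model(fits)
        comparison.to_csv(outdir / f"aicc_{period}.csv", index=False)
        best_tier = comparison["tier"].iloc[0]
        results["fits"][period] = fits
        results["selection"][period] = comparison
        results["best"][period] = best_tier

        curves = []
        best = fits[best_tier]
        grid = np.linspace(-2, 2, 41)
        for cov in mod.ENV_MAINS + mod.MOVEMENT_TERMS:
            if cov not in best.beta.index:
                continue
            curves.append(rss_mod.log_rss_curve(best, cov, grid))
            for moderator in mod.MODERATORS[best_tier]:
                if f"{cov}:{moderator}" in best.beta.index:
                    for level in (-1.0, 0.0, 1.0):
                        c = rss_mod.log_rss_curve(best, cov, grid,
                                                  moderator=moderator,
                                                  moderator_level=level)
                        c["moderator"] = moderator
                        curves.append(c)
        pd.concat(curves, ignore_index=True).to_csv(
            outdir / f"curves_{period}.csv", index=False)

    cfg_doc = asdict(config)
    manifest = {
        "config": cfg_doc,
        "config_hash": hashlib.md5(
            json.dumps(cfg_doc, sort_keys=True).encode()).hexdigest(),
        "seed": config.seed,
        "counts": counts,
        "best_tier": results["best"],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    results["manifest"] = manifest
    return results
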