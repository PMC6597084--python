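"""End-to-end orchestration: simulate -> preprocess -> tree -> estimate ->
structure analytics -> linear baselines, with a consolidated JSON report."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import baselines, estimator, preprocess, synthetic, tree_analysis
from .ndtree import DEFAULT_MAX_DEPTH, build_tree

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated options for a full pipeline run."""

    input_dir: str | None = None  # directory with gps/accel/battery/wifi CSVs
    simulate: bool = True
    n_participants: int = 20
    n_days: int = 14
    seed: int = 0
    duty_period_s: int = 300
    geo_bounds: tuple[float, float, float, float] = preprocess.DEFAULT_GEO_BOUNDS
    max_depth: int = DEFAULT_MAX_DEPTH
    saturation_fraction: float = estimator.DEFAULT_SATURATION_FRACTION
    fit_level: int | None = None
    trend_max_level: int = tree_analysis.DEFAULT_NOISE_FLOOR_LEVEL

    def validate(self) -> None:
        if self.n_participants < 1 or self.n_days < 1:
            raise ValueError("n_participants and n_days must be positive")
        if self.duty_period_s <= 0:
            raise ValueError("duty_period_s must be positive")
        if self.max_depth < 1:
            raise ValueError("max_depth must be positive")
        if not (0 < self.saturation_fraction <= 1):
            raise ValueError("saturation_fraction must be in (0, 1]")
        lon_min, lon_max, lat_min, lat_max = self.geo_bounds
        if not all(np.isfinite(v) for v in self.geo_bounds):
            raise ValueError("geo bounds must be finite")
        if lon_min >= lon_max or lat_min >= lat_max:
            raise ValueError(f"invalid geo bounds: {self.geo_bounds}")
        if not self.simulate and self.input_dir is None:
            raise ValueError("either simulate or provide input_dir")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "geo_bounds" in data:
            data["geo_bounds"] = tuple(data["geo_bounds"])
        cfg = cls(**data)
        cfg.validate()
        return cfg


def load_raw_csv(indir, duty_period_s: int = 300) -> synthetic.RawSensorLog:
    """Read the four raw tables (gps, accel, battery, wifi) from a directory."""
    indir = Path(indir)
    required = {
        "gps": ["participant", "timestamp", "lat", "lon"],
        "accel": ["participant", "timestamp", "x", "y", "z"],
        "battery": ["participant", "timestamp", "status"],
        "wifi": ["participant", "timestamp", "mac"],
    }
    tables = {}
    for name, cols in required.items():
        path = indir / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing raw table: {path}")
        df = pd.read_csv(path)
        missing = set(cols) - set(df.columns)
        if missing:
            raise ValueError(f"{name}.csv lacks columns {sorted(missing)}")
        tables[name] = df
    return synthetic.RawSensorLog(
        gps=tables["gps"],
        accel=tables["accel"],
        battery=tables["battery"],
        wifi=tables["wifi"],
        duty_period_s=duty_period_s,
    )


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute every stage in order and write artifacts to ``outdir``.

    Returns the consolidated report (also written as ``report.json``).
    """
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        raw = synthetic.gen_shed_like(
            config.n_participants,
            config.n_days,
            config.seed,
            synthetic.ShedConfig(
                bbox=config.geo_bounds, duty_period_s=config.duty_period_s
            ),
        )
    else:
        raw = load_raw_csv(config.input_dir, config.duty_period_s)

    ds = preprocess.preprocess(raw, config.duty_period_s, config.geo_bounds)
    if ds.n == 0:
        raise RuntimeError("preprocessing produced no records")
    ds.records.to_csv(out / "normalized.csv", index=False)
    logger.info("preprocessing: %s", ds.provenance)

    pts = ds.to_points()
    tree = build_tree(pts, max_depth=config.max_depth)
    stats = tree.level_stats()
    stats.to_frame().to_csv(out / "tree_stats.csv", index=False)

    summaries = estimator.level_summaries(stats)
    pd.DataFrame(
        [
            {
                "level": s.level,
                "epsilon": s.epsilon,
                "n_boxes": s.n_boxes,
                "log_inv_eps": s.log_inv_eps,
                "log_n": s.log_n,
            }
            for s in summaries
        ]
    ).to_csv(out / "loglog.csv", index=False)
    break_level = estimator.find_break_level(stats)
    fit_level = config.fit_level or estimator.find_fit_level(
        summaries, break_level, config.saturation_fraction
    )
    est = estimator.estimate_id(summaries, fit_level, break_level=break_level)
    cam = estimator.camastra_check(ds.d, ds.n)

    profile = tree_analysis.occupancy_profile(stats)
    profile.to_csv(out / "occupancy_profile.csv", index=False)
    trend = tree_analysis.fit_sparsity_trend(profile, config.trend_max_level)
    treemap, plurality = tree_analysis.export_level_treemap(
        stats, 3, min(14, stats.depth)
    )
    treemap.to_csv(out / "treemap.csv", index=False)

    pca = baselines.pca_baseline(ds)
    pca.loadings_frame().to_csv(out / "pca_loadings.csv")
    corr = baselines.correlation_matrix(ds)
    corr.to_csv(out / "correlation.csv")
    off = corr.where(~np.eye(len(corr), dtype=bool)).abs()
    strongest = off.stack().idxmax()

    report = {
        "config": {**asdict(config), "geo_bounds": list(config.geo_bounds)},
        "provenance": ds.provenance,
        "n_records": ds.n,
        "camastra": asdict(cam),
        "break_level": break_level,
        "fit_level": fit_level,
        "slopes": [est.slope_a, est.slope_b],
        "fit_r2s": list(est.fit_r2s),
        "id": est.id_value,
        "tree_depth": stats.depth,
        "plurality_leaf_level": plurality,
        "sparsity_trend": {"c": trend.c, "r2": trend.r2},
        "k90": pca.k90,
        "cumulative_inertia": pca.cumulative_inertia.tolist(),
        "strongest_correlation": {
            "pair": list(strongest),
            "value": float(corr.loc[strongest]),
        },
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
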