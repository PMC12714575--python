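"""End-to-end pipeline: rasters → ecozones → site assignment → baselines → thresholds.

The pipeline is a plain function over a :class:`PipelineConfig`; every
tunable is echoed into a ``manifest.json`` so a run can be reproduced
bit-for-bit from its manifest.  All outputs are plain text (CSV / ASCII
grid / JSON).
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

import isozone
from isozone.diet_thresholds import (
    ThresholdParams,
    ecozone_thresholds,
    site_thresholds,
    threshold_map,
)
from isozone.ecozones import (
    assign_sites,
    fit_ecozones,
    label_clusters,
    rasterize_labels,
    summarize_clusters,
)
from isozone.env_stack import (
    EnvLayer,
    EnvStack,
    read_ascii_grid,
    sample_centroids,
    write_ascii_grid,
)
from isozone.grain_data import group_summaries, read_grain_table, write_grain_table
from isozone.synthetic import SynthConfig, generate_env_rasters, generate_grain_dataset
from isozone.trend_stats import fit_linear_trend, one_way_anova, pearson_with_ci

__all__ = ["PipelineConfig", "run_pipeline", "report_summaries"]

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run.

    Either point the config at a grain CSV plus three co-registered raw
    raster layers (``grain_csv``, ``dem_path``, ``tmp_path``, ``cmi_path``,
    ESRI ASCII grids in a metre CRS), or set ``synth`` to generate both
    inputs on the fly.
    """

    out_dir: str = "results/pipeline"
    grain_csv: str | None = None
    dem_path: str | None = None
    tmp_path: str | None = None
    cmi_path: str | None = None
    synth: SynthConfig | None = None
    k: int = 20
    seed: int = 42
    n_init: int = 25
    spacing: float | None = None  # centroid lattice spacing; default = cell size
    n_min: int = 10
    threshold_params: ThresholdParams = field(default_factory=ThresholdParams)
    headline_fraction: float = 0.10
    strict: bool = False


def _load_inputs(cfg: PipelineConfig) -> tuple[pd.DataFrame, EnvLayer, EnvLayer, EnvLayer]:
    if cfg.synth is not None:
        table, _truth = generate_grain_dataset(cfg.synth)
        dem, tmp, cmi, _zones = generate_env_rasters(cfg.synth)
        return table, dem, tmp, cmi
    missing = [
        name
        for name, p in (
            ("grain_csv", cfg.grain_csv),
            ("dem_path", cfg.dem_path),
            ("tmp_path", cfg.tmp_path),
            ("cmi_path", cfg.cmi_path),
        )
        if p is None or not Path(p).exists()
    ]
    if missing:
        raise FileNotFoundError(f"[inputs] missing pipeline inputs: {missing}")
    table = read_grain_table(cfg.grain_csv, strict=cfg.strict)
    dem = read_ascii_grid(cfg.dem_path, kind="elevation")
    tmp = read_ascii_grid(cfg.tmp_path, kind="temperature")
    cmi = read_ascii_grid(cfg.cmi_path, kind="cmi")
    return table, dem, tmp, cmi


def _stage(name: str):
    """Decorator-free stage guard: re-raise with a stage-tagged message."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, FileNotFoundError):
                raise RuntimeError(f"[{name}] stage failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis and write all artifacts under ``cfg.out_dir``.

    Returns a dict of in-memory results (tables, model, raster) keyed by
    artifact name.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    table, dem, tmp, cmi = _load_inputs(cfg)

    with _stage("env_stack"):
        stack = EnvStack.from_raw_layers(dem, tmp, cmi)
        spacing = cfg.spacing or stack.grid.dx
        sample = sample_centroids(stack, spacing)

    with _stage("ecozones"):
        model = fit_ecozones(sample, k=cfg.k, seed=cfg.seed, n_init=cfg.n_init)
        ez = rasterize_labels(model, stack)
        clusters = label_clusters(summarize_clusters(model, sample))
        ez.lookup = clusters

    with _stage("assign"):
        table = assign_sites(table, ez)

    with _stage("baseline"):
        summaries = {
            by: group_summaries(table, by=by, n_min=cfg.n_min)
            for by in ("latbin", "region", "country", "ecozone")
        }

    with _stage("thresholds"):
        site_thr = site_thresholds(table, cfg.threshold_params, n_min=cfg.n_min)
        ez_thr = ecozone_thresholds(table, cfg.threshold_params, n_min=cfg.n_min)
        med_grid, sd_grid = threshold_map(ez, ez_thr, f=cfg.headline_fraction)

    with _stage("trends"):
        c3 = table[table["pathway"] == "C3"]
        trends = pd.DataFrame(
            [
                {"x": "lat", **asdict(pearson_with_ci(c3["lat"], c3["d13c"]))},
                {"x": "date_mean", **asdict(fit_linear_trend(c3["date_mean"], c3["d13c"]))},
            ]
        )
        region_groups = [
            g["d13c"].to_numpy()
            for _, g in group_summaries_input(c3).groupby("region")
            if len(g) >= 2
        ]
        anova = one_way_anova(region_groups) if len(region_groups) >= 2 else None

    with _stage("write"):
        write_grain_table(table, out / "grains_with_ecozones.csv")
        clusters.to_csv(out / "cluster_summary.csv", index=False, float_format=_FLOAT_FMT)
        for by, df in summaries.items():
            df.to_csv(out / f"summary_{by}.csv", index=False, float_format=_FLOAT_FMT)
        site_thr.to_csv(out / "site_thresholds.csv", index=False, float_format=_FLOAT_FMT)
        ez_thr.to_csv(out / "ecozone_thresholds.csv", index=False, float_format=_FLOAT_FMT)
        trends.to_csv(out / "trends.csv", index=False, float_format=_FLOAT_FMT)
        g = stack.grid
        for name, gridvals in (("threshold_map_median", med_grid), ("threshold_map_sd", sd_grid)):
            lyr = EnvLayer(kind="cmi", data=gridvals, xmin=g.xmin, ymax=g.ymax,
                           dx=g.dx, dy=g.dy, crs=g.crs)
            write_ascii_grid(lyr, out / f"{name}.asc")
        np.savetxt(out / "ecozone_raster.txt", ez.grid, fmt="%d")

        manifest = {
            "package_version": isozone.__version__,
            "python": platform.python_version(),
            "seed": cfg.seed,
            "k": cfg.k,
            "n_init": cfg.n_init,
            "spacing": spacing,
            "n_min": cfg.n_min,
            "headline_fraction": cfg.headline_fraction,
            "threshold_params": asdict(cfg.threshold_params),
            "synthetic": cfg.synth is not None,
            "synth_config": asdict(cfg.synth) if cfg.synth is not None else None,
            "inputs": {
                "grain_csv": cfg.grain_csv,
                "dem_path": cfg.dem_path,
                "tmp_path": cfg.tmp_path,
                "cmi_path": cfg.cmi_path,
            },
            "n_records": int(len(table)),
            "n_sites": int(table["site_id"].nunique()),
            "n_c3": int((table["pathway"] == "C3").sum()),
            "n_c4": int((table["pathway"] == "C4").sum()),
            "anova_regions": asdict(anova) if anova is not None else None,
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "table": table,
        "stack": stack,
        "model": model,
        "ecozone_raster": ez,
        "cluster_summary": clusters,
        "summaries": summaries,
        "site_thresholds": site_thr,
        "ecozone_thresholds": ez_thr,
        "threshold_map": (med_grid, sd_grid),
        "trends": trends,
        "manifest": manifest,
    }


def group_summaries_input(c3: pd.DataFrame) -> pd.DataFrame:
    """C3 subset with a region column (helper for the regional ANOVA)."""
    from isozone.grain_data import assign_regions

    return assign_regions(c3)


def report_summaries(run_dir: str, decimals: int = 2) -> dict[str, pd.DataFrame]:
    """Re-read pipeline artifacts and emit rounded report tables.

    Produces the grouped-baseline tables (latitude bin / region / country /
    ecozone) and the ecozone threshold table rounded to ``decimals``
    (matching published reporting precision), written next to the originals
    with a ``report_`` prefix.
    """
    run = Path(run_dir)
    wanted = [
        "summary_latbin.csv",
        "summary_region.csv",
        "summary_country.csv",
        "summary_ecozone.csv",
        "ecozone_thresholds.csv",
    ]
    out: dict[str, pd.DataFrame] = {}
    for name in wanted:
        path = run / name
        if not path.exists():
            raise FileNotFoundError(f"[report] missing upstream artifact {path}")
        df = pd.read_csv(path)
        num = df.select_dtypes(include=[np.number]).columns
        df[num] = df[num].round(decimals)
        df.to_csv(run / f"report_{name}", index=False)
        out[name] = df
    return out
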