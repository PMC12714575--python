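"""C3/C4 diet-mixing model and environmentally adjusted collagen δ13C thresholds.

The model turns grain δ13C values into the collagen δ13C value expected for a
consumer whose (theoretical, all-grain) diet contains a fraction ``f`` of C4
grain: each grain value is shifted by the diet→collagen trophic fractionation
offset (+5‰), and the two collagen end-members are mixed linearly,

    threshold(f) = (1 − f) · (δ13C_C3 + Δ) + f · (δ13C_C4 + Δ).

The C4 end-member is the site's measured mean C4 grain value where millets
were recovered, else a regional expectation: −10‰ over most of Europe,
−10.5‰ in the western Mediterranean, −11‰ in the far north.  Thresholds are
computed per grain (to preserve within-site dispersion) and then aggregated
at the site and ecozone level with robust summaries.  A 10% C4 input is the
headline fraction; 20% is computed but theoretical only, since an all-grain
diet overstates the collagen response at higher C4 shares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from isozone.ecozones import EcozoneRaster

__all__ = [
    "ThresholdParams",
    "grain_to_collagen",
    "mix_threshold",
    "resolve_c4_value",
    "site_thresholds",
    "ecozone_thresholds",
    "threshold_map",
]

FAR_NORTH_COUNTRIES = ("Lithuania", "Latvia", "Estonia", "Finland", "Norway", "Sweden")
WEST_MEDITERRANEAN_COUNTRIES = ("Spain", "Portugal", "Andorra")


@dataclass(frozen=True)
class ThresholdParams:
    """Mixing-model configuration.

    trophic_offset
        Diet→collagen δ13C fractionation, ‰ (default +5).
    c4_fractions
        Dietary C4 proportions to evaluate (defaults 0.10 and 0.20).
    c4_default_*
        Theoretical C4 grain end-members (‰) applied at sites without
        measured millet, by regional policy.
    """

    trophic_offset: float = 5.0
    c4_fractions: tuple[float, ...] = (0.10, 0.20)
    c4_default_general: float = -10.0
    c4_default_west_mediterranean: float = -10.5
    c4_default_far_north: float = -11.0
    west_mediterranean_countries: tuple[str, ...] = WEST_MEDITERRANEAN_COUNTRIES
    far_north_countries: tuple[str, ...] = FAR_NORTH_COUNTRIES

    def __post_init__(self) -> None:
        if any(not (0.0 <= f <= 1.0) for f in self.c4_fractions):
            raise ValueError("C4 fractions must lie in [0, 1]")
        if not np.isfinite(self.trophic_offset):
            raise ValueError("trophic offset must be finite")

    def regional_default(self, country: str) -> float:
        """Theoretical C4 grain δ13C for a site in *country* without millet finds."""
        if country in self.far_north_countries:
            return self.c4_default_far_north
        if country in self.west_mediterranean_countries:
            return self.c4_default_west_mediterranean
        return self.c4_default_general


def grain_to_collagen(d13c_grain, params: ThresholdParams | None = None):
    """Apply the diet→collagen trophic offset to a grain δ13C value (‰)."""
    params = params or ThresholdParams()
    return np.asarray(d13c_grain, dtype=float) + params.trophic_offset


def mix_threshold(c3_collagen, c4_collagen, f: float):
    """Linear two-end-member collagen mix: (1−f)·C3 + f·C4 (‰)."""
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"C4 fraction {f} outside [0, 1]")
    return (1.0 - f) * np.asarray(c3_collagen, dtype=float) + f * np.asarray(
        c4_collagen, dtype=float
    )


def resolve_c4_value(
    site_id: str, table: pd.DataFrame, params: ThresholdParams | None = None
) -> tuple[float, str]:
    """C4 end-member for one site: measured site mean if millets were found,
    else the regional default.  Returns (value ‰, provenance)."""
    params = params or ThresholdParams()
    site = table[table["site_id"] == site_id]
    if site.empty:
        raise KeyError(f"site {site_id!r} absent from the grain table")
    c4 = site[site["pathway"] == "C4"]
    if len(c4):
        return float(c4["d13c"].mean()), "measured_site_mean"
    country = site["country"].iloc[0]
    return params.regional_default(country), "regional_default"


def _frac_key(f: float) -> str:
    return f"f{int(round(f * 100)):03d}"


def _per_grain_thresholds(
    table: pd.DataFrame, params: ThresholdParams
) -> pd.DataFrame:
    """Per-C3-grain collagen thresholds, one column per fraction.

    Each C3 grain is paired with its site's resolved C4 end-member; both are
    shifted by the trophic offset and mixed.  Thresholds stay at full
    precision; rounding is a reporting concern.
    """
    c3 = table[table["pathway"] == "C3"].copy()
    if c3.empty:
        raise ValueError("no C3 grains in the table")
    site_c4: dict[str, tuple[float, str]] = {
        sid: resolve_c4_value(sid, table, params) for sid in c3["site_id"].unique()
    }
    c3["c4_value_used"] = [site_c4[s][0] for s in c3["site_id"]]
    c3["c4_provenance"] = [site_c4[s][1] for s in c3["site_id"]]
    c3_coll = grain_to_collagen(c3["d13c"].to_numpy(), params)
    c4_coll = grain_to_collagen(c3["c4_value_used"].to_numpy(), params)
    for f in params.c4_fractions:
        c3[_frac_key(f)] = mix_threshold(c3_coll, c4_coll, f)
    return c3


def _agg_thresholds(
    grains: pd.DataFrame, group_col: str, params: ThresholdParams, n_min: int
) -> pd.DataFrame:
    rows = []
    for key, sub in grains.groupby(group_col, sort=True):
        n = len(sub)
        row: dict = {group_col: key, "n_c3": n, "small_sample_flag": n < n_min}
        for f in params.c4_fractions:
            t = sub[_frac_key(f)].to_numpy()
            row[f"{_frac_key(f)}_mean"] = float(np.mean(t))
            row[f"{_frac_key(f)}_median"] = float(np.median(t))
            row[f"{_frac_key(f)}_sd"] = 0.0 if n == 1 else float(np.std(t, ddof=1))
            row[f"{_frac_key(f)}_mad"] = float(np.mean(np.abs(t - np.mean(t))))
        rows.append(row)
    return pd.DataFrame(rows)


def site_thresholds(
    table: pd.DataFrame, params: ThresholdParams | None = None, n_min: int = 10
) -> pd.DataFrame:
    """Site-level collagen δ13C thresholds per C4 fraction.

    Thresholds are computed grain by grain, then summarised (mean / median /
    SD / MAD) per site; sites with fewer than ``n_min`` C3 grains are
    flagged as non-representative.  Single-grain sites report SD 0 with a
    warning.
    """
    params = params or ThresholdParams()
    grains = _per_grain_thresholds(table, params)
    singles = grains.groupby("site_id").size()
    if (singles == 1).any():
        warnings.warn(
            f"{int((singles == 1).sum())} single-grain sites: SD reported as 0",
            stacklevel=2,
        )
    out = _agg_thresholds(grains, "site_id", params, n_min)
    meta = grains.groupby("site_id").agg(
        c4_value_used=("c4_value_used", "first"),
        c4_provenance=("c4_provenance", "first"),
        lon=("lon", "first"),
        lat=("lat", "first"),
    )
    return out.merge(meta, on="site_id")


def ecozone_thresholds(
    table: pd.DataFrame, params: ThresholdParams | None = None, n_min: int = 10
) -> pd.DataFrame:
    """Ecozone-level thresholds by pooling per-grain thresholds across sites.

    Grains keep their own site's C4 end-member when pooled, so an ecozone
    mixing measured-millet and default-only sites reflects both.  Ecozones
    absent from the data are simply omitted; NaN (unassigned) records are
    dropped.
    """
    params = params or ThresholdParams()
    if "ecozone" not in table.columns:
        raise KeyError("table has no 'ecozone' column; run assign_sites first")
    grains = _per_grain_thresholds(table, params)
    grains = grains[grains["ecozone"].notna()]
    if grains.empty:
        raise ValueError("no C3 grains with an assigned ecozone")
    grains["ecozone"] = grains["ecozone"].astype(int)
    return _agg_thresholds(grains, "ecozone", params, n_min)


def threshold_map(
    ez_raster: EcozoneRaster, thresholds: pd.DataFrame, f: float = 0.10
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterise ecozone threshold medians and SDs onto the ecozone grid.

    Returns (median_grid, sd_grid) as float arrays with NaN where the cell
    is NA or its ecozone has no threshold estimate (warned).
    """
    key = _frac_key(f)
    med_lut: dict[int, float] = dict(
        zip(thresholds["ecozone"].astype(int), thresholds[f"{key}_median"])
    )
    sd_lut: dict[int, float] = dict(
        zip(thresholds["ecozone"].astype(int), thresholds[f"{key}_sd"])
    )
    ids = np.unique(ez_raster.grid)
    uncovered = [
        int(i) for i in ids if i != ez_raster.na_cluster_id and int(i) not in med_lut
    ]
    if uncovered:
        warnings.warn(f"ecozones without threshold data left as nodata: {uncovered}",
                      stacklevel=2)
    med = np.full(ez_raster.grid.shape, np.nan)
    sd = np.full(ez_raster.grid.shape, np.nan)
    for cid, m in med_lut.items():
        sel = ez_raster.grid == cid
        med[sel] = m
        sd[sel] = sd_lut[cid]
    return med, sd
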