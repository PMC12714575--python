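"""K-means environmental ecozones: fit, rasterise, summarise, describe, assign.

Ecozones are clusters of 1-km cells with similar elevation, temperature and
moisture availability, fitted by k-means on z-scored predictors.  One class
is reserved for unclassified (NA / open-water) cells: rather than clustering
a nodata sentinel, NA lattice points are deterministically pre-assigned to
the reserved class and k−1 real clusters are fitted, which keeps the
unclassified geography exact regardless of initialisation.  Because raw
k-means labels are permutation-arbitrary, cluster ids are canonicalised by
ascending mean temperature (id 1 = coldest); published numberings are
display conventions only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from isozone.env_stack import CentroidSample, EnvStack, lonlat_to_mercator

__all__ = [
    "TMP_LEVELS",
    "CWB_LEVELS",
    "DEM_LEVELS",
    "EcozoneModel",
    "EcozoneRaster",
    "fit_ecozones",
    "rasterize_labels",
    "summarize_clusters",
    "label_clusters",
    "assign_sites",
    "ordinal_rank_groups",
]

# 7-level ordinal vocabularies for the qualitative cluster descriptors.
TMP_LEVELS = ("Very Cold", "Cold", "Cool", "Mild", "Warm", "Hot", "Very Hot")
CWB_LEVELS = (
    "Very Dry",
    "Dry",
    "Moderately Dry",
    "Moderate",
    "Humid",
    "Very Humid",
    "Extremely Humid",
)
DEM_LEVELS = ("Very Low", "Low", "Moderately Low", "Middle", "High", "Very High", "Alpine")

# column order of centroid-sample values
_VAR_COLS = {"dem": 0, "tmp": 1, "cwb": 2}


@dataclass
class EcozoneModel:
    """Fitted ecozone model: k−1 real cluster centres in z-space + NA class.

    Real cluster ids run 1..k−1 in ascending mean temperature; the reserved
    NA class id is k.
    """

    k: int
    centers: np.ndarray  # (k-1, 3) rows ordered by canonical id
    na_cluster_id: int
    seed: int
    n_init: int
    inertia: float = np.nan

    def predict(self, values: np.ndarray) -> np.ndarray:
        """Canonical cluster id per point; NaN rows → the reserved NA class.

        Equidistant points break ties toward the lowest canonical id.
        """
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if values.shape[1] != self.centers.shape[1]:
            raise ValueError("dimensionality mismatch between points and model centres")
        labels = np.full(values.shape[0], self.na_cluster_id, dtype=int)
        ok = np.all(np.isfinite(values), axis=1)
        if ok.any():
            d2 = ((values[ok, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
            labels[ok] = np.argmin(d2, axis=1) + 1  # argmin picks the lowest id on ties
        return labels


@dataclass
class EcozoneRaster:
    """Integer cluster-id grid on the stack georeference, with summary lookup."""

    grid: np.ndarray  # (nrows, ncols) int ids; NA cells carry na_cluster_id
    xmin: float
    ymax: float
    dx: float
    dy: float
    crs: str
    na_cluster_id: int
    lookup: pd.DataFrame | None = None

    def index_of(self, x, y):
        col = np.floor((np.asarray(x, dtype=float) - self.xmin) / self.dx).astype(int)
        row = np.floor((self.ymax - np.asarray(y, dtype=float)) / self.dy).astype(int)
        return row, col


def fit_ecozones(
    sample: CentroidSample,
    k: int = 20,
    seed: int = 42,
    n_init: int = 25,
) -> EcozoneModel:
    """Fit k−1 real ecozone clusters on the non-NA centroid points.

    Lloyd's algorithm, best of ``n_init`` random restarts by within-cluster
    sum of squares; identical (inputs, seed, n_init) give identical models.
    """
    X = sample.values[~sample.is_na]
    n_real = k - 1
    if n_real < 1:
        raise ValueError("k must be at least 2 (one real cluster + NA class)")
    if np.unique(X, axis=0).shape[0] < n_real:
        raise ValueError(
            f"only {np.unique(X, axis=0).shape[0]} distinct non-NA points for {n_real} clusters"
        )
    km = KMeans(n_clusters=n_real, n_init=n_init, random_state=seed, algorithm="lloyd")
    km.fit(X)
    order = np.argsort(km.cluster_centers_[:, _VAR_COLS["tmp"]], kind="stable")
    centers = km.cluster_centers_[order]
    return EcozoneModel(
        k=k,
        centers=centers,
        na_cluster_id=k,
        seed=seed,
        n_init=n_init,
        inertia=float(km.inertia_),
    )


def rasterize_labels(model: EcozoneModel, stack: EnvStack) -> EcozoneRaster:
    """Label every stack cell by its nearest cluster centre in z-space."""
    nrows, ncols = stack.grid.shape
    values = np.stack([lyr.data for lyr in stack.layers], axis=-1).reshape(-1, 3)
    labels = model.predict(values).reshape(nrows, ncols)
    g = stack.grid
    return EcozoneRaster(
        grid=labels,
        xmin=g.xmin,
        ymax=g.ymax,
        dx=g.dx,
        dy=g.dy,
        crs=g.crs,
        na_cluster_id=model.na_cluster_id,
    )


def _minmax_rescale(v: np.ndarray) -> tuple[np.ndarray, float]:
    lo, hi = np.nanmin(v), np.nanmax(v)
    if hi == lo:
        raise ValueError("cannot rescale: all cluster means identical for a variable")
    return (v - lo) / (hi - lo), hi - lo


def summarize_clusters(model: EcozoneModel, sample: CentroidSample) -> pd.DataFrame:
    """Per-cluster mean/SD of the three predictors, min-max rescaled to [0, 1].

    The k−1 cluster-mean values are rescaled per variable so the coldest/
    driest/lowest cluster mean maps to 0 and the warmest/wettest/highest to
    1; SDs are divided by the same per-variable range so dispersion stays
    comparable.  The NA class is reported with NaN statistics.
    """
    labels = model.predict(sample.values)
    rows = []
    for cid in range(1, model.k):
        sel = labels == cid
        n = int(sel.sum())
        if n == 0:
            warnings.warn(f"cluster {cid} has no sample points; NaN summary", stacklevel=2)
            rows.append(dict(cluster_id=cid, n_cells=0, **{f"{s}_{v}": np.nan
                        for s in ("mean", "sd") for v in ("tmp", "cwb", "dem")}))
            continue
        vals = sample.values[sel]
        rows.append(
            dict(
                cluster_id=cid,
                n_cells=n,
                mean_tmp=float(np.mean(vals[:, _VAR_COLS["tmp"]])),
                mean_cwb=float(np.mean(vals[:, _VAR_COLS["cwb"]])),
                mean_dem=float(np.mean(vals[:, _VAR_COLS["dem"]])),
                sd_tmp=float(np.std(vals[:, _VAR_COLS["tmp"]])),
                sd_cwb=float(np.std(vals[:, _VAR_COLS["cwb"]])),
                sd_dem=float(np.std(vals[:, _VAR_COLS["dem"]])),
            )
        )
    df = pd.DataFrame(rows)
    if (df["n_cells"] > 0).sum() < 2:
        raise ValueError("need at least 2 populated clusters to rescale summaries")
    for var in ("tmp", "cwb", "dem"):
        rescaled, rng = _minmax_rescale(df[f"mean_{var}"].to_numpy())
        df[f"mean_{var}"] = rescaled
        df[f"sd_{var}"] = df[f"sd_{var}"] / rng
    na_row = dict(cluster_id=model.na_cluster_id, n_cells=int(model.predict(sample.values).size
                  - df["n_cells"].sum()), **{f"{s}_{v}": np.nan
                  for s in ("mean", "sd") for v in ("tmp", "cwb", "dem")})
    df = pd.concat([df, pd.DataFrame([na_row])], ignore_index=True)
    return df


def ordinal_rank_groups(values: np.ndarray, n_groups: int = 7) -> np.ndarray:
    """Cut ranked values into near-equal groups (sizes differ by ≤ 1).

    Extras are distributed from the extremes inward (lowest group first,
    then highest, then second-lowest, ...), so the tails of the vocabulary
    stay slightly better populated than the middle.  Returns the 0-based
    group index per value, monotone non-decreasing in the value.
    """
    values = np.asarray(values, dtype=float)
    m = values.size
    base, rem = divmod(m, n_groups)
    extreme_order = []
    lo, hi = 0, n_groups - 1
    while lo <= hi:
        extreme_order.append(lo)
        if hi != lo:
            extreme_order.append(hi)
        lo, hi = lo + 1, hi - 1
    sizes = np.full(n_groups, base, dtype=int)
    for g in extreme_order[:rem]:
        sizes[g] += 1
    order = np.argsort(values, kind="stable")
    groups = np.empty(m, dtype=int)
    start = 0
    for g, sz in enumerate(sizes):
        groups[order[start : start + sz]] = g
        start += sz
    return groups


def label_clusters(summaries: pd.DataFrame) -> pd.DataFrame:
    """Attach a "TMP|CWB|DEM" ordinal descriptor to each real cluster.

    Per variable, clusters are ranked by rescaled mean and cut into 7
    near-equal rank groups mapped onto the ordered vocabularies.  With fewer
    than 7 real clusters the vocabulary is thinned to the available count
    (keeping both extremes) with a warning.
    """
    df = summaries.copy()
    real = df[df["mean_tmp"].notna()].index
    m = len(real)
    if m == 0:
        raise ValueError("no real clusters to label")
    n_groups = min(7, m)
    if m < 7:
        warnings.warn(f"only {m} real clusters; using a coarser {n_groups}-level labelling",
                      stacklevel=2)
    vocab_idx = np.round(np.linspace(0, 6, n_groups)).astype(int)
    parts = {}
    for var, vocab in (("tmp", TMP_LEVELS), ("cwb", CWB_LEVELS), ("dem", DEM_LEVELS)):
        groups = ordinal_rank_groups(df.loc[real, f"mean_{var}"].to_numpy(), n_groups)
        levels = [vocab[vocab_idx[g]] for g in groups]
        parts[var] = levels
    desc = pd.Series(index=df.index, dtype=object)
    desc.loc[real] = [
        f"{t}|{c}|{d}" for t, c, d in zip(parts["tmp"], parts["cwb"], parts["dem"])
    ]
    desc.loc[df.index.difference(real)] = "unclassified|waterbody"
    df["description"] = desc
    return df


def assign_sites(
    table: pd.DataFrame,
    ez: EcozoneRaster,
    fallback_radius: float | None = None,
) -> pd.DataFrame:
    """Attach the containing cell's ecozone id to each grain record.

    Site lon/lat (WGS84) is projected to the raster CRS; sites landing on NA
    cells (e.g. coastal water) fall back to the nearest valid cell within
    ``fallback_radius`` metres (default: 1.5 cell sizes), else stay
    unassigned (NaN) with a warning.  Sites outside the raster extent raise.
    """
    if fallback_radius is None:
        fallback_radius = 1.5 * max(ez.dx, ez.dy)
    out = table.copy()
    x, y = lonlat_to_mercator(out["lon"].to_numpy(), out["lat"].to_numpy())
    row, col = ez.index_of(x, y)
    nrows, ncols = ez.grid.shape
    outside = (row < 0) | (row >= nrows) | (col < 0) | (col >= ncols)
    if outside.any():
        bad = out.loc[outside, "site_id"].unique()[:5]
        raise ValueError(f"sites outside the ecozone raster extent: {list(bad)}")
    zone = ez.grid[row, col].astype(float)

    na_hits = zone == ez.na_cluster_id
    if na_hits.any():
        valid_rc = np.argwhere(ez.grid != ez.na_cluster_id)
        max_cells = fallback_radius / min(ez.dx, ez.dy)
        for i in np.flatnonzero(na_hits):
            d2 = (valid_rc[:, 0] - row[i]) ** 2 + (valid_rc[:, 1] - col[i]) ** 2
            j = int(np.argmin(d2))
            if np.sqrt(d2[j]) <= max_cells:
                zone[i] = ez.grid[valid_rc[j, 0], valid_rc[j, 1]]
            else:
                zone[i] = np.nan
        n_un = int(np.isnan(zone).sum())
        if n_un:
            warnings.warn(
                f"{n_un} records on NA cells with no valid neighbour within "
                f"{fallback_radius:g} m left unassigned",
                stacklevel=2,
            )
    out["ecozone"] = zone
    return out
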