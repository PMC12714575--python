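"""Charred-grain δ13C tables: schema, validation, binning schemes, robust summaries.

A grain table is a :class:`pandas.DataFrame` with one row per measured grain.
All δ13C values are per mil (‰) vs VPDB and deliberately *uncorrected* for the
charring effect; calendar years are signed integers (BCE negative, no year 0).
C3 and C4 grains are never pooled in any summary — their δ13C distributions are
disjoint by photosynthetic pathway and are analysed separately throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "C4_SPECIES",
    "C3_SPECIES",
    "GroupSummary",
    "LatBinScheme",
    "RegionScheme",
    "DEFAULT_REGION_SCHEME",
    "SchemaError",
    "read_grain_table",
    "write_grain_table",
    "validate_grain_table",
    "assign_latitude_bin",
    "assign_latitude_bins",
    "assign_region",
    "assign_regions",
    "summarize_group",
    "group_summaries",
]

REQUIRED_COLUMNS = (
    "record_id",
    "site_id",
    "site_name",
    "lon",
    "lat",
    "country",
    "species",
    "pathway",
    "d13c",
    "date_from",
    "date_to",
    "source_ref",
)
OPTIONAL_COLUMNS = ("date_mean", "corrected_flag", "ecozone")

#: Millets are the only C4 crops in the archaeobotanical record covered here.
C4_SPECIES = frozenset({"Panicum miliaceum", "Setaria italica"})
C3_SPECIES = frozenset({"Avena", "Secale", "Hordeum", "Triticum"})

# Soft plausibility bounds (‰ vs VPDB) for the two photosynthetic pathways.
C3_D13C_RANGE = (-35.0, -20.0)
C4_D13C_RANGE = (-14.0, -8.0)
# Geographic window of the compilation (degrees, WGS84).
LAT_RANGE = (30.0, 63.0)
LON_RANGE = (-8.0, 45.0)


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


# ---------------------------------------------------------------------------
# Binning schemes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LatBinScheme:
    """Latitude bins: lower-inclusive half-open intervals, last bin closed.

    The default edges partition [30, 63] into 5-degree bands with a short
    terminal [60-63] band; a boundary latitude belongs to the *upper* bin
    (e.g. 55.0 falls in [55-60)), and 63.0 falls in the closed last bin.
    """

    edges: tuple[float, ...] = (30.0, 35.0, 40.0, 45.0, 50.0, 55.0, 60.0, 63.0)

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def labels(self) -> tuple[str, ...]:
        out = []
        for i, (a, b) in enumerate(zip(self.edges, self.edges[1:])):
            close = "]" if i == len(self.edges) - 2 else ")"
            out.append(f"[{a:g}-{b:g}{close}")
        return tuple(out)

    def assign(self, lat: float) -> str:
        lo, hi = self.edges[0], self.edges[-1]
        if not (lo <= lat <= hi):
            raise ValueError(f"latitude {lat} outside bin range [{lo}, {hi}]")
        # searchsorted with side='right' makes each edge belong to the upper bin
        idx = int(np.searchsorted(np.asarray(self.edges), lat, side="right")) - 1
        idx = min(idx, len(self.edges) - 2)  # fold the closed endpoint into the last bin
        return self.labels[idx]

    def assign_many(self, lats: Sequence[float]) -> np.ndarray:
        return np.array([self.assign(float(v)) for v in lats], dtype=object)


def assign_latitude_bin(lat: float, scheme: LatBinScheme | None = None) -> str:
    return (scheme or LatBinScheme()).assign(lat)


def assign_latitude_bins(lats: Sequence[float], scheme: LatBinScheme | None = None) -> np.ndarray:
    return (scheme or LatBinScheme()).assign_many(lats)


# ---------------------------------------------------------------------------
# Region scheme
# ---------------------------------------------------------------------------

REGIONS = ("North", "UK", "Central/West", "South")

_DEFAULT_COUNTRY_TO_REGION: dict[str, str] = {
    # UK constituents
    "England": "UK",
    "Scotland": "UK",
    "Wales": "UK",
    # North: Baltic + Nordic countries + Denmark
    "Lithuania": "North",
    "Latvia": "North",
    "Estonia": "North",
    "Finland": "North",
    "Norway": "North",
    "Sweden": "North",
    "Denmark": "North",
    "Iceland": "North",
    # South: Mediterranean + Near East
    "Andorra": "South",
    "Portugal": "South",
    "Spain": "South",
    "Italy": "South",
    "Malta": "South",
    "Greece": "South",
    "Albania": "South",
    "Croatia": "South",
    "Bulgaria": "South",
    "Cyprus": "South",
    "Turkey": "South",
    "Georgia": "South",
    "Syria": "South",
    "Lebanon": "South",
    "Israel": "South",
    "Jordan": "South",
    # everything else in the compilation window: Central/West
    "Ireland": "Central/West",
    "France": "Central/West",
    "Belgium": "Central/West",
    "Netherlands": "Central/West",
    "Luxembourg": "Central/West",
    "Germany": "Central/West",
    "Switzerland": "Central/West",
    "Austria": "Central/West",
    "Czech Republic": "Central/West",
    "Slovakia": "Central/West",
    "Poland": "Central/West",
    "Hungary": "Central/West",
    "Slovenia": "Central/West",
    "Romania": "Central/West",
    "Serbia": "Central/West",
    "Ukraine": "Central/West",
    "Moldova": "Central/West",
}


@dataclass(frozen=True)
class RegionScheme:
    """Country → macro-region mapping (North / UK / Central-West / South).

    The four-region split follows the conventional European dietary-isotope
    literature; the exact country list is an editable convention, not a fact
    of nature, so the table is configurable.
    """

    country_to_region: Mapping[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_COUNTRY_TO_REGION)
    )

    def assign(self, country: str) -> str:
        try:
            return self.country_to_region[country]
        except KeyError:
            raise KeyError(
                f"country {country!r} has no region mapping; extend the RegionScheme"
            ) from None


DEFAULT_REGION_SCHEME = RegionScheme()


def assign_region(country: str, scheme: RegionScheme | None = None) -> str:
    return (scheme or DEFAULT_REGION_SCHEME).assign(country)


def assign_regions(table: pd.DataFrame, scheme: RegionScheme | None = None) -> pd.DataFrame:
    """Return a copy of *table* with a ``region`` column added."""
    scheme = scheme or DEFAULT_REGION_SCHEME
    out = table.copy()
    out["region"] = [scheme.assign(c) for c in out["country"]]
    return out


# ---------------------------------------------------------------------------
# Validation and I/O
# ---------------------------------------------------------------------------


def _row_problems(df: pd.DataFrame) -> pd.Series:
    """Return a Series of per-row problem descriptions ('' where clean)."""
    msgs = pd.Series("", index=df.index, dtype=object)

    def flag(mask: pd.Series, msg: str) -> None:
        sel = mask.fillna(False)
        msgs[sel] = msgs[sel].str.cat([msg] * int(sel.sum()), sep="; ").str.lstrip("; ")

    c3 = df["pathway"] == "C3"
    c4 = df["pathway"] == "C4"
    flag(~(c3 | c4), "pathway must be C3 or C4")
    flag(c3 & ~df["d13c"].between(*C3_D13C_RANGE), "C3 d13c outside plausible range")
    flag(c4 & ~df["d13c"].between(*C4_D13C_RANGE), "C4 d13c outside plausible range")
    flag(~df["lat"].between(*LAT_RANGE), "latitude outside study window")
    flag(~df["lon"].between(*LON_RANGE), "longitude outside study window")
    flag(df["date_from"] > df["date_to"], "date_from after date_to")
    is_millet = df["species"].isin(C4_SPECIES)
    is_known_c3 = df["species"].isin(C3_SPECIES)
    flag(is_millet & ~c4, "millet species must be pathway C4")
    flag(is_known_c3 & ~c3, "C3 cereal species must be pathway C3")
    return msgs


def validate_grain_table(df: pd.DataFrame, strict: bool = False) -> pd.DataFrame:
    """Validate schema and row invariants of a grain table.

    Rows violating invariants are dropped (with a warning) in strict mode
    and kept with a warning otherwise.  ``date_mean`` is filled with the
    midpoint of (date_from, date_to) where absent.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"grain table missing required columns: {missing}")

    out = df.copy()
    for col in ("lon", "lat", "d13c"):
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = vals.isna() & out[col].notna()
        if bad.any():
            msg = f"{int(bad.sum())} rows with unparsable {col!r} values"
            if strict:
                raise ValueError(msg)
            warnings.warn(msg + " (dropped)", stacklevel=2)
        out[col] = vals
    unparsable = out[["lon", "lat", "d13c"]].isna().any(axis=1)
    out = out[~unparsable]

    for col in ("date_from", "date_to"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    if "date_mean" not in out.columns:
        out["date_mean"] = np.nan
    out["date_mean"] = pd.to_numeric(out["date_mean"], errors="coerce")
    mid = (out["date_from"] + out["date_to"]) / 2.0
    out["date_mean"] = out["date_mean"].fillna(mid)
    if "corrected_flag" not in out.columns:
        out["corrected_flag"] = False

    problems = _row_problems(out)
    bad = problems != ""
    if bad.any():
        detail = "; ".join(
            f"{rid}: {msg}" for rid, msg in zip(out.loc[bad, "record_id"].head(5), problems[bad])
        )
        if strict:
            warnings.warn(
                f"rejected {int(bad.sum())} invalid rows in strict mode ({detail} ...)",
                stacklevel=2,
            )
            out = out[~bad]
        else:
            warnings.warn(
                f"{int(bad.sum())} rows violate grain-table invariants ({detail} ...)",
                stacklevel=2,
            )
    return out.reset_index(drop=True)


def read_grain_table(path, strict: bool = False) -> pd.DataFrame:
    """Read and validate a grain δ13C table from CSV (UTF-8, '.' decimals)."""
    df = pd.read_csv(path, encoding="utf-8")
    return validate_grain_table(df, strict=strict)


def write_grain_table(df: pd.DataFrame, path) -> None:
    """Write a grain table as CSV; round-trips through :func:`read_grain_table`."""
    df.to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# Robust group summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSummary:
    """n / mean / median / sample SD / mean-absolute-deviation for one group."""

    group_key: str
    n: int
    mean: float
    median: float
    sd: float
    mad: float
    small_sample_flag: bool


def summarize_group(
    values: Iterable[float],
    n_min: int = 10,
    group_key: str = "",
    mad_center: str = "mean",
) -> GroupSummary:
    """Summarise one group of δ13C values.

    SD is the sample standard deviation (divisor n−1); MAD is the *mean*
    absolute deviation about the arithmetic mean by default (``mad_center``
    may be set to ``"median"``).  Groups with n < ``n_min`` are flagged as
    non-representative.  A single-value group gets sd = 0 with a warning.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarise an empty group")
    if mad_center not in ("mean", "median"):
        raise ValueError("mad_center must be 'mean' or 'median'")
    n = int(x.size)
    mean = float(np.mean(x))
    median = float(np.median(x))
    if n == 1:
        warnings.warn(f"group {group_key!r} has a single value; sd reported as 0", stacklevel=2)
        sd = 0.0
    else:
        sd = float(np.std(x, ddof=1))
    center = mean if mad_center == "mean" else median
    mad = float(np.mean(np.abs(x - center)))
    return GroupSummary(
        group_key=str(group_key),
        n=n,
        mean=mean,
        median=median,
        sd=sd,
        mad=mad,
        small_sample_flag=n < n_min,
    )


_GROUPING_COLUMN = {
    "site": "site_id",
    "country": "country",
    "region": "region",
    "latbin": "latbin",
    "ecozone": "ecozone",
    "species": "species",
    "pathway": "pathway",
}


def group_summaries(
    table: pd.DataFrame,
    by: str,
    n_min: int = 10,
    mad_center: str = "mean",
    latbin_scheme: LatBinScheme | None = None,
    region_scheme: RegionScheme | None = None,
) -> pd.DataFrame:
    """Per-group δ13C summaries, C3 and C4 grains summarised separately.

    ``by`` is one of site / country / region / latbin / ecozone / species /
    pathway.  Derived groupings (region, latbin) are computed on the fly if
    the column is absent; ``ecozone`` requires prior assignment.  Returns a
    DataFrame with one row per (pathway, group).
    """
    if by not in _GROUPING_COLUMN:
        raise KeyError(f"unknown grouping {by!r}; expected one of {sorted(_GROUPING_COLUMN)}")
    col = _GROUPING_COLUMN[by]
    df = table
    if col not in df.columns:
        if by == "latbin":
            df = df.copy()
            df["latbin"] = assign_latitude_bins(df["lat"], latbin_scheme)
        elif by == "region":
            df = assign_regions(df, region_scheme)
        else:
            raise KeyError(f"grouping column {col!r} not present; assign it first")

    rows = []
    group_cols = ["pathway"] if by == "pathway" else ["pathway", col]
    for keys, sub in df.groupby(group_cols, sort=True, observed=True):
        pathway = keys[0]
        label = keys[0] if by == "pathway" else keys[1]
        s = summarize_group(sub["d13c"], n_min=n_min, group_key=str(label), mad_center=mad_center)
        rows.append(
            {
                "pathway": pathway,
                "group": s.group_key,
                "n": s.n,
                "mean": s.mean,
                "median": s.median,
                "sd": s.sd,
                "mad": s.mad,
                "small_sample_flag": s.small_sample_flag,
            }
        )
    return pd.DataFrame(rows)
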