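"""Published reference tables shipped with the package.

Two small CSVs hold published summary statistics used as inputs and as
regression fixtures:

* ``published_ecozone_baselines.csv`` — per-ecozone C3/C4 grain δ13C
  summaries (n, mean, median, MAD, SD) plus the C4 end-member policy that
  applies in each ecozone (``measured`` where millets were recovered there,
  else the regional theoretical default).
* ``published_cluster_summary.csv`` — rescaled per-cluster predictor means/
  SDs and the qualitative "TMP|CWB|DEM" descriptors of the 20-cluster
  European ecozone model (the unclassified water class has no statistics).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["published_ecozone_baselines", "published_cluster_summary"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("isozone.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def published_ecozone_baselines() -> pd.DataFrame:
    """Per-ecozone published C3/C4 grain δ13C summary statistics."""
    return _read("published_ecozone_baselines.csv")


def published_cluster_summary() -> pd.DataFrame:
    """Published rescaled cluster means/SDs and ordinal descriptors."""
    return _read("published_cluster_summary.csv")
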