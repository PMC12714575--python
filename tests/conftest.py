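import numpy as np
import pandas as pd
import pytest

from isozone.env_stack import EnvLayer
from isozone.synthetic import SynthConfig, generate_grain_dataset


def make_table(rows):
    """Build a minimal valid grain table from (site, country, lon, lat, species, pathway, d13c)."""
    recs = []
    for i, (site, country, lon, lat, species, pathway, d13c) in enumerate(rows):
        recs.append(
            dict(
                record_id=f"r{i}",
                site_id=site,
                site_name=site,
                lon=lon,
                lat=lat,
                country=country,
                species=species,
                pathway=pathway,
                d13c=d13c,
                date_from=-1000,
                date_to=-800,
                source_ref="fixture",
            )
        )
    return pd.DataFrame(recs)


@pytest.fixture
def tiny_table():
    """Two sites, each with C3 and C4 grains."""
    return make_table(
        [
            ("A", "Lithuania", 24.0, 55.5, "Hordeum", "C3", -25.0),
            ("A", "Lithuania", 24.0, 55.5, "Triticum", "C3", -25.4),
            ("A", "Lithuania", 24.0, 55.5, "Panicum miliaceum", "C4", -10.9),
            ("B", "Greece", 22.5, 38.0, "Triticum", "C3", -23.1),
            ("B", "Greece", 22.5, 38.0, "Hordeum", "C3", -23.5),
            ("B", "Greece", 22.5, 38.0, "Setaria italica", "C4", -10.2),
        ]
    )


@pytest.fixture(scope="session")
def synth_small():
    """Small seeded synthetic dataset with truth record (session-cached)."""
    cfg = SynthConfig(seed=7, n_sites=30, grains_per_site=(10, 20))
    table, truth = generate_grain_dataset(cfg)
    return cfg, table, truth


def constant_layer(value=5.0, shape=(10, 10), kind="temperature", cell=1000.0):
    return EnvLayer(
        kind=kind,
        data=np.full(shape, float(value)),
        xmin=0.0,
        ymax=shape[0] * cell,
        dx=cell,
        dy=cell,
    )
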