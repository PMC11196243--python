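"""Bundled field tables from the three-pool Merced vernal pool survey.

Two small printed tables travel with the package: the species attribute
list (42 flowering species with family, origin, and the zones each was
observed in) and the pool dimension/edaphic table (transect spans, depth,
clay content).  They drive the species-accounting and pool-geometry
checks and serve as realistic inputs for examples.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ..communities import normalize_zone
from ..geometry import PoolGeometry

__all__ = ["load_merced_species", "load_merced_pools"]


def _path(name: str):
    return resources.files(__package__) / name


def load_merced_species() -> pd.DataFrame:
    """Species attribute table: species, genus, family, native, zones (set)."""
    df = pd.read_csv(_path("merced_species.csv"))
    df["native"] = df["native"].str.strip().str.lower().eq("yes")
    df["zones"] = df["zones"].map(
        lambda z: frozenset(normalize_zone(part) for part in str(z).split(";"))
    )
    return df


def load_merced_pools() -> pd.DataFrame:
    """Pool dimensions and edaphic characteristics, plus PoolGeometry objects."""
    df = pd.read_csv(_path("merced_pools.csv"))
    df["geometry"] = [
        PoolGeometry(r.ns_span_m, r.ew_span_m, r.max_depth_m, r.clay_bottom_pct)
        for r in df.itertuples()
    ]
    return df
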