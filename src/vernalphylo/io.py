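"""Readers and writers for the package's delimited-text dialects.

Community observations travel as long-format CSV (pool, zone, year, week,
species), traits as a species-keyed CSV, climate as a daily CSV, and trees
as newick.  The writers emit exactly what the readers consume, so a
simulated study folder round-trips bit-for-bit.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from .communities import CommunityCollection, CommunityObservation, normalize_zone
from .phylogeny import Phylogeny
from .tables import ClimateSeries, TraitTable

__all__ = [
    "read_community_long",
    "write_community_long",
    "read_traits",
    "write_traits",
    "read_climate",
    "write_climate",
    "read_newick",
    "write_newick",
]

_COMMUNITY_COLUMNS = ["pool", "zone", "year", "week", "species"]


def read_community_long(path) -> CommunityCollection:
    """Read weekly presence observations from long-format CSV.

    Duplicate (pool, zone, year, week, species) rows are deduplicated with
    a warning; malformed rows raise naming the offending line.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _COMMUNITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"community file missing columns: {missing}")

    records = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            pool = str(row.pool).strip()
            zone = normalize_zone(row.zone)
            year = int(row.year)
            week = int(row.week)
            species = str(row.species).strip()
            if not pool or not species or pool == "nan" or species == "nan":
                raise ValueError("empty pool or species field")
            if week < 1:
                raise ValueError("week must be >= 1")
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed community row at line {pos}: {exc}") from exc
        records.append((pool, zone, year, week, species))

    n_dup = len(records) - len(set(records))
    if n_dup:
        warnings.warn(f"dropped {n_dup} duplicate observation row(s)", stacklevel=2)
        records = list(dict.fromkeys(records))

    cells: dict = {}
    for pool, zone, year, week, species in records:
        cells.setdefault((pool, zone, year, week), set()).add(species)
    obs = [
        CommunityObservation(pool, zone, year, frozenset(sp), week=week)
        for (pool, zone, year, week), sp in sorted(cells.items())
    ]
    return CommunityCollection(obs, level="weekly")


def write_community_long(collection: CommunityCollection, path) -> None:
    if collection.level != "weekly":
        raise ValueError("only weekly collections are written to long format")
    df = collection.to_frame()[_COMMUNITY_COLUMNS]
    df.to_csv(path, index=False)


def read_traits(path) -> TraitTable:
    df = pd.read_csv(path)
    if "species" not in df.columns:
        raise ValueError("trait file requires a 'species' column")
    df = df.set_index("species")
    if df["native"].dtype == object:
        df["native"] = (
            df["native"].astype(str).str.strip().str.lower().isin(["yes", "true", "1"])
        )
    return TraitTable(df)


def write_traits(traits: TraitTable, path) -> None:
    traits.df.to_csv(path)


def read_climate(path) -> ClimateSeries:
    return ClimateSeries(pd.read_csv(path))


def write_climate(climate: ClimateSeries, path) -> None:
    out = climate.df.copy()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_newick(path) -> Phylogeny:
    """Read a rooted, branch-lengthed newick tree, reporting tips/polytomies."""
    tree = Phylogeny.from_file(path)
    if tree.n_polytomies:
        warnings.warn(
            f"tree has {tree.n_polytomies} polytomy(ies) among {tree.n_tips} tips",
            stacklevel=2,
        )
    return tree


def write_newick(tree: Phylogeny, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")
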