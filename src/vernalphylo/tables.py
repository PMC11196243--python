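"""Species attributes, functional traits, and daily climate series.

All three are thin, validated wrappers over pandas DataFrames so the rest
of the package can rely on column names and invariants (non-negative
traits, ordered dates, tmin <= tmean <= tmax) without re-checking them.
Missing trait values are NaN, never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SpeciesRecord", "TraitTable", "ClimateSeries", "cumulative_rainfall"]

#: Functional trait columns and their units.
TRAIT_COLUMNS = {
    "height": "cm",
    "leaf_area": "cm2",
    "seed_mass": "g",
    "inflorescence_size": "cm",
    "floral_duration": "days",
    "first_flowering": "week",
}


@dataclass(frozen=True)
class SpeciesRecord:
    """One species attribute row: identity, family, origin, zones observed."""

    name: str
    family: str = ""
    native: bool = True
    zones_observed: frozenset = frozenset()

    def __post_init__(self):
        if not self.name:
            raise ValueError("species name must be nonempty")
        object.__setattr__(self, "zones_observed", frozenset(self.zones_observed))


class TraitTable:
    """Per-species functional traits and attributes, indexed by species name.

    Any subset of :data:`TRAIT_COLUMNS` may be present; a boolean
    ``native`` column is required.  Extra columns (family, latent
    simulation variables) pass through untouched.
    """

    def __init__(self, df: pd.DataFrame):
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].tolist()
            raise ValueError(f"duplicate species in trait table: {dups}")
        if "native" not in df.columns:
            raise ValueError("trait table requires a 'native' column")
        for col in TRAIT_COLUMNS:
            if col in df.columns:
                vals = pd.to_numeric(df[col], errors="raise")
                if (vals.dropna() < 0).any():
                    raise ValueError(f"trait {col!r} has negative values")
        self.df = df.copy()
        self.df.index = self.df.index.astype(str)
        self.df.index.name = "species"

    @property
    def species(self) -> list:
        return list(self.df.index)

    @property
    def natives(self) -> frozenset:
        return frozenset(self.df.index[self.df["native"].astype(bool)])

    @property
    def invasives(self) -> frozenset:
        return frozenset(self.df.index[~self.df["native"].astype(bool)])

    def trait(self, name: str) -> pd.Series:
        if name not in self.df.columns:
            raise KeyError(f"trait {name!r} not in table")
        return self.df[name]

    def __len__(self) -> int:
        return len(self.df)


class ClimateSeries:
    """Daily precipitation and min/mean/max air temperature."""

    COLUMNS = ("precipitation", "tmin", "tmean", "tmax")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in ("date",) + self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"climate table missing columns: {missing}")
        df = df.copy()
        df["date"] = pd.to_datetime(df["date"])
        if not df["date"].is_monotonic_increasing or df["date"].duplicated().any():
            raise ValueError("climate dates must be strictly increasing")
        if (df["precipitation"] < 0).any():
            raise ValueError("precipitation cannot be negative")
        bad = ~((df["tmin"] <= df["tmean"]) & (df["tmean"] <= df["tmax"]))
        if bad.any():
            raise ValueError(
                f"tmin <= tmean <= tmax violated on {int(bad.sum())} day(s)"
            )
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def window(self, start, end) -> pd.DataFrame:
        start, end = pd.Timestamp(start), pd.Timestamp(end)
        if start > end:
            raise ValueError("start must not be after end")
        if start < self.df["date"].iloc[0] or end > self.df["date"].iloc[-1]:
            raise ValueError("requested window extends outside the series")
        mask = (self.df["date"] >= start) & (self.df["date"] <= end)
        return self.df.loc[mask]


def cumulative_rainfall(cs: ClimateSeries, start, end) -> float:
    """Total precipitation (mm) over the inclusive [start, end] date window.

    The conventional accounting window for this habitat is the water year,
    October 1 through the following September.
    """
    return float(cs.window(start, end)["precipitation"].sum())
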