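"""Community observation units, zone labels, season bins, and aggregation.

The sampling unit is a weekly flowering-presence census of one vegetation
zone (bottom / edge / upland) of one pool.  Downstream analyses use the
same censuses at coarser grain: zone-year-season (union of the three-week
bin), zone-year (union of the whole spring), or zone pooled across pools
and years.  Aggregation is always a set union, so richness can only grow
with coarsening.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "ZONES",
    "SEASONS",
    "normalize_zone",
    "season_bin",
    "CommunityObservation",
    "CommunityCollection",
    "aggregate",
]

#: Canonical zone order, bottom of the pool outward.
ZONES = ("bottom", "edge", "upland")

#: Canonical season order across the nine-week spring.
SEASONS = ("early", "mid", "late")

_ZONE_ALIASES = {"b": "bottom", "e": "edge", "u": "upland"}

#: Supported aggregation grains, finest to coarsest.
LEVELS = ("weekly", "zone-year-season", "zone-year", "zone-pooled")


def normalize_zone(label: str) -> str:
    """Map a raw zone label to its canonical form.

    Labels are case- and whitespace-insensitive; single-letter codes
    B/E/U (as used in species attribute tables) are accepted.
    """
    z = str(label).strip().lower()
    z = _ZONE_ALIASES.get(z, z)
    if z not in ZONES:
        raise ValueError(f"unknown zone label: {label!r} (expected one of {ZONES})")
    return z


def season_bin(week: int) -> str:
    """Assign a survey week (1-9, counted from the March 1 start) to a season.

    Weeks 1-3 are 'early', 4-6 'mid', 7-9 'late'.  Years whose flowering
    season ended early simply leave the late bin partially filled.
    """
    week = int(week)
    if not 1 <= week <= 9:
        raise ValueError(f"week must be in 1..9, got {week}")
    return SEASONS[(week - 1) // 3]


@dataclass(frozen=True)
class CommunityObservation:
    """One community: the species flowering in a (pool, zone, year[, week/season]) cell."""

    pool: str | None
    zone: str
    year: int | None
    species: frozenset
    week: int | None = None
    season: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "zone", normalize_zone(self.zone))
        object.__setattr__(self, "species", frozenset(self.species))
        if self.week is not None and self.week < 1:
            raise ValueError("week must be >= 1")

    @property
    def richness(self) -> int:
        return len(self.species)

    def key(self, level: str = "weekly") -> tuple:
        if level == "weekly":
            return (self.pool, self.zone, self.year, self.week)
        if level == "zone-year-season":
            season = self.season if self.season is not None else season_bin(self.week)
            return (self.pool, self.zone, self.year, season)
        if level == "zone-year":
            return (self.pool, self.zone, self.year)
        if level == "zone-pooled":
            return (self.zone,)
        raise ValueError(f"unknown aggregation level: {level!r}")


@dataclass
class CommunityCollection:
    """A set of community observations at a uniform aggregation grain."""

    observations: list = field(default_factory=list)
    level: str = "weekly"

    def __post_init__(self):
        if self.level not in LEVELS:
            raise ValueError(f"unknown aggregation level: {self.level!r}")
        seen = set()
        for obs in self.observations:
            k = obs.key(self.level) if self.level == "weekly" else _id_key(obs, self.level)
            if k in seen:
                raise ValueError(f"duplicate community cell {k}")
            seen.add(k)

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self) -> Iterator[CommunityObservation]:
        return iter(self.observations)

    @property
    def species_pool(self) -> frozenset:
        out: set = set()
        for obs in self.observations:
            out |= obs.species
        return frozenset(out)

    def subset(self, keep: Iterable[str]) -> "CommunityCollection":
        """Restrict every community to ``keep`` species (e.g. natives only).

        Communities left empty are dropped.
        """
        keep = frozenset(keep)
        obs = [
            replace(o, species=o.species & keep)
            for o in self.observations
            if o.species & keep
        ]
        return CommunityCollection(obs, level=self.level)

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per (cell, species)."""
        rows = [
            {
                "pool": o.pool,
                "zone": o.zone,
                "year": o.year,
                "week": o.week,
                "season": o.season,
                "species": s,
            }
            for o in self.observations
            for s in sorted(o.species)
        ]
        return pd.DataFrame(
            rows, columns=["pool", "zone", "year", "week", "season", "species"]
        )


def _id_key(obs: CommunityObservation, level: str) -> tuple:
    # identity key at an aggregated grain: season kept only where meaningful
    if level == "zone-year-season":
        return (obs.pool, obs.zone, obs.year, obs.season)
    return obs.key(level)


def aggregate(collection: CommunityCollection, level: str) -> CommunityCollection:
    """Union weekly censuses up to a coarser grain.

    ``level`` is one of ``zone-year-season`` (3 pools x 3 zones x 3 years x
    3 seasons -> at most 81 cells on the full design), ``zone-year`` (27
    cells), or ``zone-pooled`` (one community per zone).  Aggregating a
    collection to its own level is the identity.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown aggregation level: {level!r}")
    if level == collection.level:
        return CommunityCollection(list(collection.observations), level=level)
    if LEVELS.index(level) < LEVELS.index(collection.level):
        raise ValueError(f"cannot refine {collection.level!r} to {level!r}")

    groups: dict = {}
    for obs in collection.observations:
        groups.setdefault(obs.key(level), set()).update(obs.species)

    out = []
    for key in sorted(groups, key=lambda k: tuple(str(x) for x in k)):
        sp = frozenset(groups[key])
        if level == "zone-year-season":
            pool, zone, year, season = key
            out.append(
                CommunityObservation(pool, zone, year, sp, season=season)
            )
        elif level == "zone-year":
            pool, zone, year = key
            out.append(CommunityObservation(pool, zone, year, sp))
        else:  # zone-pooled
            (zone,) = key
            out.append(CommunityObservation(None, zone, None, sp))
    return CommunityCollection(out, level=level)
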