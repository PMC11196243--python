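"""Pool geometry: planar area, elliptical cross-section, and water volume.

A vernal pool is surveyed with two transects (north-south and east-west)
plus the maximum standing-water depth at the pool centre.  The planar area
reported for each pool is the raw product of the two spans; the estimated
water volume treats the pool as one third of an elliptical cylinder
(``pi/4 * ns * ew`` cross-section times depth, divided by 3).  Both forms
are kept: :func:`pool_area` reproduces the reported areas bit-for-bit,
while :func:`elliptical_area` is the cross-section used inside
:func:`pool_volume`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from ._util import round_half_up

__all__ = ["PoolGeometry", "pool_area", "elliptical_area", "pool_volume"]


@dataclass
class PoolGeometry:
    """Dimensional and edaphic description of one pool.

    Parameters
    ----------
    ns_span, ew_span : float
        North-south and east-west transect lengths in metres (> 0).
    max_depth : float
        Maximum standing-water depth in metres (> 0).
    clay_bottom_pct : float
        Mean clay content of the pool bottom, percent in [0, 100].
    inundation_length : dict
        Optional ``(zone, year) -> weeks`` of standing water.
    """

    ns_span: float
    ew_span: float
    max_depth: float = 0.0
    clay_bottom_pct: float = 0.0
    inundation_length: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.ns_span <= 0 or self.ew_span <= 0:
            raise ValueError("pool spans must be positive")
        if self.max_depth < 0:
            raise ValueError("max depth cannot be negative")
        if not 0.0 <= self.clay_bottom_pct <= 100.0:
            raise ValueError("clay percentage must lie in [0, 100]")


def pool_area(g: PoolGeometry, ndigits: int | None = 2) -> float:
    """Planar area of the pool in m^2: the raw product of the two spans."""
    area = g.ns_span * g.ew_span
    return area if ndigits is None else round_half_up(area, ndigits)


def elliptical_area(g: PoolGeometry) -> float:
    """Area of the ellipse whose axes are the two spans: pi/4 * ns * ew."""
    return math.pi / 4.0 * g.ns_span * g.ew_span


def pool_volume(g: PoolGeometry, ndigits: int | None = 2) -> float:
    """Estimated water volume in m^3: elliptical cross-section x depth / 3."""
    if g.max_depth <= 0:
        raise ValueError("pool depth must be positive to estimate volume")
    vol = elliptical_area(g) * g.max_depth / 3.0
    return vol if ndigits is None else round_half_up(vol, ndigits)
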