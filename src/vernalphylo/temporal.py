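"""Seasonal phylodiversity dynamics: trends, factorial models, Mantel tests.

Weekly SES-PD within a zone is modelled by polynomial regression (degrees
1-3) with AIC selection and residual diagnostics; zone-year-season
communities feed a zone x season factorial ANOVA with Tukey contrasts;
and Mantel tests relate weekly community turnover (Jaccard) or weekly
phylodiversity differences to annual or seasonal climate distance.

Weeks are treated as independent observations, matching the standard
workflow for this design; no autocorrelation structure is modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .communities import CommunityCollection, aggregate, season_bin
from .tables import ClimateSeries
from skbio import DistanceMatrix

__all__ = [
    "PolyFit",
    "poly_trend",
    "factorial_model",
    "MantelResult",
    "mantel",
    "env_distance",
    "community_time_distance",
    "value_distance",
    "climate_matrix",
]


# ---------------------------------------------------------------------------
# polynomial trend with AIC selection
# ---------------------------------------------------------------------------

@dataclass
class PolyFit:
    """Best-AIC polynomial trend with residual diagnostics."""

    degree: int
    coefficients: np.ndarray  # ascending powers, intercept first
    aic: float
    aic_by_degree: dict
    p_value: float  # model F-test
    breusch_pagan_p: float
    shapiro_p: float
    n: int

    def predict(self, x) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(x, float),
                                                self.coefficients)


def _gaussian_aic(resid: np.ndarray, k_params: int) -> float:
    n = len(resid)
    sigma2 = float(np.sum(resid**2)) / n
    return n * np.log(2 * np.pi * sigma2) + n + 2 * k_params


def poly_trend(x, y, max_degree: int = 3) -> PolyFit:
    """Fit degree-1..max_degree polynomials and keep the lowest-AIC model.

    AIC uses the Gaussian likelihood with parameter count degree + 2
    (coefficients plus residual variance).  Breusch-Pagan and
    Shapiro-Wilk p-values are computed on the selected model's residuals.
    """
    import statsmodels.api as sm
    from statsmodels.stats.diagnostic import het_breuschpagan

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite; drop degenerate SES first")
    n = len(x)
    degrees = list(range(1, max_degree + 1))
    usable = [d for d in degrees if n >= d + 3]
    dropped = sorted(set(degrees) - set(usable))
    if not usable:
        raise ValueError(
            f"too few observations (n={n}) for any candidate degree {degrees}"
        )
    if dropped:
        raise ValueError(
            f"too few observations (n={n}) for polynomial degree(s) {dropped}"
        )

    fits = {}
    aics = {}
    for d in usable:
        X = np.vander(x, d + 1, increasing=True)
        model = sm.OLS(y, X).fit()
        fits[d] = model
        aics[d] = _gaussian_aic(model.resid, d + 2)
    best = min(usable, key=lambda d: aics[d])
    model = fits[best]
    X = np.vander(x, best + 1, increasing=True)
    bp_p = float(het_breuschpagan(model.resid, X)[1])
    sw_p = float(stats.shapiro(model.resid).pvalue)
    return PolyFit(
        degree=best,
        coefficients=np.asarray(model.params),
        aic=aics[best],
        aic_by_degree=aics,
        p_value=float(model.f_pvalue),
        breusch_pagan_p=bp_p,
        shapiro_p=sw_p,
        n=n,
    )


# ---------------------------------------------------------------------------
# zone x season factorial ANOVA
# ---------------------------------------------------------------------------

def factorial_model(df: pd.DataFrame, response: str,
                    alpha: float = 0.05) -> dict:
    """Two-way ANOVA of a community response on zone, season, and interaction.

    ``df`` has one row per zone-year-season community with columns
    ``zone``, ``season`` and ``response``.  Type-II sums of squares;
    Tukey-Kramer pairwise contrasts on the zone x season cell means.
    Missing cells are fitted around with a warning.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    data = df.dropna(subset=[response, "zone", "season"]).copy()
    if data["zone"].nunique() < 2 or data["season"].nunique() < 2:
        raise ValueError("factorial model needs >= 2 levels of zone and season")
    n_cells = data.groupby(["zone", "season"]).size()
    expected = data["zone"].nunique() * data["season"].nunique()
    if len(n_cells) < expected:
        warnings.warn(
            f"{expected - len(n_cells)} empty zone x season cell(s); "
            "model fitted without them", stacklevel=2,
        )
    data = data.rename(columns={response: "_y"})
    model = smf.ols("_y ~ C(zone) * C(season)", data=data).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    cell = data["zone"].astype(str) + ":" + data["season"].astype(str)
    tukey = pairwise_tukeyhsd(data["_y"].to_numpy(), cell.to_numpy(), alpha=alpha)
    tukey_frame = pd.DataFrame(tukey.summary().data[1:],
                               columns=tukey.summary().data[0])
    return {
        "p_zone": float(anova.loc["C(zone)", "PR(>F)"]),
        "p_season": float(anova.loc["C(season)", "PR(>F)"]),
        "p_interaction": float(anova.loc["C(zone):C(season)", "PR(>F)"]),
        "r_squared": float(model.rsquared),
        "f_ratio": float(model.fvalue),
        "n": int(model.nobs),
        "anova": anova,
        "tukey": tukey_frame,
    }


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MantelResult:
    """Mantel z and r statistics with a one-sided permutation p-value."""

    z_statistic: float
    r_statistic: float
    p_value: float
    n_permutations: int
    n: int


def mantel(dm_a: DistanceMatrix, dm_b: DistanceMatrix, n_perm: int = 999,
           seed: int | None = None,
           rng: np.random.Generator | None = None) -> MantelResult:
    """Mantel association between two distance matrices over the same labels.

    z is the sum of cross-products of corresponding off-diagonal (upper
    triangle) entries; r is the Pearson correlation of the same entries.
    The permutation p-value is one-sided for positive association,
    permuting rows and columns of the second matrix jointly.
    """
    if list(dm_a.ids) != list(dm_b.ids):
        raise ValueError("distance matrices must share labels in the same order")
    n = dm_a.shape[0]
    if n < 4:
        raise ValueError("Mantel test needs at least 4 objects")
    if rng is None:
        rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    a = dm_a.data[iu]
    b = dm_b.data[iu]
    z_obs = float(np.sum(a * b))
    r_obs = float(np.corrcoef(a, b)[0, 1])

    count = 0
    B = dm_b.data
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = B[np.ix_(perm, perm)][iu]
        if np.corrcoef(a, bp)[0, 1] >= r_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return MantelResult(z_obs, r_obs, p, n_perm, n)


# ---------------------------------------------------------------------------
# distance-matrix construction
# ---------------------------------------------------------------------------

def _season_of_date(ts: pd.Timestamp) -> str | None:
    """Season bin of a calendar day relative to the March 1 survey start."""
    start = pd.Timestamp(ts.year, 3, 1)
    offset = (ts - start).days
    if 0 <= offset < 63:
        return season_bin(offset // 7 + 1)
    return None


def _climate_groups(cs: ClimateSeries, grouping: str, variable: str) -> pd.Series:
    if variable not in ("tmean", "tmax", "precipitation"):
        raise ValueError(f"unknown climate variable {variable!r}")
    df = cs.df.copy()
    agg = "sum" if variable == "precipitation" else "mean"
    if grouping == "annual":
        # water year: Oct 1 of the previous calendar year through Sep 30
        wy = df["date"].dt.year + (df["date"].dt.month >= 10).astype(int)
        return df.groupby(wy.rename("group"))[variable].agg(agg)
    if grouping == "seasonal":
        df["season"] = df["date"].map(_season_of_date)
        df = df.dropna(subset=["season"])
        key = df["date"].dt.year.astype(str) + "-" + df["season"]
        return df.groupby(key.rename("group"))[variable].agg(agg)
    raise ValueError("grouping must be 'annual' or 'seasonal'")


def env_distance(cs: ClimateSeries, grouping: str, variable: str) -> DistanceMatrix:
    """Euclidean (1-D absolute) distance between climate aggregates.

    Temperatures are averaged and precipitation summed within each group —
    water years for ``annual``, year x 3-week spring season bins for
    ``seasonal`` — then all pairwise absolute differences are taken.
    """
    vals = _climate_groups(cs, grouping, variable)
    return value_distance(vals)


def value_distance(values: pd.Series) -> DistanceMatrix:
    """Pairwise absolute differences of a scalar per labelled unit."""
    v = values.to_numpy(dtype=float)
    mat = np.abs(v[:, None] - v[None, :])
    return DistanceMatrix(mat, ids=[str(i) for i in values.index])


def community_time_distance(collection: CommunityCollection,
                            unit: str = "weekly-pool",
                            zone: str | None = None,
                            tree=None):
    """Jaccard (and optional Faith-PD-difference) matrices over weekly units.

    ``weekly-pool`` pools the three zones of each pool each week; passing
    ``zone`` restricts to that zone's weekly communities instead.  Returns
    ``(jaccard_dm, pd_dm, meta)`` where ``pd_dm`` is the pairwise absolute
    difference of Faith's PD (``None`` when no tree is given) and ``meta``
    records pool/year/week/season per label.  Empty weekly communities are
    dropped with a warning.
    """
    from .beta import jaccard
    from .phylo import faith_pd

    if unit not in ("weekly-pool", "zone"):
        raise ValueError("unit must be 'weekly-pool' or 'zone'")
    if unit == "zone" and zone is None:
        raise ValueError("unit='zone' requires a zone")

    groups: dict = {}
    for obs in collection:
        if zone is not None and obs.zone != zone:
            continue
        key = (obs.pool, obs.year, obs.week)
        groups.setdefault(key, set()).update(obs.species)

    labels, sets, meta_rows = [], [], []
    for (pool, year, week) in sorted(groups, key=lambda k: tuple(map(str, k))):
        sp = groups[(pool, year, week)]
        if not sp:
            continue
        label = f"{pool}|{year}|w{week}"
        labels.append(label)
        sets.append(frozenset(sp))
        meta_rows.append({"label": label, "pool": pool, "year": year,
                          "week": week, "season": season_bin(week)})
    dropped = len(groups) - len(labels)
    if dropped:
        warnings.warn(f"dropped {dropped} empty weekly communit(ies)", stacklevel=2)
    if len(labels) < 2:
        raise ValueError("need at least two nonempty weekly communities")

    n = len(labels)
    jac = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            jac[i, j] = jac[j, i] = jaccard(sets[i], sets[j])
    jdm = DistanceMatrix(jac, ids=labels)

    pdm = None
    if tree is not None:
        pd_vals = pd.Series([faith_pd(s, tree) for s in sets], index=labels)
        pdm = value_distance(pd_vals)
    meta = pd.DataFrame(meta_rows).set_index("label")
    return jdm, pdm, meta


def climate_matrix(meta: pd.DataFrame, cs: ClimateSeries, grouping: str,
                   variable: str) -> DistanceMatrix:
    """Climate distance matrix expanded onto weekly community labels.

    Each weekly community inherits the aggregate of its water year
    (``annual``) or its year x season bin (``seasonal``); distances are
    absolute differences, giving a matrix aligned with the community
    matrices from :func:`community_time_distance`.
    """
    groups = _climate_groups(cs, grouping, variable)
    if grouping == "annual":
        keys = meta["year"].astype(int)
    else:
        keys = meta["year"].astype(str) + "-" + meta["season"]
    missing = sorted(set(keys) - set(groups.index))
    if missing:
        raise KeyError(f"climate series lacks group(s): {missing}")
    vals = pd.Series(groups.loc[keys].to_numpy(), index=meta.index)
    return value_distance(vals)
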