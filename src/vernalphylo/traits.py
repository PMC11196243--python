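"""Community trait moments, the competitiveness axis, and slope diagnostics.

Competition intensity in a community is summarized by community-wide
moments of two stature traits — plant height and leaf area — that track
competitive ability in vernal pool annuals.  'Competitiveness' is the
first principal component of the two community-wide means (CWM.H,
CWM.LA); an analogous axis over the community-wide variances (CWV)
separates two explanations of a competitive community: if the whole
community is competitive, CWV moves opposite to CWM along phylogenetic
structure; if one or a few dominant species drag the mean, the two move
in parallel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import TraitTable

__all__ = [
    "cwm",
    "cwv",
    "trait_moments",
    "competitiveness_pc",
    "CompetitivenessPC",
    "competition_structure_fit",
    "slope_parallelism",
]


def _member_values(community, traits: TraitTable, trait: str) -> np.ndarray:
    missing_sp = sorted(set(community) - set(traits.species))
    if missing_sp:
        raise KeyError(f"species absent from trait table: {missing_sp}")
    vals = traits.trait(trait).loc[sorted(community)]
    if vals.isna().any():
        dropped = sorted(vals.index[vals.isna()])
        warnings.warn(
            f"dropping {len(dropped)} species with missing {trait!r}: {dropped}",
            stacklevel=3,
        )
        vals = vals.dropna()
    return vals.to_numpy(dtype=float)


def cwm(community, traits: TraitTable, trait: str) -> float:
    """Community-wide mean: unweighted mean trait value over member species."""
    vals = _member_values(community, traits, trait)
    if len(vals) == 0:
        raise ValueError(f"no usable {trait!r} values in community")
    return float(vals.mean())


def cwv(community, traits: TraitTable, trait: str) -> float:
    """Community-wide variance: sample variance (n-1) over member species."""
    vals = _member_values(community, traits, trait)
    if len(vals) < 2:
        raise ValueError(f"community-wide variance needs >= 2 {trait!r} values")
    return float(vals.var(ddof=1))


def trait_moments(communities: dict, traits: TraitTable,
                  trait_names=("height", "leaf_area")) -> pd.DataFrame:
    """CWM and CWV of each trait for every community (label -> species set)."""
    rows = []
    for label, sp in communities.items():
        row: dict = {"community": label, "richness": len(sp)}
        for t in trait_names:
            row[f"cwm_{t}"] = cwm(sp, traits, t)
            row[f"cwv_{t}"] = cwv(sp, traits, t) if len(sp) >= 2 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CompetitivenessPC:
    """PC1 of two z-scored community moments, oriented by the height loading."""

    scores: pd.Series  # PC1 score per community
    loadings: pd.Series  # unit-norm loadings, height entry positive
    variance_explained: float
    which: str  # 'mean' or 'variance'


def competitiveness_pc(moments: pd.DataFrame, which: str = "mean",
                       traits=("height", "leaf_area")) -> CompetitivenessPC:
    """First principal component of the two stature moments.

    Both columns are z-scored before the decomposition (correlation PCA),
    and the axis sign is fixed so the height loading is positive — larger
    scores always mean a more competitive community.
    """
    prefix = {"mean": "cwm", "variance": "cwv"}.get(which)
    if prefix is None:
        raise ValueError("which must be 'mean' or 'variance'")
    cols = [f"{prefix}_{t}" for t in traits]
    data = moments.set_index("community")[cols].dropna()
    if len(data) < 3:
        raise ValueError("need at least 3 communities with both moments")
    X = data.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        flat = [c for c, s in zip(cols, sd) if s == 0]
        raise ValueError(f"zero variance across communities in {flat}")
    Z = (X - X.mean(axis=0)) / sd
    # 2-variable correlation PCA in closed form via SVD
    _, svals, vt = np.linalg.svd(Z, full_matrices=False)
    load = vt[0]
    if load[0] < 0:  # orient: height loads positively
        load = -load
    scores = Z @ load
    var_explained = float(svals[0] ** 2 / np.sum(svals**2))
    return CompetitivenessPC(
        scores=pd.Series(scores, index=data.index, name=f"pc_{which}"),
        loadings=pd.Series(load, index=cols),
        variance_explained=var_explained,
        which=which,
    )


def competition_structure_fit(pc_scores: pd.Series, ses_values: pd.Series):
    """OLS of the competitiveness PC on an SES metric over matched communities.

    The PC is the response and phylogenetic structure (SES MPD or MNTD)
    the predictor; a positive slope reads as competition associated with
    overdispersion, a negative slope as competition associated with
    clustering.  Returns a dict with df, F, estimate, SE, p and R^2.
    """
    import statsmodels.api as sm

    joined = pd.concat([pc_scores.rename("pc"), ses_values.rename("ses")],
                       axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 matched communities")
    model = sm.OLS(joined["pc"], sm.add_constant(joined["ses"])).fit()
    return {
        "n": int(len(joined)),
        "df": int(model.df_model),
        "df_error": int(model.df_resid),
        "f_ratio": float(model.fvalue),
        "estimate": float(model.params.iloc[1]),
        "se": float(model.bse.iloc[1]),
        "p_value": float(model.f_pvalue),
        "r_squared": float(model.rsquared),
    }


def slope_parallelism(mean_fit: dict, var_fit: dict, alpha: float = 0.05) -> str:
    """Interpret the CWM-slope / CWV-slope pair against phylogenetic structure.

    Opposite-signed significant slopes -> 'community-wide' competition
    (the whole assemblage is competitive); same-signed significant slopes
    -> 'outlier-driven' (one or a few dominants drag the mean); anything
    else is 'inconclusive'.
    """
    sig = mean_fit["p_value"] <= alpha and var_fit["p_value"] <= alpha
    if not sig:
        return "inconclusive"
    same_sign = np.sign(mean_fit["estimate"]) == np.sign(var_fit["estimate"])
    if same_sign:
        return "outlier-driven"
    return "community-wide"
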