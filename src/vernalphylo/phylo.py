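"""Phylogenetic alpha/beta diversity and tip-shuffle standardized effect sizes.

Alpha metrics over a presence set on a rooted, branch-lengthed tree:

* Faith's PD — total branch length of the minimal subtree spanning the
  community's tips (root included by default);
* MPD — mean patristic distance over all unordered member pairs,
  sensitive to tree-wide structure;
* MNTD — mean distance from each member to its nearest other member,
  sensitive to structure near the tips.

Standardized effect sizes compare the observed value to a null in which
tip labels are shuffled across the full species pool, preserving each
community's richness: SES = (obs - null mean) / null SD, with a rank
p-value; rank p <= 0.05 reads as phylogenetic clustering and >= 0.95 as
overdispersion.

Phylogenetic beta diversity between communities is the mean patristic
distance over all cross-community member pairs; UPGMA clustering of that
matrix asks whether zones of vegetation form monophyletic groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from skbio import DistanceMatrix

from .phylogeny import Phylogeny

__all__ = [
    "faith_pd",
    "mpd",
    "mntd",
    "ses",
    "SesResult",
    "phylo_beta",
    "upgma",
    "Dendrogram",
    "zones_monophyletic",
    "inundation_regression",
]


# ---------------------------------------------------------------------------
# alpha metrics
# ---------------------------------------------------------------------------

def faith_pd(community, tree: Phylogeny, include_root: bool = True) -> float:
    """Faith's phylogenetic diversity of a species set.

    With ``include_root`` (the conventional default) the spanning subtree
    is anchored at the root, so a singleton contributes its root path;
    without it, branches above the community's most recent common ancestor
    are excluded.
    """
    cmask = tree.mask_of(community)
    if cmask == 0:
        raise ValueError("community must contain at least one species")
    total = 0.0
    for length, emask in tree.edge_table():
        hit = emask & cmask
        if hit and (include_root or hit != cmask):
            total += length
    return total


def _distances(community, dm: DistanceMatrix) -> np.ndarray:
    idx = [dm.index(sp) for sp in sorted(community)]
    if len(idx) < 2:
        raise ValueError(
            "MPD/MNTD require at least two species; exclude singleton communities"
        )
    return dm.data[np.ix_(idx, idx)]


def mpd(community, dm: DistanceMatrix) -> float:
    """Mean pairwise patristic distance within a community (richness >= 2)."""
    sub = _distances(community, dm)
    k = sub.shape[0]
    return float(sub.sum() / (k * (k - 1)))


def mntd(community, dm: DistanceMatrix) -> float:
    """Mean nearest-taxon distance within a community (richness >= 2)."""
    sub = _distances(community, dm).copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


# ---------------------------------------------------------------------------
# tip-shuffle null and SES
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SesResult:
    """Observed metric, null summary, SES, rank p, and structure verdict."""

    metric: str
    observed: float
    null_mean: float
    null_sd: float
    ses: float
    rank_p: float
    n_permutations: int
    verdict: str | None  # 'clustered' | 'random' | 'overdispersed' | None
    degenerate: bool = False


def _null_subsets(n_pool: int, k: int, n_perm: int, rng) -> np.ndarray:
    """(n_perm, k) index array of uniform k-subsets of the pool.

    Shuffling tip labels uniformly maps a fixed community to a uniform
    random subset of the same richness, so the taxa-label null is sampled
    directly as subsets.
    """
    return np.argsort(rng.random((n_perm, n_pool)), axis=1)[:, :k]


def _metric_batch(metric: str, subsets: np.ndarray, data: dict) -> np.ndarray:
    if metric == "PD":
        n = data["n_pool"]
        ind = np.zeros((subsets.shape[0], n), dtype=bool)
        rows = np.repeat(np.arange(subsets.shape[0]), subsets.shape[1])
        ind[rows, subsets.ravel()] = True
        counts = ind @ data["edge_tips"].T  # members below each edge
        if data["include_root"]:
            cover = counts > 0
        else:
            cover = (counts > 0) & (counts < subsets.shape[1])
        return cover @ data["edge_lengths"]
    sub = data["D"][subsets[:, :, None], subsets[:, None, :]]
    k = subsets.shape[1]
    if metric == "MPD":
        return sub.sum(axis=(1, 2)) / (k * (k - 1))
    if metric == "MNTD":
        sub = sub + np.where(np.eye(k, dtype=bool), np.inf, 0.0)
        return sub.min(axis=2).mean(axis=1)
    raise ValueError(f"unknown metric {metric!r} (expected PD, MPD or MNTD)")


def _metric_data(tree: Phylogeny, include_root: bool) -> dict:
    edges = tree.edge_table()
    n = tree.n_tips
    lengths = np.array([l for l, _ in edges])
    tips = np.zeros((len(edges), n), dtype=bool)
    for e, (_, mask) in enumerate(edges):
        for i in range(n):
            if mask >> i & 1:
                tips[e, i] = True
    return {
        "n_pool": n,
        "edge_lengths": lengths,
        "edge_tips": tips,
        "D": tree.cophenetic().data,
        "include_root": include_root,
    }


def ses(
    metric: str,
    community,
    tree: Phylogeny,
    n_perm: int = 999,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
    include_root: bool = True,
) -> SesResult:
    """Standardized effect size of PD, MPD or MNTD under the taxa-label null.

    The null shuffles tip labels across the full species pool of the tree,
    preserving the community's richness.  ``rank_p`` is the rank of the
    observed value among observed + nulls over ``n_perm + 1``, with ties
    assigned their mid-rank; the verdict applies the two-tailed
    ``alpha`` / ``1 - alpha`` rule.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    community = sorted(community)
    k = len(community)
    data = _metric_data(tree, include_root)
    if metric == "PD":
        observed = faith_pd(community, tree, include_root=include_root)
    elif metric == "MPD":
        observed = mpd(community, tree.cophenetic())
    elif metric == "MNTD":
        observed = mntd(community, tree.cophenetic())
    else:
        raise ValueError(f"unknown metric {metric!r} (expected PD, MPD or MNTD)")

    subsets = _null_subsets(data["n_pool"], k, n_perm, rng)
    nulls = _metric_batch(metric, subsets, data)

    null_mean = float(nulls.mean())
    null_sd = float(nulls.std(ddof=1))
    # mid-rank over ties: patristic distances on ultrametric trees tie
    # heavily (one value per node depth), and one-sided tie counting
    # would bias the upper tail of the rank p
    tol = 1e-9 * max(1.0, abs(observed))
    less = int(np.sum(nulls < observed - tol))
    eq = int(np.sum(np.abs(nulls - observed) <= tol))
    rank_p = (1 + less + 0.5 * eq) / (n_perm + 1)
    if null_sd <= 1e-12 * max(1.0, abs(null_mean)):
        return SesResult(metric, observed, null_mean, 0.0, float("nan"),
                         rank_p, n_perm, None, degenerate=True)
    z = (observed - null_mean) / null_sd
    if rank_p <= alpha:
        verdict = "clustered"
    elif rank_p >= 1.0 - alpha:
        verdict = "overdispersed"
    else:
        verdict = "random"
    return SesResult(metric, observed, null_mean, null_sd, float(z),
                     rank_p, n_perm, verdict)


def ses_table(
    communities: dict,
    tree: Phylogeny,
    metrics=("PD", "MPD", "MNTD"),
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    min_richness: int = 2,
) -> pd.DataFrame:
    """SES of several metrics for many communities, one row per community.

    Communities below ``min_richness`` are skipped for MPD/MNTD (reported
    as NaN) following the convention that singleton communities carry no
    pairwise structure.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    for label, sp in communities.items():
        row: dict = {"community": label, "richness": len(sp)}
        for m in metrics:
            if m != "PD" and len(sp) < min_richness:
                row[f"ses_{m.lower()}"] = np.nan
                row[f"p_{m.lower()}"] = np.nan
                row[f"verdict_{m.lower()}"] = None
                continue
            res = ses(m, sp, tree, n_perm=n_perm, rng=rng)
            row[f"ses_{m.lower()}"] = res.ses
            row[f"p_{m.lower()}"] = res.rank_p
            row[f"verdict_{m.lower()}"] = res.verdict
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# phylogenetic beta diversity and clustering
# ---------------------------------------------------------------------------

def phylo_beta(communities: dict, dm: DistanceMatrix) -> DistanceMatrix:
    """Inter-community mean pairwise patristic distance.

    ``communities`` maps labels to nonempty species sets; entry (X, Y) is
    the mean of d(i, j) over i in X, j in Y, with a zero diagonal.
    """
    labels = list(communities)
    if len(labels) < 2:
        raise ValueError("need at least two communities")
    idx = {}
    for lab in labels:
        if not communities[lab]:
            raise ValueError(f"community {lab!r} is empty")
        idx[lab] = [dm.index(sp) for sp in sorted(communities[lab])]
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            block = dm.data[np.ix_(idx[labels[i]], idx[labels[j]])]
            out[i, j] = out[j, i] = block.mean()
    return DistanceMatrix(out, ids=[str(l) for l in labels])


@dataclass
class Dendrogram:
    """Average-linkage dendrogram with half-height (ultrametric) node heights."""

    linkage: np.ndarray  # scipy linkage matrix (heights are cluster distances)
    labels: list

    @property
    def merge_heights(self) -> np.ndarray:
        """Ultrametric leaf-to-node heights: cluster distance / 2."""
        return self.linkage[:, 2] / 2.0

    def leaf_sets(self) -> list:
        """Leaf-label set below every node, leaves included."""
        n = len(self.labels)
        sets = [frozenset([lab]) for lab in self.labels]
        for row in self.linkage:
            a, b = int(row[0]), int(row[1])
            sets.append(sets[a] | sets[b])
        return sets

    def to_newick(self) -> str:
        n = len(self.labels)
        heights = np.concatenate([np.zeros(n), self.merge_heights])
        names: list = [str(l) for l in self.labels]
        for i, row in enumerate(self.linkage):
            a, b = int(row[0]), int(row[1])
            h = heights[n + i]
            names.append(
                f"({names[a]}:{h - heights[a]:.6g},{names[b]}:{h - heights[b]:.6g})"
            )
        return names[-1] + ";"


def upgma(dm: DistanceMatrix, method: str = "average") -> Dendrogram:
    """Hierarchical clustering of a distance matrix (UPGMA by default).

    Labels are sorted before linkage so tie-breaking is deterministic and
    lexicographic.  Node heights follow the half-distance convention so
    the output is ultrametric.
    """
    order = np.argsort(np.asarray(dm.ids, dtype=object))
    ids = [dm.ids[i] for i in order]
    data = dm.data[np.ix_(order, order)]
    condensed = data[np.triu_indices(len(ids), k=1)]
    Z = hierarchy.linkage(condensed, method=method)
    return Dendrogram(Z, ids)


def zones_monophyletic(dend: Dendrogram, zone_of: dict) -> dict:
    """Whether each zone's communities form one exclusive dendrogram cluster.

    ``zone_of`` maps every leaf label to a zone.  A zone is monophyletic
    when some node's leaf set equals exactly that zone's leaves (a
    single-leaf zone is trivially monophyletic).
    """
    unmapped = [l for l in dend.labels if l not in zone_of]
    if unmapped:
        raise KeyError(f"leaves without a zone assignment: {unmapped}")
    zone_leaves: dict = {}
    for leaf, zone in zone_of.items():
        if leaf in dend.labels:
            zone_leaves.setdefault(zone, set()).add(leaf)
    node_sets = set(dend.leaf_sets())
    return {z: frozenset(ls) in node_sets for z, ls in zone_leaves.items()}


# ---------------------------------------------------------------------------
# inundation regression
# ---------------------------------------------------------------------------

def inundation_regression(df: pd.DataFrame, response: str,
                          predictor: str = "inundation") -> pd.DataFrame:
    """Per-zone OLS of phylogenetic structure on inundation length.

    ``df`` carries one row per community with columns ``zone``,
    ``predictor`` and ``response`` (an SES value).  A negative slope reads
    as habitat filtering intensifying with longer standing water.
    Returns one row per zone: df, F, estimate (slope), SE, p, R^2.
    """
    import statsmodels.api as sm

    rows = []
    for zone, grp in df.groupby("zone", sort=True):
        grp = grp.dropna(subset=[response, predictor])
        if len(grp) < 3:
            raise ValueError(f"zone {zone!r} has fewer than 3 usable communities")
        x = grp[predictor].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError(f"zone {zone!r}: predictor has zero variance")
        model = sm.OLS(grp[response].to_numpy(dtype=float), sm.add_constant(x)).fit()
        rows.append({
            "zone": zone,
            "df": int(model.df_model),
            "df_error": int(model.df_resid),
            "f_ratio": float(model.fvalue),
            "estimate": float(model.params[1]),
            "se": float(model.bse[1]),
            "p_value": float(model.f_pvalue),
            "r_squared": float(model.rsquared),
        })
    return pd.DataFrame(rows)
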