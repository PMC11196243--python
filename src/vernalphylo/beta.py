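"""Taxonomic beta diversity and the seven-class spatial/temporal framework.

Every unordered pair of zone-year communities on a pools x zones x years
design falls into exactly one comparison class according to which of pool,
zone, and year differ:

========  ====================================================
label     pattern (a vs b)
========  ====================================================
H         same zone, same year, different pool  (horizontal)
V         different zone, same pool, same year  (vertical)
HT        same zone, same pool, different year
HV        different zone, different pool, same year
HHT       same zone, different pool, different year
VT        different zone, same pool, different year
VVT       different zone, different pool, different year
========  ====================================================

Lower horizontal than vertical dissimilarity indicates that zones of
vegetation are real, taxonomically discrete community units.  Class means
are compared by one-way ANOVA with Tukey-Kramer grouping letters.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .communities import CommunityCollection, CommunityObservation

__all__ = [
    "CLASS_LABELS",
    "jaccard",
    "sorensen",
    "classify_pair",
    "enumerate_classes",
    "class_summary",
    "ComparisonPair",
    "ClassSummary",
]

#: Comparison classes in canonical report order.
CLASS_LABELS = ("H", "V", "HT", "HV", "HHT", "VT", "VVT")


def _check_sets(a, b):
    a, b = frozenset(a), frozenset(b)
    if not a and not b:
        raise ValueError("dissimilarity of two empty communities is undefined")
    if not a or not b:
        warnings.warn(
            "dissimilarity of an empty vs nonempty community set to 1", stacklevel=3
        )
    return a, b


def jaccard(a, b) -> float:
    """Jaccard dissimilarity: 1 - |intersection| / |union|."""
    a, b = _check_sets(a, b)
    if not a or not b:
        return 1.0
    return 1.0 - len(a & b) / len(a | b)


def sorensen(a, b) -> float:
    """Sorensen dissimilarity: 1 - 2|intersection| / (|a| + |b|)."""
    a, b = _check_sets(a, b)
    if not a or not b:
        return 1.0
    return 1.0 - 2.0 * len(a & b) / (len(a) + len(b))


def classify_pair(a: CommunityObservation, b: CommunityObservation) -> str:
    """Comparison class of two zone-year cells, or 'identical-cell'."""
    same_pool = a.pool == b.pool
    same_zone = a.zone == b.zone
    same_year = a.year == b.year
    key = (same_pool, same_zone, same_year)
    table = {
        (True, True, True): "identical-cell",
        (False, True, True): "H",
        (True, False, True): "V",
        (True, True, False): "HT",
        (False, False, True): "HV",
        (False, True, False): "HHT",
        (True, False, False): "VT",
        (False, False, False): "VVT",
    }
    return table[key]


@dataclass(frozen=True)
class ComparisonPair:
    """A classified unordered pair of zone-year communities."""

    obs_a: CommunityObservation
    obs_b: CommunityObservation
    class_label: str
    jaccard: float
    sorensen: float


def enumerate_classes(collection: CommunityCollection) -> list:
    """Classify every unordered pair of distinct zone-year cells.

    On a full P pools x Z zones x Y years design the class sizes follow
    closed forms (e.g. H = Z*Y*C(P,2)); on the 3x3x3 design they are
    27/27/27/54/54/54/108 summing to C(27,2) = 351.  Input must be at the
    zone-year grain.
    """
    if collection.level != "zone-year":
        raise ValueError(
            f"comparison classes are defined over zone-year communities, "
            f"got level {collection.level!r}"
        )
    pairs = []
    for a, b in itertools.combinations(collection.observations, 2):
        label = classify_pair(a, b)
        if label == "identical-cell":
            continue
        pairs.append(
            ComparisonPair(a, b, label, jaccard(a.species, b.species),
                           sorensen(a.species, b.species))
        )
    return pairs


def pairs_to_frame(pairs) -> pd.DataFrame:
    """Audit table: one row per classified pair with both dissimilarities."""
    return pd.DataFrame(
        [
            {
                "pool_a": p.obs_a.pool, "zone_a": p.obs_a.zone, "year_a": p.obs_a.year,
                "pool_b": p.obs_b.pool, "zone_b": p.obs_b.zone, "year_b": p.obs_b.year,
                "class": p.class_label,
                "jaccard": p.jaccard,
                "sorensen": p.sorensen,
            }
            for p in pairs
        ]
    )


@dataclass
class ClassSummary:
    """Per-class summary plus the one-way ANOVA over classes."""

    table: pd.DataFrame  # class, n, mean, se, letter
    metric: str
    f_statistic: float
    df: tuple
    p_value: float


def class_summary(pairs, metric: str = "jaccard", alpha: float = 0.05,
                  on_ranks: bool = False) -> ClassSummary:
    """Class means, standard errors, ANOVA, and Tukey-Kramer letters.

    ``on_ranks=True`` rank-transforms the dissimilarities before the Tukey
    step (a nonparametric variant); the default works on raw values.
    Classes with no pairs are omitted with a warning.
    """
    values: dict = {}
    for p in pairs:
        values.setdefault(p.class_label, []).append(getattr(p, metric))
    empty = [c for c in CLASS_LABELS if c not in values]
    if empty:
        warnings.warn(f"comparison classes with no pairs omitted: {empty}",
                      stacklevel=2)
    classes = [c for c in CLASS_LABELS if c in values]
    if len(classes) < 2:
        raise ValueError("need at least two populated comparison classes")

    groups = [np.asarray(values[c], dtype=float) for c in classes]
    all_vals = np.concatenate(groups)
    labels = np.concatenate([[c] * len(g) for c, g in zip(classes, groups)])

    if np.ptp(all_vals) == 0:
        f_stat, p_val = 0.0, 1.0
        letters = {c: "A" for c in classes}
    else:
        f_stat, p_val = stats.f_oneway(*groups)
        tukey_vals = stats.rankdata(all_vals) if on_ranks else all_vals
        letters = _tukey_letters(tukey_vals, labels, classes, alpha)

    rows = []
    for c, g in zip(classes, groups):
        se = float(np.std(g, ddof=1) / np.sqrt(len(g))) if len(g) > 1 else np.nan
        rows.append({"class": c, "n": len(g), "mean": float(np.mean(g)),
                     "se": se, "tukey_group": letters[c]})
    dof = (len(classes) - 1, len(all_vals) - len(classes))
    return ClassSummary(pd.DataFrame(rows), metric, float(f_stat), dof, float(p_val))


def _tukey_letters(values, labels, classes, alpha) -> dict:
    """Compact letter display from Tukey-Kramer pairwise tests.

    Insert-and-absorb: start with one letter covering all groups, split it
    on each significantly different pair, drop subsets, then assign letters
    in descending order of group mean.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    different = set()
    for _, row in frame.iterrows():
        if bool(row["reject"]):
            different.add(frozenset((str(row["group1"]), str(row["group2"]))))

    letter_sets = [set(classes)]
    for pair in different:
        g1, g2 = tuple(pair)
        for s in [s for s in letter_sets if g1 in s and g2 in s]:
            letter_sets.remove(s)
            letter_sets.extend([s - {g1}, s - {g2}])
        # absorb subsets
        letter_sets = [
            s for s in letter_sets
            if s and not any(s < t for t in letter_sets)
        ]
    # deduplicate identical sets
    uniq = []
    for s in letter_sets:
        if s not in uniq:
            uniq.append(s)

    means = {c: np.mean(values[labels == c]) for c in classes}
    uniq.sort(key=lambda s: -max(means[c] for c in s))
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    out: dict = {c: "" for c in classes}
    for letter, s in zip(alphabet, uniq):
        for c in classes:
            if c in s:
                out[c] += letter
    return out
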