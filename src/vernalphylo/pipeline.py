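"""Config-driven end-to-end analysis of a vernal pool study folder.

``run_all`` takes either a data folder (communities, traits, tree,
climate, inundation CSV/newick) or a synthetic-study configuration and
reproduces the full report suite: species accounting, the seven-class
beta-diversity summary, per-zone SES of PD/MPD/MNTD with and without
invasives, inundation regressions, competitiveness fits with the
slope-parallelism diagnostic, zone x season factorial models, trait-PD
regressions, phylogenetic-beta dendrograms, weekly SES-PD trends, and the
Mantel suite against climate distance.  A manifest captures the seed,
permutation count, and every analysis flag so a run can be repeated
bit-for-bit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._util import round_half_up, substream
from .beta import class_summary, enumerate_classes, pairs_to_frame
from .communities import SEASONS, ZONES, CommunityCollection, aggregate
from .phylo import (
    Dendrogram,
    faith_pd,
    inundation_regression,
    mntd,
    mpd,
    phylo_beta,
    ses_table,
    upgma,
    zones_monophyletic,
)
from .simulate import SimulationConfig, SyntheticDataset, simulate_dataset
from .tables import ClimateSeries, TraitTable
from .temporal import (
    climate_matrix,
    community_time_distance,
    factorial_model,
    mantel,
    poly_trend,
    value_distance,
)
from .traits import (
    competition_structure_fit,
    competitiveness_pc,
    slope_parallelism,
    trait_moments,
)

__all__ = ["RunConfig", "run_all", "species_summary", "load_study"]


@dataclass
class RunConfig:
    """One of ``data_dir`` / ``synthetic`` selects the input; the rest tune analyses."""

    data_dir: str | None = None
    synthetic: SimulationConfig | None = None
    n_permutations: int = 999
    alpha: float = 0.05
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self):
        if (self.data_dir is None) == (self.synthetic is None):
            raise ValueError("provide exactly one of data_dir or synthetic")
        if self.n_permutations < 99:
            raise ValueError("n_permutations must be >= 99")


def load_study(data_dir) -> SyntheticDataset:
    """Read a study folder written by :func:`vernalphylo.simulate.write_dataset`.

    The same layout serves deposited field data: communities.csv,
    traits.csv, tree.nwk, climate.csv, and optionally inundation.csv.
    """
    from . import io as vio

    d = Path(data_dir)
    communities = vio.read_community_long(d / "communities.csv")
    traits = vio.read_traits(d / "traits.csv")
    tree = vio.read_newick(d / "tree.nwk")
    climate = (
        vio.read_climate(d / "climate.csv") if (d / "climate.csv").exists() else None
    )
    inund = (
        pd.read_csv(d / "inundation.csv")
        if (d / "inundation.csv").exists()
        else pd.DataFrame(columns=["pool", "zone", "year", "inundation_weeks"])
    )
    return SyntheticDataset(None, tree, traits, communities, climate, inund)


def species_summary(traits, collection: CommunityCollection | None = None) -> dict:
    """Total / native / invasive species counts and per-zone richness.

    ``traits`` is a TraitTable or a DataFrame with a boolean ``native``
    column (and optionally a ``zones`` set column).  When observations are
    given, every observed species must be present in the table and
    per-zone richness is counted from the observations; a species seen in
    several zones counts once per zone but once in the totals.
    """
    df = traits.df if isinstance(traits, TraitTable) else traits
    if "species" in df.columns:
        df = df.set_index("species")
    native = df["native"].astype(bool)
    out = {
        "n_species": int(len(df)),
        "n_native": int(native.sum()),
        "n_invasive": int((~native).sum()),
    }
    zone_sets: dict = {z: set() for z in ZONES}
    if collection is not None:
        missing = sorted(collection.species_pool - set(df.index))
        if missing:
            raise KeyError(f"observed species missing from the table: {missing}")
        for obs in collection:
            zone_sets[obs.zone] |= obs.species
    elif "zones" in df.columns:
        for sp, zones in df["zones"].items():
            for z in zones:
                zone_sets[z].add(sp)
    out["richness_per_zone"] = {z: len(zone_sets[z]) for z in ZONES}
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _zone_season_frame(ds, zys: CommunityCollection, n_perm, rng) -> pd.DataFrame:
    """Per zone-year-season community: richness, SES metrics, CWMs, inundation."""
    comm = {
        (o.pool, o.zone, o.year, o.season): set(o.species) for o in zys
    }
    stab = ses_table(comm, ds.tree, n_perm=n_perm, rng=rng)
    meta = pd.DataFrame(
        [
            {"community": k, "pool": k[0], "zone": k[1], "year": k[2], "season": k[3]}
            for k in comm
        ]
    )
    out = meta.merge(stab, on="community")
    moments = trait_moments(comm, ds.traits)
    out = out.merge(moments.drop(columns="richness"), on="community")
    out["pd_faith"] = [faith_pd(comm[k], ds.tree) for k in out["community"]]
    if len(ds.inundation):
        inun = ds.inundation.set_index(["pool", "zone", "year"])["inundation_weeks"]
        out["inundation"] = [
            inun.get((p, z, y), np.nan)
            for p, z, y in zip(out["pool"], out["zone"], out["year"])
        ]
    else:
        out["inundation"] = np.nan
    return out


def _table5(ds, n_perm, rng) -> pd.DataFrame:
    """Zone-pooled SES MNTD / MPD, with and then without invasive species."""
    rows = []
    for label, keep in (("all", None), ("no-invasives", ds.traits.natives)):
        if keep is None:
            coll, tree = ds.communities, ds.tree
        else:
            coll = ds.communities.subset(keep)
            tree = ds.tree.retain(sorted(set(keep) & set(ds.tree.tip_labels)))
        pooled = aggregate(coll, "zone-pooled")
        comm = {o.zone: set(o.species) for o in pooled}
        tab = ses_table(comm, tree, metrics=("MNTD", "MPD"), n_perm=n_perm, rng=rng)
        tab.insert(0, "species_set", label)
        tab = tab.rename(columns={"community": "zone"})
        tab["tree_wide"] = [
            {"clustered": "Clustered", "overdispersed": "Over-Dispersed",
             "random": "Random", None: "Random"}[v]
            for v in tab["verdict_mpd"]
        ]
        rows.append(tab)
    return pd.concat(rows, ignore_index=True)


def _table7(zs_frame: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Competitiveness PC vs SES MNTD / MPD per zone, plus parallelism calls."""
    rows = []
    for zone, grp in zs_frame.groupby("zone", sort=True):
        grp = grp.set_index("community")
        moments = grp.reset_index()[
            ["community", "richness", "cwm_height", "cwm_leaf_area",
             "cwv_height", "cwv_leaf_area"]
        ]
        pcs = {
            "PC Mean": competitiveness_pc(moments, "mean"),
            "PC Variance": competitiveness_pc(moments, "variance"),
        }
        for metric in ("mntd", "mpd"):
            fits = {}
            for resp, pc in pcs.items():
                fit = competition_structure_fit(pc.scores, grp[f"ses_{metric}"])
                fits[resp] = fit
                rows.append({
                    "phylo_variable": f"SES {metric.upper()}",
                    "zone": zone,
                    "response": resp,
                    **{k: fit[k] for k in
                       ("df", "df_error", "f_ratio", "estimate", "se",
                        "p_value", "r_squared")},
                })
            rows[-2]["parallelism"] = rows[-1]["parallelism"] = slope_parallelism(
                fits["PC Mean"], fits["PC Variance"], alpha=alpha
            )
    return pd.DataFrame(rows)


def _table8(zs_frame: pd.DataFrame, alpha: float) -> pd.DataFrame:
    responses = {
        "SES PD": "ses_pd", "SES MNTD": "ses_mntd", "SES MPD": "ses_mpd",
        "Richness": "richness", "Height": "cwm_height",
        "Leaf Area": "cwm_leaf_area",
    }
    rows = []
    for name, col in responses.items():
        if col not in zs_frame.columns:
            continue
        res = factorial_model(zs_frame, col, alpha=alpha)
        rows.append({
            "response": name, "p_zone": res["p_zone"], "p_season": res["p_season"],
            "p_interaction": res["p_interaction"], "r_squared": res["r_squared"],
            "n": res["n"], "f_ratio": res["f_ratio"],
        })
    return pd.DataFrame(rows)


def _table9(zs_frame: pd.DataFrame) -> pd.DataFrame:
    """OLS of community-wide trait means on Faith's PD, per zone and pool-wide."""
    import statsmodels.api as sm

    traits = [c for c in zs_frame.columns if c.startswith("cwm_")]
    rows = []
    scopes = [("Whole Pool", zs_frame)] + [
        (z, g) for z, g in zs_frame.groupby("zone", sort=True)
    ]
    for trait in traits:
        for scope, grp in scopes:
            grp = grp.dropna(subset=[trait, "pd_faith"])
            if len(grp) < 4 or np.ptp(grp["pd_faith"].to_numpy()) == 0:
                continue
            model = sm.OLS(
                grp[trait].to_numpy(dtype=float),
                sm.add_constant(grp["pd_faith"].to_numpy(dtype=float)),
            ).fit()
            rows.append({
                "trait": trait.removeprefix("cwm_"), "scope": scope,
                "df": int(model.df_resid), "estimate": float(model.params[1]),
                "se": float(model.bse[1]), "p_value": float(model.f_pvalue),
                "r_squared": float(model.rsquared),
            })
    return pd.DataFrame(rows)


def _mantel_suite(ds, n_perm, rng) -> pd.DataFrame:
    """Mantel tests of turnover / PD / MNTD / MPD distance vs climate distance."""
    coph = ds.tree.cophenetic()
    rows = []
    units = [("Pool Wide", None)] + [(z.capitalize(), z) for z in ZONES]
    for unit_name, zone in units:
        unit = "zone" if zone else "weekly-pool"
        jdm, pdm, meta = community_time_distance(
            ds.communities, unit=unit, zone=zone, tree=ds.tree
        )
        groups: dict = {}
        for obs in ds.communities:
            if zone is not None and obs.zone != zone:
                continue
            groups.setdefault((obs.pool, obs.year, obs.week), set()).update(obs.species)
        rich_ok = [lab for lab in meta.index
                   if len(groups[(meta.loc[lab, "pool"], meta.loc[lab, "year"],
                                  meta.loc[lab, "week"])]) >= 2]
        mets = {"Turnover": jdm, "PD": pdm}
        if len(rich_ok) >= 4:
            vals_mntd = pd.Series(
                [mntd(groups[(meta.loc[l, "pool"], meta.loc[l, "year"],
                              meta.loc[l, "week"])], coph) for l in rich_ok],
                index=rich_ok)
            vals_mpd = pd.Series(
                [mpd(groups[(meta.loc[l, "pool"], meta.loc[l, "year"],
                             meta.loc[l, "week"])], coph) for l in rich_ok],
                index=rich_ok)
            mets["MNTD"] = value_distance(vals_mntd)
            mets["MPD"] = value_distance(vals_mpd)
        for grouping in ("annual", "seasonal"):
            for var in ("tmax", "tmean", "precipitation"):
                env_full = climate_matrix(meta, ds.climate, grouping, var)
                for met_name, dm in mets.items():
                    env = (env_full if list(dm.ids) == list(env_full.ids)
                           else env_full.filter(dm.ids))
                    res = mantel(dm, env, n_perm=n_perm, rng=rng)
                    rows.append({
                        "unit": unit_name,
                        "environment": f"{grouping} {var}",
                        "metric": met_name,
                        "z_statistic": res.z_statistic,
                        "r_statistic": res.r_statistic,
                        "p_value": res.p_value,
                    })
    return pd.DataFrame(rows)


def _dendrograms(ds) -> dict:
    """Zone-year and zone-pool phylogenetic beta dendrograms + monophyly calls."""
    coph = ds.tree.cophenetic()
    out = {}
    zy = {}
    for obs in ds.communities:
        zy.setdefault(f"{obs.zone}-{obs.year}", set()).update(obs.species)
    dm = phylo_beta(zy, coph)
    dend = upgma(dm)
    out["zone_year"] = {
        "dendrogram": dend,
        "newick": dend.to_newick(),
        "zones_monophyletic": zones_monophyletic(
            dend, {lab: lab.rsplit("-", 1)[0] for lab in dend.labels}
        ),
    }
    zp = {}
    for obs in ds.communities:
        zp.setdefault(f"{obs.zone}-{obs.pool}", set()).update(obs.species)
    dend2 = upgma(phylo_beta(zp, coph))
    out["zone_pool"] = {"dendrogram": dend2, "newick": dend2.to_newick()}
    return out


def _weekly_trends(ds, n_perm, rng) -> dict:
    """Per-zone polynomial trend of weekly SES PD with AIC selection."""
    comm: dict = {}
    for obs in ds.communities:
        comm[(obs.zone, obs.pool, obs.year, obs.week)] = set(obs.species)
    stab = ses_table(comm, ds.tree, metrics=("PD",), n_perm=n_perm, rng=rng)
    stab["zone"] = [k[0] for k in stab["community"]]
    stab["week"] = [k[3] for k in stab["community"]]
    # singletons have degenerate SES PD on an ultrametric tree (every
    # root path equals the depth); they carry no trend information
    stab = stab.dropna(subset=["ses_pd"])
    fits = {}
    for zone, grp in stab.groupby("zone", sort=True):
        fits[zone] = poly_trend(grp["week"].to_numpy(dtype=float),
                                grp["ses_pd"].to_numpy(dtype=float))
    return {"points": stab, "fits": fits}


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_all(cfg: RunConfig) -> dict:
    """Run every analysis stage; return (and optionally write) the bundle."""
    if cfg.synthetic is not None:
        ds = simulate_dataset(cfg.synthetic)
    else:
        ds = load_study(cfg.data_dir)
    n_perm = cfg.n_permutations
    rng_null = substream(cfg.seed, "null-models")
    rng_mantel = substream(cfg.seed, "mantel")

    bundle: dict = {}
    bundle["species_summary"] = species_summary(ds.traits, ds.communities)

    zy = aggregate(ds.communities, "zone-year")
    pairs = enumerate_classes(zy)
    bundle["pairs"] = pairs_to_frame(pairs)
    summaries = []
    for metric in ("jaccard", "sorensen"):
        s = class_summary(pairs, metric=metric, alpha=cfg.alpha)
        t = s.table.copy()
        t.insert(0, "metric", metric)
        t["anova_f"] = s.f_statistic
        t["anova_p"] = s.p_value
        summaries.append(t)
    bundle["class_summary"] = pd.concat(summaries, ignore_index=True)

    bundle["ses_by_zone"] = _table5(ds, n_perm, rng_null)

    zys = aggregate(ds.communities, "zone-year-season")
    zs_frame = _zone_season_frame(ds, zys, n_perm, rng_null)
    bundle["zone_season_communities"] = zs_frame

    flooded = zs_frame[zs_frame["zone"].isin(["bottom", "edge"])]
    inun_rows = []
    for resp in ("ses_mntd", "ses_mpd"):
        t = inundation_regression(flooded.dropna(subset=["inundation"]),
                                  response=resp)
        t.insert(0, "phylo_variable", resp.replace("ses_", "SES ").upper())
        inun_rows.append(t)
    bundle["inundation_regression"] = pd.concat(inun_rows, ignore_index=True)

    bundle["competition"] = _table7(zs_frame, cfg.alpha)
    bundle["factorial"] = _table8(zs_frame, cfg.alpha)
    bundle["trait_pd_regression"] = _table9(zs_frame)
    if ds.climate is not None:
        bundle["mantel"] = _mantel_suite(ds, n_perm, rng_mantel)
    bundle["dendrograms"] = _dendrograms(ds)
    bundle["weekly_trends"] = _weekly_trends(ds, n_perm, rng_null)

    bundle["manifest"] = {
        "version": __version__,
        "seed": cfg.seed,
        "n_permutations": n_perm,
        "alpha": cfg.alpha,
        "input": cfg.data_dir or "synthetic",
        "synthetic_config": (
            None if cfg.synthetic is None
            else {k: (list(v) if isinstance(v, tuple) else v)
                  for k, v in vars(cfg.synthetic).items()}
        ),
        "flags": {
            "faith_pd_include_root": True,
            "null_model": "taxa-label shuffle over the full pool",
            "linkage": "average (UPGMA), half-height convention",
            "tukey": "Tukey-Kramer on raw values",
            "pca": "correlation (z-scored) PCA of CWM/CWV height + leaf area",
            "phylo_time_matrix": "absolute Faith-PD difference between weeks",
            "anova_type": "type II",
        },
    }

    if cfg.outdir is not None:
        _write_bundle(bundle, cfg.outdir)
    return bundle


def _write_bundle(bundle: dict, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "species_summary": None,  # json
        "pairs": "pairs.csv",
        "class_summary": "class_summary.csv",
        "ses_by_zone": "ses_by_zone.csv",
        "zone_season_communities": "zone_season_communities.csv",
        "inundation_regression": "inundation_regression.csv",
        "competition": "competition.csv",
        "factorial": "factorial.csv",
        "trait_pd_regression": "trait_pd_regression.csv",
    }
    for key, fname in tables.items():
        if fname and key in bundle:
            df = bundle[key].copy()
            num = df.select_dtypes(include=[float]).columns
            df[num] = df[num].map(lambda x: round_half_up(x, 4) if pd.notna(x) else x)
            df.to_csv(out / fname, index=False)
    if "mantel" in bundle:
        bundle["mantel"].to_csv(out / "mantel.csv", index=False)
    (out / "species_summary.json").write_text(
        json.dumps(bundle["species_summary"], indent=2) + "\n")
    for name, d in bundle["dendrograms"].items():
        (out / f"dendrogram_{name}.nwk").write_text(d["newick"] + "\n")
    trend = bundle["weekly_trends"]
    pts = trend["points"].copy()
    pts["community"] = pts["community"].map(lambda k: "|".join(map(str, k)))
    pts.to_csv(out / "weekly_ses_pd.csv", index=False)
    fitrows = [
        {"zone": z, "degree": f.degree, "aic": f.aic, "p_value": f.p_value,
         "breusch_pagan_p": f.breusch_pagan_p, "shapiro_p": f.shapiro_p, "n": f.n}
        for z, f in trend["fits"].items()
    ]
    pd.DataFrame(fitrows).to_csv(out / "weekly_trend_fits.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(bundle["manifest"], indent=2) + "\n")
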