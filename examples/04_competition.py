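"""Competitiveness and phylogenetic structure in the upland grassland.

Builds the competitiveness axis (PC1 of community-wide mean height and
leaf area), regresses it on SES MNTD for upland communities, and applies
the slope-parallelism rule to the CWM and CWV axes.  Removing the
invasive clade shows whether invasion drives the pattern.
"""

import warnings

warnings.filterwarnings("ignore")

from vernalphylo import aggregate, ses_table
from vernalphylo._util import substream
from vernalphylo.simulate import SimulationConfig, simulate_dataset
from vernalphylo.traits import (
    competition_structure_fit,
    competitiveness_pc,
    slope_parallelism,
    trait_moments,
)

ds = simulate_dataset(SimulationConfig(seed=2005, invasive_trait_boost=4.0))

for label, keep in (("with invasives", None), ("natives only", ds.traits.natives)):
    coll = ds.communities if keep is None else ds.communities.subset(keep)
    tree = ds.tree if keep is None else ds.tree.retain(
        sorted(set(keep) & set(ds.tree.tip_labels)))
    comm = {
        (o.pool, o.year, o.season): set(o.species)
        for o in aggregate(coll, "zone-year-season")
        if o.zone == "upland" and len(o.species) >= 2
    }
    stab = ses_table(comm, tree, metrics=("MNTD",), n_perm=199,
                     rng=substream(0, "null")).set_index("community")
    moments = trait_moments(comm, ds.traits)
    fits = {}
    for which in ("mean", "variance"):
        pc = competitiveness_pc(moments, which)
        fits[which] = competition_structure_fit(pc.scores, stab["ses_mntd"])
    call = slope_parallelism(fits["mean"], fits["variance"])
    print(f"{label}: CWM slope {fits['mean']['estimate']:+.2f} "
          f"(p={fits['mean']['p_value']:.4f}), CWV slope "
          f"{fits['variance']['estimate']:+.2f} "
          f"(p={fits['variance']['p_value']:.4f}) -> {call}")
# A significant negative CWM slope with invasives present — competitive
# communities are phylogenetically clustered — that vanishes on the
# native subset indicates invasion-driven clustering.
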