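# Methods

This note documents the models, defaults, and numerical conventions behind
`vernalphylo`, and what the synthetic generator does and does not emulate.

## Community units and aggregation

The sampling unit is a weekly flowering-presence census of one vegetation
zone (bottom / edge / upland) of one pool. Coarser units are set unions of
weekly censuses: zone-year-season (≤ 81 cells on a 3×3×3 design with three
3-week season bins), zone-year (27 cells), and zone pooled across pools and
years. The seven comparison classes are defined over zone-year communities —
the only unit whose pair counts (27/27/27/54/54/54/108, total C(27,2))
match the closed forms `H = Z·Y·C(P,2)`, `V = P·Y·C(Z,2)`, `HT = P·Z·C(Y,2)`,
`HV = 2·Y·C(P,2)·C(Z,2)`, `HHT = 2·Z·C(P,2)·C(Y,2)`, `VT = 2·P·C(Z,2)·C(Y,2)`,
`VVT = 4·C(P,2)·C(Z,2)·C(Y,2)`. Weeks are 1-based ordinals from the March 1
survey start; seasons are weeks 1–3 / 4–6 / 7–9, and years whose flowering
season ended early simply leave the late bin partially filled — they are
never padded. Zone labels are lowercased and stripped, with single-letter
codes B/E/U accepted; canonical order is bottom < edge < upland.

## Pool geometry

Reported pool areas equal the raw product of the north–south and east–west
transect spans, while the water-volume estimate uses the elliptical
cross-section: `V = (π/4 · ns · ew · depth) / 3`. Both forms are kept —
`pool_area` returns the span product so the dimension table is reproduced
bit-for-bit, and the elliptical form is a separate helper used only inside
`pool_volume`. Report tables round half-up at 2 decimals at write time;
internal computation is full precision.

## Phylogenetic metrics and the null model

Faith's PD sums branch lengths of the minimal subtree spanning a community's
tips; root inclusion is on by default (the convention of the standard
community-phylogenetics toolchain) and only affects singletons and the
subtree above the MRCA. MPD and MNTD use patristic distances; communities
with richness < 2 are excluded from MPD/MNTD analyses and reported as NaN.

The null model shuffles tip labels across the full observed species pool,
which is equivalent to drawing uniform random subsets at the observed
richness; nulls are therefore sampled directly as subsets and evaluated
vectorized. SES uses the sample standard deviation of the 999 null values
(999 by default everywhere; calibration experiments use 199 for speed).

The rank p-value assigns tied values their mid-rank. This matters:
ultrametric trees carry one distinct patristic value per node depth, so
exact ties among null MPD/MNTD values are common, and one-sided tie
counting demonstrably inflates the upper tail of the null rank distribution
(measured ≈ 0.075 instead of 0.055 at the .95 cut on 42-tip trees).
With mid-ranks both tails sit at their nominal rate. Degenerate nulls
(sd ≈ 0, e.g. the full species pool, or singleton PD on an ultrametric tree
where every root path equals the depth) are flagged and excluded from
verdicts rather than given an SES.

Phylogenetic beta diversity between communities is the mean patristic
distance over all cross-community member pairs (self-pairs included when
the communities share species). Hierarchical clustering defaults to UPGMA
(average linkage is the conventional reading of "hierarchical clustering"
in this workflow; complete linkage is available via the `method` argument).
Node heights follow the half-distance convention so dendrograms are
ultrametric; labels are sorted before linkage so tie-breaking is
deterministic and lexicographic. A zone is called monophyletic when some
node's leaf set equals exactly that zone's leaves.

## Beta-diversity summaries

Jaccard and Sørensen dissimilarities obey `J = 2S/(1+S)`; this identity is a
standing property test. The dissimilarity of an empty versus nonempty
community is defined as 1 with a warning. Class summaries report raw means
and standard errors (labelled as such; no least-squares adjustment is
applied) with a one-way ANOVA and Tukey–Kramer letters computed by
insert-and-absorb from the pairwise tests. Because "nonparametric Tukey" is
not a standard procedure, the default is Tukey–Kramer on raw dissimilarities
with a rank-transform variant behind `on_ranks=True`.

## Traits and competitiveness

CWM is the unweighted mean trait value over member species (the study
recorded presence, not abundance); CWV is the sample variance (n−1).
Species with a missing trait value are dropped from that trait's moment
with a warning — never silently imputed. The competitiveness axis is the
first principal component of the two stature moments after z-scoring
(correlation PCA; the covariance choice is not identifiable from the
workflow this mirrors, and z-scoring makes the axis unit-free). The sign is
fixed so the height loading is positive. The structure fit regresses the PC
(response) on SES MNTD or MPD (predictor); since only sign and significance
are interpreted, the orientation does not change conclusions, and R² is
orientation-symmetric. The slope-parallelism rule at α = 0.05: opposite
significant CWM/CWV slopes → community-wide competition; same-signed
significant slopes → outlier-driven; otherwise inconclusive.

## Temporal machinery

Polynomial trends of weekly SES-PD use OLS on degrees 1–3 with Gaussian AIC
(`n·log(2πσ̂²) + n + 2k`, k = degree + 2 counting the residual variance);
the lowest-AIC model is kept and Breusch–Pagan / Shapiro–Wilk p-values are
computed on its residuals. Weeks are treated as independent observations —
no autocorrelation structure is modelled, a deliberate simplification
matching the standard workflow for this design.

The factorial model is a type-II two-way ANOVA with interaction on
zone-year-season communities, with Tukey–Kramer contrasts on the zone ×
season cell means; empty cells are fitted around with a warning.

The Mantel statistic is `z = Σ_{i<j} a_ij·b_ij` with `r` the Pearson
correlation of the same entries; the permutation p is one-sided for
positive association, permuting rows and columns of the second matrix
jointly (999 permutations). Climate distance matrices aggregate daily
series per water year (October 1 – September 30, for "annual") or per
year × season bin ("seasonal") — means for temperatures, sums for
precipitation — then take absolute differences. The phylogenetic analogue
of community turnover over time is the absolute difference in Faith's PD
between time points: a square matrix over weekly communities requires a
scalar per community, and PD is that scalar. This is an interpretation
(flagged in the API docstring), as is the analogous |Δ| construction for
MPD and MNTD.

## The synthetic generator

The generator's defaults are the study conditions: 42 species, 3 pools ×
3 zones × 3 years, weekly censuses with survey lengths (7, 8, 9) weeks
emulating truncated field seasons, and per-zone pooled richness in the
9–25 band.

*Tree.* Pure-birth (Yule), strictly binary, scaled to depth 1.

*Tolerance.* The latent inundation-tolerance axis evolves under an
early-burst Brownian clock (rate ∝ `exp(−burst·t)`, default burst 3) plus a
planted shift of +2 (before standardization) on one randomly chosen
16-species clade — a single deep origin of flooding adaptation, the pattern
documented for vernal pool lineages, which makes tolerance reliably
clade-structured rather than leaving clade separation to the luck of one
Brownian draw. Morphological traits (height, leaf area, seed mass,
inflorescence size) evolve by ordinary Brownian motion on the log scale
around field-realistic bases.

*Assembly.* Two-stage: species *s* enters the regional pool of zone *z*
with probability `exp(−a_z (tol_s − opt_z)²)` on the standardized tolerance
scale (optima +1 / 0 / −1 for bottom / edge / upland; default strengths
2 / 1 / 1), times an invasion bias weight (0.15 / 0.4 / 1.0) when *s* is
invasive; each regional member then occupies a pool-year with probability
0.85. The two stages give zones regional fidelity across pools and years —
the property that makes horizontal beta diversity low — while standardizing
tolerance keeps realized zone sizes stable across tree realizations.

*Invasion.* The invasive set is the descendants of one internal node
(default six species), preferring the shallowest qualifying clade — the
shape of a recent radiation such as the Eurasian annual grasses — chosen
disjoint from the wetland clade. Invasives get a ×2 competitive boost to
height and leaf area (×4 in the planted-competition experiments) and flower
late (start weeks 5–7, 3–5 week duration), as invasive grasses do in the
field; natives draw start weeks 1–7 and durations 1–5 weeks, with ±2 weeks
of independent per-pool-year phenological jitter.

*Climate.* Sinusoidal daily temperature (mean 17 °C, amplitude 9 °C, noise
1.5 °C) with `tmin ≤ tmean ≤ tmax` enforced by construction;
winter-concentrated precipitation scaled exactly to per-water-year totals
(drawn in 150–500 mm when not given). Inundation lengths are drawn
directly per zone-year (bottom ≈ 8 weeks, edge ≈ 4, upland 0) — no
hydrological model.

With all filter strengths zero and no invasion bias
(`SimulationConfig.neutral()`), species presences are i.i.d. across the
pool, so communities conditioned on richness are uniform random subsets —
the exact case in which SES ranks are uniform. This is the type-I
calibration condition.

What the generator does **not** emulate: abundance (presence only),
observation error and detectability, a seed bank or dispersal limitation,
hydrological coupling between climate and inundation, and trait–phenology
correlations beyond the invasive shift. Tests passing on synthetic data
therefore certify the statistical machinery and the direction of planted
effects, not field realism.

## Experiment sizes

The recovery and calibration experiments are sized to be decisive yet
quick: null calibration uses 24 neutral studies (~5,000 weekly communities,
199 permutations each); habitat-filter recovery uses 50 replicate studies
with bottom filter strength 10 (the bottom then pools 5–10 flood-tolerant
species and is called "clustered" by SES-MPD in well over 80% of
replicates); the invasion experiment uses 25 replicate studies with the ×4
competitive boost. All seeds are fixed; every stochastic stage draws from a
named substream of one root seed, so reruns are bit-identical.

## Known limitations

- The tip-shuffle null uses the full observed pool only; per-zone null
  pools are out of scope.
- Presence/absence only; no abundance-weighted metrics, no UniFrac.
- LS-means are not computed; class summaries report raw means.
- The |ΔPD| time-distance matrix is one defensible construction of a
  square phylodiversity distance over weeks, not the only one.
- Ordination (NMDS) is not implemented; the exported pair/dissimilarity
  tables feed external ordination tools directly.
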