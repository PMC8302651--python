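# Methods

This note documents the models and procedures implemented in
`soilfoodweb`, the parameter choices that matter, and what the synthetic
data generator does and does not emulate.

## Trophic scheme and assignment

The packaged scheme (`data/groups.csv`, `data/taxon_lookup.csv`) defines
37 fine trophic groups in 9 broad classes (primary producers,
decomposers, phytophagous/plant parasites, mycorrhizal fungi,
bacterivores, fungivores, omnivores, predators, animal parasites).
Groups named directly in the literature on this study system (e.g.
ectomycorrhizal, arbuscular and ericoid mycorrhizal fungi, wood
saprotroph and saprotroph-plant-pathogen fungi, copiotrophic and
oligotrophic bacteria, bacterivore mites/nematodes/protists, collembola,
enchytraeids) carry `provenance=main_text`; the remaining rows complete
the scheme with standard soil-food-web groups and are flagged
`provenance=reconstructed`. The taxon lookup is likewise a frozen,
package-local knowledge table in the spirit of FUNGuild/FAPROTAX/
Nemaplex-style assignment — no live database queries.

Assignment is most-specific-match-wins over the taxonomy rank list
(case-insensitive), with guild-qualified entries searched before
clade-only entries when a MOTU carries a guild annotation. MOTUs with no
match at any rank form an explicitly retained "unassigned" partition and
never enter downstream computation; assigned plus unassigned reads
always sum exactly to the input reads.

## Metaweb rules

Feeding knowledge is data (per-group prey whitelists and blacklists);
rules are code. A candidate link survives only if it passes:

* **size** — consumer `size_rank` ≥ prey `size_rank`, unless the
  consumer has `size_exception` (animal parasites, omnivore nematodes);
* **scale** — micro and macro organisms do not interact, unless the
  consumer is a declared `cross_scale_feeder` (microbivorous mites,
  collembola, enchytraeids, earthworms, etc.);
* **habitat** — prey flagged `endoparasite` (plant-pathogen protists)
  are not taken by free-living consumers;
* **blacklist** — explicit avoidances; the fungivore groups blacklist
  arbuscular mycorrhizal fungi, whose intraradical biomass makes them a
  non-preferred resource compared with saprotrophic and ectomycorrhizal
  fungi. Whether ericoid mycorrhizal fungi should also be fungivore prey
  is genuinely open; the packaged scheme follows the narrower reading
  (saprotrophs + ectomycorrhizal only).

Edges point prey → consumer (energy flow). Resource nodes (sunlight,
organic matter, plants) have no incoming links, are carried for
structural completeness, and are stripped before any diversity
computation. The packaged adjacency (`data/metaweb_groups.csv`, 115
links) is the frozen output of `build_metaweb(default_scheme())` and
serves as a regression fixture; it is a reconstruction from the rule
set, not a transcription of a published adjacency matrix.

Class aggregation is existential: classes k → l are linked iff some
member group pair is linked.

## Abundance measures

Within-group MOTU diversity per sample is the Hill-Shannon number
`exp(−Σ q ln q)` over the group's MOTU read proportions (0 for an empty
group). For cross-group comparability it is standardized by each group's
maximum across samples.

Relative abundance uses the double transform: reads → proportion within
the sample's read pool, then rescaled by the group's maximum proportion
across samples, giving values in [0, 1] with at least one exact 1 per
occurring group. Because read totals of different amplicons (16S, ITS1,
18S) are not comparable, proportions are computed **within each marker's
read pool** by default; a pooled mode (`per_marker=False`) is provided
since the original pooling convention is not documented. The transform
is invariant to per-sample sequencing depth. Samples with zero assigned
reads are rejected, not silently dropped. Class abundances are plain
sums of member-group values (they may exceed 1; normalization to
proportions happens inside each local web).

## Local webs and link abundances

A sample's group-level web keeps the groups with positive transformed
abundance, links two present groups iff the metaweb does, and weights
nodes by abundance. Link weights are binary at this resolution. At the
class level, node weights are member sums normalized to 1 and the link
weight is the encounter-conditional interaction probability
`W_kl = Σ_{i∈k,j∈l} p_i p_j π_ij / Σ_{i∈k,j∈l} p_i p_j` over locally
present groups (i ≠ j); pairs with zero encounter mass have no defined
weight and are recorded as absent.

The link-abundance distribution `L` needed for link diversity is not
uniquely determined by binary links. The implemented default weights
each realized link by the product of its endpoint node weights
(the same encounter logic as `W_kl`), normalized over links; a
uniform-over-links variant is available (`mode="uniform"`). This choice
is the package's own reconstruction and is stated here so results are
auditable.

## Network diversity and dissimilarity

Hill number of order η (viewpoint parameter, default 1):
`D_η(q) = (Σ q^η)^{1/(1−η)}`, with the exponential of Shannon entropy as
the η → 1 limit. α-diversity over a set of webs is the generalized mean
with exponent 1 − η of the local diversities (geometric mean at η = 1),
computed per area × condition cell.

Pairwise dissimilarity embeds both webs' node (or link) distributions in
their union space, takes γ = Hill number of the equal-weight mixture,
ᾱ = generalized mean of the two local diversities, β = γ/ᾱ ∈ [1, 2], and
normalizes: `ln β / ln 2` at η = 1, `(β^{1−η} − 1)/(2^{1−η} − 1)`
otherwise. Identical webs give 0; webs with disjoint support give 1.
Equal weights are used for the two webs of every pair. Pairs where one
web is empty for the chosen component are missing values, not 0 or 1.

## Hierarchical defoliation model

Per trophic group, `y_i = μ + β·d_i + u_{station(i)} + v_{area(i)} + ε_i`
with stations (8 levels) nested in areas (2 levels). Responses are the
standardized MOTU diversity, or the relative abundance after a
Yeo-Johnson transform whose λ is the per-group profile-likelihood MLE
(searched in [−5, 5]; hitting the window edge is flagged, never silently
returned). The Yeo-Johnson transform itself and the λ optimizer are
delegated to scipy.

The default estimation path is a conjugate Gibbs sampler: flat priors on
(μ, β), Jeffreys prior on the residual variance, and half-Cauchy priors
(inverse-gamma mixture representation) on the station and area
intercept standard deviations, scaled by the response's standard
deviation — the same weakly-informative spirit as regularized Bayesian
LMM defaults. Four chains; the full profile keeps 15 000 draws per chain
after an equal warmup, the reduced profile used in simulation studies
keeps 1 500; convergence is monitored with split-Rhat (< 1.10). The
sampler is vectorized over replicate response vectors, which is what
makes the 500-replicate calibration run in seconds. Under the null
(β = 0, station/area sd 0.1, residual sd 0.2, default design), the 90%
credible interval covers 0 at its nominal rate (≈ 90%, checked in the
test suite and the acceptance script). An alternative `bootstrap` path
resamples stations within area × condition strata and reads the point
estimate from OLS on station means with area indicators; with only two
stations per stratum its percentile intervals are approximate, and it
exists as a fast frequentist cross-check, not the reference method.

The area × defoliation interaction is deliberately absent from the
default model (it can be emulated by fitting areas separately); effect
screening across groups is reported without multiplicity adjustment,
matching standard practice for forest-plot style summaries.

## MDMR with restricted permutations

The dissimilarity matrix is squared, Gower-centred
(`G = −½ J D² J`), and the pseudo-F for the defoliation dummy is
`[x̃ᵀGx̃/x̃ᵀx̃] / [(tr G − x̃ᵀGx̃/x̃ᵀx̃)/(n−2)]`. The null distribution must
respect the nesting: condition labels are permuted across stations
within each area and samples move with their stations. With the default
8-station design the restricted space has 36 assignments, and the global
label flip reproduces the observed statistic exactly; random draws are
therefore taken uniformly from the non-identity assignments while the
observed one enters once through the add-one estimator
`p = (1 + #{perm ≥ obs})/(1 + n_perm)`, keeping p-values valid
(super-uniform) and α = 0.05 reachable. An exhaustive mode enumerates
all 35 distinct non-identity assignments, where the smallest attainable
p is 2/36. The granularity of such small restricted spaces is a real
limitation of the design, not of the implementation.

## Synthetic data generator

The generator emulates the study layout (2 areas × [2 defoliated + 2
undamaged] stations × 15 cores; optional uniform dropout to 86 retained
samples) and a Dirichlet-multinomial read model: per-group log shares
get station and area intercepts (sd 0.15 each) and the defoliation
effect β_g; realized shares are Dirichlet with concentration 50 around
the softmax means; depths are lognormal (mean 20 000 reads, CV 0.3);
within-group MOTU reads are Dirichlet-multinomial with a concentration
multiplied by δ_g under defoliation, so δ_g > 1 raises expected
Hill-Shannon MOTU diversity. Baseline shares make undamaged communities
dominated by ectomycorrhizal fungi, saprotrophic fungi and bacteria,
with rare higher-trophic-level groups whose presence/absence fluctuates
— the feature that lets defoliation change web size and evenness.

The `paper_signs` preset encodes the reported response directions:
ectomycorrhizal fungi strongly down (β = −2, δ = 0.6), arbuscular
mycorrhizal fungi strongly up, decomposer groups weakly up
(β = 0.15–0.3), bacterivores/omnivores up (β = 1.5), predators up
(β = 1.2), with ericoid mycorrhizal fungi and herbivore mites unaffected
— the weak-decomposer/strong-consumer contrast is what produces a
*decreasing* decomposer share inside local webs even though every
decomposer group individually increases. **All magnitudes are
stand-ins**: the source system reports directions and interval plots,
not numeric effect sizes. Passing directional checks therefore shows
that the pipeline propagates a known ground truth correctly, not that
real soils behave with these magnitudes. The generator also ignores
marker-specific amplification bias, gene-copy-number variation,
cross-contamination and spatial autocorrelation within stations.

Directional summaries (α contrasts, class-proportion changes) are
averaged over 5 replicate simulated studies in the acceptance script and
test suite: with only 4 stations per condition, a single simulated study
has cluster-level noise of the same order as some of the weaker
directional effects.

## Numerical choices and problem sizes

* Natural logarithms throughout; Hill numbers treat |η − 1| < 1e−9 as
  the Shannon limit.
* Class node weights must sum to 1 within 1e−9; class-link oracle
  equivalence is required to 1e−12 in tests.
* Zero-variance responses short-circuit the effect fit to (0, [0, 0]).
* Degenerate designs (< 2 stations per condition) are errors, not
  warnings.
* Test-suite problem sizes: 1000-distribution Hill property sweeps,
  1000 random small webs (≤ 12 groups, ≤ 4 classes) for the aggregation
  oracle, 500 replicate fits for interval calibration, 200 × 199 for
  MDMR calibration, 5 × 86-sample studies for directional checks —
  sizes chosen to give stable Monte-Carlo estimates in minutes on one
  CPU.

## Known limitations

* The 37-group membership and the metaweb adjacency are partially
  reconstructed (see provenance flags); swapping in a curated scheme is
  a matter of editing two CSVs.
* Binary local links ignore interaction strengths; `A^η(L)` depends on
  the encounter-product construction of L.
* The MDMR permutation space is coarse for 8 stations; p-values below
  ~0.03 (random mode) or 2/36 (exhaustive) are unattainable by design.
* eDNA read proportions are at best rank proxies for biomass; all
  "abundance" statements inherit that caveat.
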