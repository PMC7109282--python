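# Methods

`landqgen` implements a multi-scale landscape-genetics workflow for a
mixed-mating, animal-pollinated savanna tree sampled as replicated
landscapes, each containing a pair of habitat sites: neutral
microsatellite statistics per site and per site pair, quantitative
genetics of open-pollinated progeny under mixed mating, raster landscape
metrics at node (site) and link (site-pair) scales, and information-
theoretic model selection connecting the two. Because workflows of this
kind are usually published without deposited genotypes, traits or GIS
layers, the package ships a first-class synthetic-data module whose
generating parameters are known, so every stage is validated by parameter
recovery rather than by re-fitting published numbers.

## Neutral-locus statistics

**Expected heterozygosity.** Nei's unbiased gene diversity per site and
locus, `He = n/(n-1) * (1 - sum p_a^2)` with `n` the number of observed
gene copies; multilocus values are means over loci. Missing allele calls
are dropped per locus (pairwise deletion), matching the convention of the
classical F-statistics packages.

**Allelic richness.** Rarefaction to a common number of gene copies `g`:
`AR = sum_a [1 - C(N - N_a, g) / C(N, g)]`, evaluated with exact integer
binomials. By default `g` is the smallest gene-copy count over all
site-by-locus cells. The test suite verifies the formula against
exhaustive subsample enumeration in exact rational arithmetic for
`N <= 12`.

**Inbreeding.** The Weir–Cockerham within-population estimator (ratio of
summed `b`, `c` components over alleles and loci). Deviation from
Hardy–Weinberg proportions is tested by permuting gene copies among
individuals within the site, per locus; p-values use the add-one
correction `(b + 1)/(n_perm + 1)` and are reported both multilocus
(default) and per locus, since either convention appears in practice.

**F-statistics.** Weir–Cockerham variance components `a` (among
populations), `b` (among individuals within populations) and `c` (within
individuals), per allele and locus; multilocus `F_ST`, `F_IS`, `F_IT` are
ratios of summed components. Loci monomorphic across the analysed sites
are skipped. A delete-one-locus jackknife supplies standard errors for
`F_ST` and `R_ST`.

**G'_ST and Jost's D.** Both are built from `H_S` and `H_T` estimated
with gene-copy-weighted allele frequencies and small-sample corrections
(`H_S` is the weighted mean of per-site unbiased diversities; `H_T` adds
the Nei–Chesser-style `H_S/(c_h k)` term with `c_h` the harmonic-mean
gene-copy count). `G'_ST = G_ST / G_ST(max)` with
`G_ST(max) = (k-1)(1-H_S)/(k-1+H_S)`;
`D = (k/(k-1)) (H_T - H_S)/(1 - H_S)`. Multilocus combination averages
the heterozygosity components over loci before forming the ratio.
Because the estimators are unbiased, slightly negative values occur for
weak differentiation; they are reported as computed.

**R_ST.** One-way ANOVA variance components of allele sizes (gene copies
as observations, populations as groups) with Searle's `n_0` coefficient;
multilocus by ratio of summed components. The hypothesis `F_ST = R_ST`
(no stepwise-mutation contribution to differentiation) is tested by
permuting the sizes assigned to the distinct allelic states within each
locus and comparing `|R_ST - F_ST|` to its permutation distribution.
This is one of the two permutation schemes in circulation (the
alternative permutes sizes among all gene copies); the choice is exposed
in the docstring.

**Effective size.** The molecular-coancestry method: the pairwise
similarity of genotypes `(a,b)` and `(c,d)` at a locus is
`S = (I_ac + I_ad + I_bc + I_bd)/4`; coancestry `fhat` averages `S` over
loci within a pair and then over pairs, and `Ne = 1/(2 fhat)`. When
`fhat <= 0` the size is reported as not estimable (`inf` sentinel). No
small-sample or allele-frequency correction beyond the plain ratio is
applied, so with many-allele microsatellites the identity-by-state
baseline biases `Ne` downward; treat it as a relative index across sites
rather than a calibrated census-scale estimate.

## Quantitative genetics under mixed mating

Open-pollinated families of a partially selfing tree are more related
than half-sibs. With population inbreeding `f` estimated from the
neutral loci (per site, overridable), the selfing rate is
`s = 2f/(1+f)`, the within-family coancestry
`theta = (1+3f)^2 / (8(1+f))`, and the correction coefficient
`c = 2 theta = (1+s)^2 / (2(2-s))` — both routes are computed and must
agree to 1e-12. Additive variance is recovered from the among-family
variance component as `Va = sigma2_fam / (2 theta)`; at `f = 0` this is
the textbook `4 sigma2_fam`. Evolvability is `CVa% = 100 sqrt(Va)/mean`
and narrow-sense heritability `h2 = Va / (sigma2_fam + sigma2_res)`,
i.e. over the within-population phenotypic variance; including the
among-population variance in the denominator is a defensible alternative
that would lower every estimate, and is not the default. Because the
correction divides by `2 theta <= 2`, `h2 > 1` is possible; raw values
are reported with a capped copy and a flag rather than silently
truncated.

**REML.** Variance components come from restricted maximum likelihood
with the residual variance profiled out and the optimisation run over
variance ratios with non-negativity bounds. The one-way (family) model
uses the closed-form block structure of `V = sigma2_e (I + gamma J)`;
the nested population + family(population) model uses an exact
eigenvalue decomposition for balanced designs and per-population dense
Cholesky factorisations otherwise. Boundary estimates (components at 0)
are considered explicitly. The implementation agrees with
`statsmodels.MixedLM` and with a brute-force full-covariance REML
likelihood in the tests; an ANOVA method-of-moments estimator (Searle's
`n_0` for unbalanced data) is the documented fallback when REML fails to
converge, and equals REML on balanced interior cases.

**Q_ST and P_ST.** For each within-landscape site pair,
`Q_ST = sigma2_pop / (sigma2_pop + 2 sigma2_A)` from the nested model
with `sigma2_A = sigma2_fam/(2 theta)` (the `f` used for a pair is the
mean of the two sites' estimates). Seed traits are measured on
field-collected seeds where genetic and maternal/environmental effects
cannot be separated, so they get the phenotypic analogue
`P_ST = c' sigma2_pop / (c' sigma2_pop + 2 sigma2_within)` with the
assumed additive proportion `c'` defaulting to 1 and exposed for
sensitivity analysis.

**Trait handling.** Repeated height/diameter measurements at days 76,
116, 133 and 145 are collapsed to OLS growth rates (HGR cm/day, DGR
mm/day) plus initial/final values. Germination yields PG
(germinated/sown per family) and TG (days to shoot, germinants only).
Before any fitting, traits are pruned on the pairwise Pearson matrix:
repeatedly drop the trait with the most partners at `|r| > 0.5` (ties
broken by larger mean `|r|`) until none remain; a configurable keep-list
(defaults to the seed/seedling set SLD, STD, SM, NL, LW, RL, RDM, ASL)
is never dropped. The same greedy rule drives the landscape-metric
screen.

## Landscape metrics

All geometry is raster-only: a buffer is the set of cells whose centers
lie within the radius, so there is no vector-GIS dependency and
discretisation error vanishes with cell size (verified against
closed-form areas). Node buffers default to 0.5 km around each site;
link buffers to 2, 4 and 6 km around the midpoint of each
within-landscape pair; link buffers are not clipped to the landscape
boundary. Metrics:

* per-class percentage of buffer area, with composite groups (e.g. the
  open-vegetation or pollinator-habitat unions) as member sums;
* donut subtraction between successive scales (`pct(4 km) - pct(2 km)`),
  the decorrelation device for multi-scale habitat amount — negative
  values are legitimate and mean the class concentrates inside the inner
  radius;
* SHDI `= -sum p_i ln p_i` over classes present in the buffer;
* BMQ `= sum P_i Q_i / sum P_i`, the area-weighted mean of per-class
  quality scores. The default score table spans 0.2–1.0 with the habitat
  class at 1.0; the per-class values are synthetic placeholders for the
  simulated classes and are fully user-configurable;
* functional connectivity: habitat cells in the buffer are labeled into
  8-neighbour patches and dilated by a dispersal radius (default 500 m, a
  pollinator foraging distance) via a Euclidean distance transform; the
  reported area (hectares) is the dilated union. A
  `patches_plus_corridors` variant adds only the halo shared by two or
  more patches to the raw patch area, for users who read "patches plus
  connected area" more narrowly.

The scale-of-effect screen collapses a metric across scales when all
inter-scale correlations exceed 0.90 (keeping the smallest scale) and
then applies the greedy `|r| > 0.5` pruning across metrics.

## Model selection

Responses and predictors are one observation per site (node level,
`n = 10` in the reference design) or per landscape (link level, `n = 5`).
Models are single-predictor Gaussian fits (maximum likelihood, i.e. OLS
with ML variance in the log-likelihood so criteria are comparable);
`AICc = -2 logLik + 2k + 2k(k+1)/(n-k-1)` with `k = 3` counting
intercept, slope and residual variance. Candidate sets are ranked by
AICc with Akaike weights (`sum w = 1`), a plausible-set flag at
`dAICc < 2`, and significance tiers annotated at p < 0.05 (**) and
p < 0.10 (*). At link level the sample is too small for stable
information-theoretic ranking, so only slope significance is reported
and predictors are log10-transformed to tame outlier landscapes; an
exclusion flag for an outlier landscape exists but nothing is excluded
by default. No multiple-testing correction is applied across responses;
output metadata says so.

## Synthetic data

* **Genotypes.** Per-site allele frequencies follow the Balding–Nichols
  divergence model: Dirichlet with concentration `(1-F)/F` times the
  ancestral frequencies, chosen because its expected `F_ST` equals `F`,
  which is what makes parameter-recovery testing clean. Within sites,
  inbreeding is an identity-by-descent mixture: with probability `f` the
  two gene copies are one draw duplicated, else independent draws —
  exactly the `f` the downstream correction consumes. Alleles are
  reported as sizes on a ladder (base 100, step 2) so `R_ST` is
  computable. The reference design (10 sites of 60, 10 loci, 15 alleles,
  `F = 0.05`, `f = 0.15`) produces per-site gene diversities around
  0.87–0.92 and inbreeding around 0.12–0.18.
* **Progeny trials.** `y = mean + pop + family + residual` with the
  family variance set to `2 theta Va`, so the mixed-mating correction
  recovers the target `Va` exactly in expectation. The reference trait
  table uses balanced families (15 per site, 7 offspring) because the
  field design published only totals; per-trait generating values are
  chosen to give realistic means, CVs and heritabilities (see
  `presets.TRAIT_PARAMS`). Redundant companion traits (leaf length from
  leaf width, masses from lengths) and the repeated growth series are
  generated with strong correlations so the pruning and growth-rate
  stages do real work.
* **Scenes.** Smoothed Gaussian noise fields thresholded at the habitat
  target quantile give autocorrelated, patchy rasters whose realized
  habitat percentage is exact to rounding; remaining cells are
  partitioned among the other 10 classes along a second smoothed field.
  Sites are placed inside the largest habitat patches. The five
  landscapes span 15–60 % habitat.

What the generators deliberately do not emulate: coalescent history,
mutation-model realism, linkage, spatially explicit gene flow,
genotype-by-environment interaction, and any causal coupling between the
landscape rasters and the genetic or trait values. Passing recovery
tests therefore demonstrates that the estimators are correct and
calibrated under the assumed models, not that the ecological
conclusions of any particular field system would be reproduced.

## Numerical choices and problem sizes

Permutation tests default to 999 replicates (199 inside the full
pipeline preset) with add-one p-values and seeded generators; every
stochastic step in the pipeline derives its stream from the run seed, and
repeated runs are byte-identical. REML optimisations bound variance
ratios to `[0, 1e6]` and compare interior optima against the boundary
corners. The validation suite uses 50 random instances per statistic for
oracle agreement (tolerance 1e-10), 50 replicate simulations for the
`F_ST` recovery (tolerance ±0.015 around 0.05), 200 replicates for the
`Va` sign test and 100 for `Q_ST` (mean bias ≤ 0.05), and convergence of
the connectivity area at 20/10/5 m cells against the closed-form
Minkowski sum (within 2 % at 10 m). These sizes keep the whole suite in
the low minutes on one core while leaving Monte-Carlo noise well below
the tested tolerances.

## Known limitations

* The coancestry `Ne` lacks the reference-implementation small-sample
  corrections (undocumented internals); see above.
* SELEGEN's exact covariance structures ("model 82"/"model 5") are not
  published; the nested random-effects models here are standard
  equivalents, not byte-level reimplementations.
* `G'_ST`/`D` weighting (sample-size weights vs unweighted population
  means) differs among published implementations; this package uses
  gene-copy weights and documents it.
* Raster buffers use cell-center membership; at coarse resolutions the
  buffer area is quantised (bounded by the convergence tests).
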