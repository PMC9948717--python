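# Methods

`betabef` implements a two-stage analysis of how compositional turnover
(β diversity) between paired microbial communities relates to their summed
biomass, and how that relationship is modulated by the determinism of
community assembly as read from a phylogenetic null model. This note
documents the statistical machinery, the synthetic-data generator that
provides ground truth, and the numerical and design choices a user should
know about.

## The pair-level data model

The sampling unit is the unordered pair of sites within one cruise. A
survey of `n_sites = 6` stations visited on `n_cruises = 14` cruises yields
C(6,2) = 15 pairs per cruise. For each pair we record:

* **β diversity** — Bray-Curtis dissimilarity `1 − 2Σᵢmin(xᵢ,yᵢ)/(Σx+Σy)`
  on count vectors rarefied once, without replacement, to a common depth
  (the global minimum row sum by default). Rarefaction draws are
  multivariate hypergeometric, so a rarefied count can never exceed the raw
  count and every row sums exactly to the target depth.
* **Summed biomass** — the arithmetic sum of the two sites' bacterial
  biomass (µg C/L). Cell densities convert to carbon with 2×10⁻¹⁴ g C/cell
  for bacteria and 4.7×10⁻¹² g C/cell for heterotrophic nanoflagellates.
* **Pooled α diversity** — richness and Shannon entropy (nats) of the
  combined count vector.
* **Environment** — per-variable arithmetic mean of the two sites
  (temperature, salinity, dissolved inorganic nitrogen, phosphate, PAR,
  chlorophyll *a*); a missing value at one site leaves the other site's
  value, missing at both propagates as missing.

## The assembly statistic (β-MPTI)

For a site pair with presence sets A and B, the observed mean pairwise
phylogenetic distance is

    MPD_obs = mean over (i ∈ A, j ∈ B) of d(i, j),

with d the patristic (sum-of-branch-length) distance and shared taxa
contributing zero-distance pairs (`pair_set="between"`, the βMPD
construction of the βNTI family; `pair_set="union"` averages over all
unordered pairs in A ∪ B instead). The null model shuffles tip labels
uniformly at random and recomputes MPD; after `n_rand = 999` shuffles,

    β-MPTI = (MPD_obs − mean MPD_null) / SD MPD_null.

Negative values mean the two communities hold taxa more closely related
than a random draw (homogenizing selection); positive values mean
overdispersion (diversifying selection); values near zero are consistent
with stochastic assembly.

**Null pool.** The shuffled pool defaults to *all* tree tips
(`pool="all"`), the regional-species-pool convention of picante-style
taxa-label nulls. This is a deliberate choice: if labels are shuffled only
within the union A ∪ B (`pool="pair"`), two communities confined to a
single clade are compared against a null that is itself confined to that
clade, and homogenizing selection becomes invisible (z ≈ 0 even under
strong clustering; in the limit A = B = A∪B the null is exactly
degenerate). `pool="pair"` and `pool="cruise"` (taxa observed anywhere in
the cruise) remain available for sensitivity analysis.

**Determinism and degeneracy.** Each pair's null draws come from an RNG
stream keyed on the global seed and the unordered pair of taxon sets, so
results are independent of execution order, safe to parallelize, and
identical compositions receive identical z-scores. When the null has zero
spread (e.g. both communities contain every pooled taxon) the statistic is
undefined and is reported as missing with a warning; zero spread is
detected relative to the null mean (threshold 10⁻¹² × max(1, |mean|))
because permutation-order floating-point jitter leaves O(ε) variance even
in exactly degenerate cases.

The z-score is exactly invariant under uniform rescaling of branch lengths
(scale cancels) and invariant in distribution under taxon relabeling (the
content-keyed RNG makes relabeled runs differ within Monte Carlo error,
about ±0.1 at 999 draws).

## Hypothesis tests

**Stage I (pair level).** `log(summed biomass)` is regressed on
`log(Bray-Curtis)` in a Gaussian linear mixed model with a random intercept
per cruise, fitted by REML (statsmodels `MixedLM`). All logs are natural.
Pairs with Bray-Curtis = 0 drop out of log-scale fits with a warning.
Environmental covariates (log-transformed) enter a backward-elimination
loop: repeatedly refit and drop the non-protected term with the largest
p ≥ α (default 0.05) until all remaining non-protected terms are
significant. The β-diversity term is protected and never dropped; pooled
Shannon diversity can optionally be added as a second protected confounder.
With α = 1 the procedure returns the full model, with α = 0 only the
protected terms. Reported fit quality is the Nakagawa–Schielzeth marginal
R² = var(Xβ) / (var(Xβ) + σ²_cruise + σ²_resid). A singular or
non-converged random-effect fit falls back to pooled OLS and says so in the
result's notes.

**Stage II (cruise level).** The β-diversity *effect* of cruise c is the
OLS slope of `log(summed biomass)` on `log(Bray-Curtis)` over that cruise's
usable pairs (skipped with a warning below 3 pairs; constant regressors are
an error). The effects are then regressed across cruises on the cruise mean
β-MPTI, optionally with cruise-mean log environmental covariates under the
same backward selection (β-MPTI protected). A positive coefficient means
the β-diversity effect strengthens where assembly is more diversifying /
less homogenizing. When there are too few cruises to fit the full
covariate model the covariates are dropped with a warning rather than
failing the run. A companion mixed model of `log(Bray-Curtis)` on β-MPTI
checks that β diversity itself tracks assembly.

All tests are two-sided Wald/t tests at α = 0.05; no randomness enters any
regression.

## Phylogenetic signal (Mantel correlogram)

Using phylogeny to infer assembly presumes ecological similarity tracks
relatedness. Each taxon's niche value per environmental variable is its
abundance-weighted mean environment over all cruise-sites; niche values are
z-standardized per variable and combined into Euclidean between-taxon
distances. Phylogenetic distances are cut into equal-width classes
(Sturges' rule by default); per class the Mantel statistic is the Pearson
correlation between the condensed niche-distance vector and the class
indicator, with a two-sided permutation p over 999 taxon-label
permutations and Holm correction across classes (classes with fewer than
3 pairs are reported as missing). Significant negative correlations at
short phylogenetic distance indicate signal.

## The synthetic-data generator

The generator emulates the repeated-transect design so that every analysis
stage can be tested against known truth. What it does — and does not —
emulate:

* **Phylogeny:** a Yule (pure-birth, rate 1) tree. The simulator's stopping
  rule leaves the final sibling pair with zero-length tip edges, so every
  tip edge is extended by the next exponential waiting time; branch lengths
  are strictly positive. Real 16S gene trees have rate heterogeneity and
  uncertainty the Yule tree lacks; none of the downstream statistics
  depends on the tree model.
* **Assembly regimes:** a continuous trait evolves along the tree by
  Brownian motion (rate `trait_sigma`), is redrawn for every cruise (each
  cruise selects on its own environmental axis — this also averages out
  the realization-to-realization variability in how faithfully one BM draw
  mirrors the phylogeny) and is z-standardized. Site sampling weights are
  a per-site lognormal baseline (σ = 1.5, emulating stochastic local
  dynamics and a realistic abundance distribution) times, under selection,
  a Gaussian kernel exp(−s·(trait − optimum)²); `selection_strength` s is
  therefore in units of inverse squared trait SD. Under *homogenizing*
  selection all sites share one optimum (a randomly chosen taxon's trait);
  under *diversifying* selection the six optima are spread evenly over the
  full standardized trait range; under *neutral* the kernel is absent.
  Reads are one multinomial draw of `depth` per site (default 13,129, the
  depth-standardization floor the pipeline defaults emulate; any value
  ≥ 1,000 is accepted).
* **Biomass:** two modes. `site` mode gives each site biomass
  exp(intercept_c/2)·(mean Bray-Curtis to the cruise's other sites)^slope_c
  times lognormal noise — pair sums then associate positively with pair
  dissimilarity when slope_c > 0, but not through an exact linear law.
  `pair-exact` mode writes `log(summed biomass) = intercept_c +
  slope_c·log(BC) + N(0, noise_sd)` directly at the pair level, existing
  solely to test the regression stages in isolation (a site-level
  generator cannot make pair sums follow an exact linear model). Defaults
  plant slope 0.17 and intercept 3.7 (≈ 40 µg C/L per pair) in every
  cruise, with noise_sd = 0.1.
* **Environment:** inshore→offshore gradients with per-cruise offsets —
  temperature and salinity rise linearly offshore, riverine nutrients and
  chlorophyll *a* decay exponentially, with magnitudes typical of a
  river-influenced shelf sea. The generator has no space, currents,
  dispersal, or sequencing error; passing tests demonstrate correctness of
  the statistical machinery under the stated generative model, not
  robustness to the messiness of field data.

All randomness descends from one integer seed through per-cruise
substreams (`SeedSequence([seed, stream, cruise])`), so runs are
bit-reproducible and single cruises can be regenerated independently.

## Numerical and scale choices

* Null draws per pair: 999; Mantel permutations: 999; both configurable.
* The acceptance checks and test suite run the generator at reduced scale
  (50 taxa, depth 2,000 for null-model calibration; 30 taxa, depth 1,500
  for regression recovery; 100 Monte Carlo replicates), sizes at which the
  measured quantities are stable to within the tolerances asserted.
* Monotonicity of the homogenizing regime (stronger selection → more
  negative mean β-MPTI) holds over moderate strengths (0.5–5). Under
  extreme selection communities shrink to a handful of taxa, the null SD
  grows, and the attainable |z| saturates — the z-score is a detection
  statistic, not an effect-size scale.
* Backward selection at α = 0.05 with k independent noise covariates
  retains at least one of them with probability ≈ 1 − 0.95^k (≈ 14% for
  k = 3); simulation checks of "all noise dropped" rates are read against
  that baseline.
* TSV outputs use pandas' default float repr, "NA" for missing, UTF-8;
  reruns with identical config and seed are byte-identical, and the JSON
  manifest records config, seed, versions, input checksums and all
  warnings raised during the run.

## Known limitations

* The mixed models use a random intercept only (no random β-diversity
  slope); cruise-to-cruise slope variation is instead captured explicitly
  by the stage-II cruise fits.
* Coverage-based (rather than equal-depth) standardization is not
  implemented; the pipeline rarefies once to a common depth.
* β-MPTI is reported per pair with no multiple-comparison adjustment — it
  feeds a regression, not a per-pair significance claim.
* The Mantel correlogram uses equal-width distance classes; very uneven
  phylogenetic-distance distributions can leave sparse classes (reported
  as missing rather than estimated).
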