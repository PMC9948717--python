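# betabef

Does compositional difference between microbial communities (β diversity)
raise their combined ecosystem function, and is that effect stronger where
community assembly is deterministic rather than stochastic? `betabef` is a
Python toolkit for answering those questions in multi-site, multi-visit
surveys of bacterioplankton (or any community with a count table, a
phylogeny, and a per-site function proxy such as biomass).

It is aimed at microbial ecologists who have per-cruise site × ASV count
tables, a rooted 16S phylogeny, and per-site biomass/environment records —
or who want a fully synthetic test bed with planted effects.

## What it computes

For every pair of sites within a cruise (6 sites → 15 pairs):

* **β diversity**: Bray-Curtis dissimilarity
  `BC = 1 − 2Σᵢ min(xᵢ, yᵢ) / (Σx + Σy)` on counts rarefied once (without
  replacement) to a common depth;
* **function**: the summed bacterial biomass of the two sites (µg C/L);
* **assembly**: the β mean pairwise taxonomic index, a tip-shuffle null
  z-score of between-community phylogenetic distance,

  `β-MPTI = (MPD_obs − mean MPD_null) / SD MPD_null`,

  where `MPD_obs` is the mean patristic distance over all cross-community
  taxon pairs and the null is 999 random tip-label shuffles of the
  phylogeny. Negative values: the two communities hold closer relatives
  than random (homogenizing selection); positive: overdispersion
  (diversifying selection); ≈ 0: stochastic assembly.

Two regression stages then test the hypotheses:

1. **log(summed biomass) ~ log(BC)** in a linear mixed model with a cruise
   random intercept, with backward elimination of log-environment
   covariates (the β-diversity term is always retained) and
   Nakagawa–Schielzeth marginal R²;
2. per-cruise OLS slopes of the same relation (the **β-diversity
   effects**) regressed across cruises on each cruise's **mean β-MPTI** —
   a positive coefficient means deterministic (diversifying) assembly
   strengthens the β-diversity effect.

A phylogenetic Mantel correlogram (abundance-weighted niche values,
equal-width phylogenetic distance classes, permutation tests with Holm
correction) checks the premise that ecological similarity tracks
relatedness. A synthetic-data module generates the whole survey — Yule
phylogeny, trait-based selection regimes (neutral / homogenizing /
diversifying), environment gradients, and biomass with planted per-cruise
β-diversity effects — so every stage can be validated against ground truth.

## Worked example

```python
import numpy as np
from betabef import (SyntheticConfig, simulate_phylogeny, simulate_communities,
                     simulate_site_biomass, build_pair_table, cophenetic_distances,
                     pairwise_assembly, fit_cruise_slopes, cross_cruise_regression)

cfg = SyntheticConfig(n_cruises=14, n_taxa=50, depth=2000,
                      regime="homogenizing", seed=42)
tree = simulate_phylogeny(cfg.n_taxa, cfg.seed)
tables = simulate_communities(tree, cfg)
metadata = simulate_site_biomass(tables, cfg)          # site-level biomass
pairs = build_pair_table(tables, metadata)             # 14 cruises x 15 pairs

dist = cophenetic_distances(tree)
pairs, cruises = pairwise_assembly(pairs, tables, dist, n_rand=999, seed=42)
print(f"pairs: {len(pairs)}, mean beta-MPTI: {pairs.beta_mpti.mean():.2f}")

# planted-effect recovery on the exact pair-level generator
exact = SyntheticConfig(n_cruises=14, n_taxa=50, depth=2000,
                        biomass_slope_per_cruise=0.17, noise_sd=0.02, seed=42)
effects = fit_cruise_slopes(simulate_site_biomass(tables, exact, mode="pair-exact"))
print(f"planted slope 0.17 -> fitted mean {effects.slope.mean():.3f} "
      f"+/- {effects.se.mean():.3f}")

mpti = np.linspace(-2.0, 0.0, 14)
exact2 = SyntheticConfig(n_cruises=14, n_taxa=50, depth=2000,
                         biomass_slope_per_cruise=list(0.3 + 0.79 * mpti),
                         noise_sd=0.02, seed=43)
effects2 = fit_cruise_slopes(simulate_site_biomass(tables, exact2, mode="pair-exact"))
effects2["mean_beta_mpti"] = mpti
h2 = cross_cruise_regression(effects2)
print(f"planted determinism coefficient 0.79 -> fitted "
      f"{h2.coef('mean_beta_mpti'):.3f} (p = {h2.pvalue('mean_beta_mpti'):.1e})")
```

prints

```
pairs: 210, mean beta-MPTI: -2.94
planted slope 0.17 -> fitted mean 0.185 +/- 0.032
planted determinism coefficient 0.79 -> fitted 0.800 (p = 9.6e-15)
```

The homogenizing regime pushes β-MPTI strongly negative (communities share
one clade), the per-cruise slope estimates recover the planted β-diversity
effect, and the cross-cruise regression recovers the planted link between
assembly determinism and effect strength.

## Command line

```sh
betabef simulate --config sim.yaml --outdir data      # synthetic survey
betabef run      --config run.yaml --outdir out       # full pipeline
```

`run` consumes either a `synthetic:` block or real-data paths
(`data: {tree, counts: [...], metadata}`) plus a `params:` block (`depth`,
`n_rand`, `pool`, `pair_set`, `alpha`, `n_perm`, `seed`) and writes
`pairs.tsv`, `cruise_assembly.tsv`, `cruise_effects.tsv`, `h1_model.tsv`,
`h2_model.tsv`, `beta_vs_assembly.tsv`, `correlogram.tsv`,
`selection_trace.txt` and a `manifest.json` (config echo, seed, versions,
input checksums, warnings). Identical config + seed reproduces
byte-identical outputs. The stages are also available individually as
`betadiv`, `assembly`, `bef` and `signal`.

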