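# multidiv

Multifaceted plant-diversity analysis for communities sampled along
environmental gradients — built for the kind of study design used in
dam-regulated riparian zones, where sites sit in discrete inundation zones
along a river and the question is whether environmental filtering or
dispersal limitation assembles the vegetation.

The package computes, from a site-by-species table, a species trait table,
a dated phylogeny, a site environment table and site coordinates:

- **Alpha diversity** in three dimensions: taxonomic and functional Rao
  quadratic entropy *Q* = Σᵢ Σⱼ dᵢⱼ pᵢ pⱼ (Gower trait distances dᵢⱼ;
  dᵢⱼ = 1 gives Gini–Simpson), Faith's phylogenetic diversity, and the
  mean pairwise (MPD) and mean nearest-taxon (MNTD) distances.
- **Standardised effect sizes** against a richness-preserving null:
  SES = (obs − mean_null)/sd_null with species labels shuffled on the
  distance matrix; SES < 0 indicates clustering, SES > 0 overdispersion,
  |SES| > 1.96 a significant departure.
- **Beta diversity** in the Sørensen family, partitioned into turnover
  (β_sim) and nestedness (β_sne = β_sor − β_sim) components, pairwise and
  multiple-site, in species counts (taxonomic), tree branch lengths
  (phylogenetic) and functional-dendrogram branch lengths or trait-space
  convex-hull volumes (functional).
- **Drivers of beta diversity**: PCNM spatial eigenvectors, PCA-reduced
  climate and soil predictors, Mantel and partial Mantel permutation
  tests, and variance partitioning of adjusted R² over the four predictor
  sets (inundation gradient, climate, soil, spatial) with forward
  selection.
- **A synthetic-data generator** that builds species pools on Yule trees
  with phylogenetically structured traits, a zoned riverbank landscape,
  and communities assembled under named scenarios (neutral, filtering,
  dispersal, nested loss, turnover, mixed) — so every analysis stage can
  be checked against known ground truth.

## Worked example

```python
import multidiv as md

bundle, truth = md.generate(md.scenario_presets()["paperlike"], seed=1)
alpha = md.alpha_pipeline(bundle).data
zones = bundle.env.data["zone"]
print(alpha.groupby(zones).mean().round(3))

ses = md.ses(bundle, metric="mntd", dimension="phylo", n_null=1000, seed=1)
print(md.classify_structure(ses, zones)[["n", "clustered", "sig_clustered"]])

for dim, part in md.beta_all(bundle).items():
    m = part.multisite
    print(f"{dim}: SOR={m['SOR']:.3f} "
          f"turnover={m['turnover_pct']:.1f}% "
          f"nestedness={m['nestedness_pct']:.1f}%")
```

prints (seed 1):

```
      raoq_td  raoq_fd  faith_pd    mpd   mntd
zone
I       0.944    0.459    47.313  8.248  3.585
II      0.929    0.457    40.720  8.375  4.117
III     0.909    0.432    32.428  8.071  4.145
IV      0.875    0.408    21.435  7.200  3.255
       n  clustered  sig_clustered
zone
I     16          8              0
II    16          7              1
III   16          9              0
IV    16         15              9
taxonomic: SOR=0.973 turnover=99.4% nestedness=0.6%
phylogenetic: SOR=0.954 turnover=98.3% nestedness=1.7%
functional: SOR=0.947 turnover=98.4% nestedness=1.6%
```

Reading this like a field study: all three alpha-diversity dimensions
decline from zone I (68 days of inundation) to zone IV (204 days), and the
count of phylogenetically clustered communities rises from 8/16 to 15/16
down the gradient — exactly the signature the generator's graded
environmental filtering was designed to leave.  Multi-site beta diversity
is turnover-dominated here because each site draws a small community from
a 166-species pool.

The same analyses run from the shell:

```bash
multidiv simulate --scenario paperlike --seed 1 --out-dir sim/
multidiv run --scenario paperlike --seed 1 --out-dir run/
multidiv mantel --x run/beta_tax_sor.csv --y run/pcnm.csv --n-perm 999
```

`multidiv run` writes alpha.csv, ses.csv, zone_summary.csv, the nine
pairwise beta matrices, beta_multisite.csv, pcnm.csv, envpca.csv,
mantel.csv, varpart.csv and a manifest.yaml recording every numeric
convention in effect; a run is a pure function of (inputs, config, seed).

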