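# Methods

This note records the statistical conventions, generator design and
numerical choices behind `multidiv`, in the spirit of a package methods
appendix: everything here is implemented and exercised by the test suite;
no empirical claim is made beyond what the tests and
`scripts/acceptance.py` themselves compute.

## Data model and reconciliation

Analyses run on a validated bundle: a site-by-species matrix (presence or
abundance), a trait table with every column declared `categorical`,
`ordinal` or `continuous` in a sidecar schema (a column of 1/2/3 codes is
ambiguous, so kinds are never inferred from values), a rooted phylogeny
with branch lengths (Newick; trees without lengths are rejected because
every downstream metric needs them), a site environment table and site
coordinates.  Species and sites are matched by exact whitespace-trimmed
label; under the `drop` policy the label intersection is used, the tree is
pruned (path lengths between retained tips are preserved), and per-source
drop counts are reported.  Sites with zero richness are dropped with a
warning — diversity is undefined for them, and silently keeping empty rows
corrupts the beta-diversity denominators.

## Alpha diversity

Rao's quadratic entropy is computed as the full double sum over relative
abundances; in presence mode all present species get equal weight, so the
taxonomic variant (dᵢⱼ = 1) reduces to 1 − 1/S.  Faith's PD sums the
branch lengths of the subtree spanning the community's tips **including
the path to the root** — the common default in community-phylogenetics
software, and the convention that makes single-species communities carry
their root-to-tip distance rather than zero.  It is switchable
(`include_root=False`) because published analyses are split on it; the
choice is stamped into the pipeline manifest.  MPD and MNTD are unweighted
(presence-based) means over distinct pairs and nearest neighbours
respectively, and are reported as missing for communities with fewer than
two species.

## Null model and SES

The null shuffles species labels on the distance matrix (equivalently,
tree tips) while holding the occurrence matrix fixed.  This is the
least-assumption model that preserves observed site richness exactly;
occurrence-matrix randomisations (independent/trial swap) preserve
different margins and give different SES magnitudes, and are deliberately
out of scope.  One *shared* permutation is drawn per replicate across all
sites, so SES values are comparable within a replicate; a per-site variant
is available.  sd_null uses the sample (ddof = 1) convention; rank
p-values use (r+1)/(n+1) so no p is ever zero; a degenerate null (sd ≈ 0,
e.g. a site holding the whole pool) is flagged rather than producing ±∞.
Under neutral assembly at the default calibration size (500 communities of
10 species from a 60-species pool, 499 nulls) the |SES| > 1.96 rate sits
inside 3–8% and the mean SES inside ±0.2 — the acceptance suite recomputes
this every run.

## Beta diversity

The Sørensen family is used throughout: for a pair, sor = (b+c)/(2a+b+c),
sim = min(b,c)/(a+min(b,c)), sne = sor − sim; multiple-site values use the
Σmin/Σmax formulation over all pairs with K = Σᵢ totalᵢ − total_pooled.
The same algebra runs in three currencies: species counts; shared/unique
branch lengths of the spanning subtrees (so a + b = PD(site i), with the
same root convention as Faith's PD); and functional units.  The functional
default is **dendrogram mode** — branch algebra on the UPGMA tree of the
Gower distances — because it is deterministic, needs no axis-count choice
and is valid for mixed trait types.  Convex-hull mode (intersection /
unique hull volumes in the first k ≤ 3 PCoA axes of Gower space, Lingoes-
corrected) is provided for pairwise matrices; every community then needs
more than k species, and violations are a hard error pointing back to
dendrogram mode.  The multi-site functional summary always uses the
dendrogram, since a hull analogue would require union volumes over many
hulls.  The mode used is stamped into outputs because the two are not
numerically interchangeable.  Both the multi-site SOR and the mean of the
pairwise sor values are emitted, since "overall beta diversity" is
reported under either convention in the literature.

Turnover% and nestedness% are SIM/SOR and SNE/SOR × 100; additivity
sor = sim + sne holds to 1e-12 in every dimension and is asserted.

## Trait space

Gower dissimilarity: categorical traits contribute 0/1 mismatches,
continuous traits range-normalised absolute differences, ordinal traits
(e.g. flowering phenology months) are converted to average ranks first and
then range-normalised.  Missing values are handled by pairwise deletion
with weight renormalisation; a species pair sharing no trait is an error,
not a NaN.  Continuous traits with zero pool range are dropped with a
warning, and ranges are recomputed after any species drop so distances are
stable per bundle.  Weights default to equal.  The UPGMA dendrogram is
agglomerated explicitly with lexicographic tie-breaking so functional beta
is reproducible bit-for-bit; it matches average-linkage clustering to
numerical precision on tie-free inputs.

## Spatial and environmental predictors

PCNM: distances beyond the truncation threshold t (default: the largest
minimum-spanning-tree edge, the standard convention) are replaced by 4t;
the matrix is double-centred as in PCoA and eigendecomposed; only
positive-eigenvalue axes are exposed by default (positively autocorrelated
patterns), orthogonal and centred to stated tolerances.  Climate and soil
families are reduced by correlation-matrix PCA (variables standardised to
population SD first); axes with variance proportion above 0.10 are
retained, and axis signs are fixed so the largest-magnitude loading is
positive.  The inundation gradient enters models as the zone's inundation
days (68/112/152/204), standardised — a continuous coding; a categorical
option exists.  Environmental distance is Euclidean over the standardised
predictor table.

## Inference

Mantel r is the Pearson correlation of the n(n−1)/2 off-diagonal
elements; the null jointly permutes rows and columns of the second matrix;
p is one-tailed for positive association.  Partial Mantel uses the
residual-correlation method with permutation of the raw second matrix
(Legendre's method 1); residuals that are pure floating-point noise are
zeroed so exact collinearity yields r = 0.  Multiple testing across the
Mantel table is left uncorrected by default (mirroring how such tables are
usually starred), with a Holm option.

Variance partitioning regresses the positive-eigenvalue PCoA axes of the
beta matrix (db-RDA style response) on the predictor sets; adjusted R²
uses the Ezekiel correction with m = number of predictor columns.  The 15
Venn fractions of the four sets are recovered by solving the
inclusion–exclusion system exactly, so the fractions always sum to the
global adjusted R² (1e-10) and the residual is 1 − adjR²(all).  Negative
fractions are reported as-is — truncating them destroys the sum identity;
clamping is display-only.  Forward selection adds the largest
adjusted-R²-gain candidate, tests it by permuting response rows, and
stops when p > α or — beyond the first selected term — when the cumulative
adjusted R² would exceed the global model's (the scope rule is not applied
to the first term: a lone strong predictor among pure-noise candidates
has a higher adjusted R² than the noise-diluted global model, and
rejecting it would return an empty model in exactly the situation
selection exists for).

## Synthetic data generator

The generator emulates the study design the package targets, and its
defaults are the conditions the analyses are validated under:

- **Pool**: Yule tree (birth rate 1) with S tips; terminal branches
  extended by one shared exponential waiting time (tree stays
  ultrametric); the root stem is dropped (crown-group convention, 2S−2
  positive-length edges).
- **Traits**: shoot height lognormal around a Brownian latent (rate 1);
  flowering phenology an ordinal quantile-binning of a second Brownian
  trait; dispersal type / growth form / life cycle as symmetric k-state
  Markov chains (rate 0.3).  A third Brownian trait is the species'
  elevation optimum, linearly rescaled to 150–174 m — Brownian, so optima
  are phylogenetically conserved and environmental filtering produces
  phylogenetic clustering; a flag decouples optima from the tree to test
  the contrary case.
- **Landscape**: sites along a 1-D riverbank (100 km default) in chains
  of four zone sites, zones I–IV at 172.5/167.5/162.5/152.5 m (± 0.8 m)
  carrying 68/112/152/204 days of inundation; 11 soil variables load on a
  latent fertility factor that rises as elevation falls (organic matter
  and nutrients enrich downslope); MAT/MAP are smooth along-river
  gradients (around 18.22 °C and 1110 mm) plus noise.
- **Assembly**: occurrence weight ∝ exp(−(opt − elev)²/2σ²) ·
  exp(−d(centre, site)/λ); fixed per-site richness drawn without
  replacement by these weights, so the richness-preserving null matches
  the generative design.  `nested_loss` makes every community a prefix of
  one global species order (pairwise turnover exactly zero); `turnover`
  gives each zone a disjoint species block; `neutral` sets both kernels
  flat.
- **paperlike preset**: S = 166 species, N = 64 sites (16 per zone),
  mixed assembly with zone richness 18/14/11/8 and filtering breadth
  σ = 10/6/3.5/2 m from zone I to IV — diversity loss and intensifying
  filtering down the inundation gradient — plus dispersal λ = 30 km.

What the generator does *not* emulate: species interactions (so the
overdispersion that competition can cause at benign sites is out of
recovery scope), temporal dynamics, explicit hydrology, abundance
structure (scenarios are presence-based), and 2-D geography.  Passing
tests therefore show that the estimators recover the processes they claim
to measure under these idealised conditions — not that any particular
field pattern must arise.

## Problem sizes and determinism

Default validation sizes: calibration uses 500 neutral communities with
499 nulls and 500 independent-noise Mantel runs at n = 15 with 99
permutations; ground-truth checks use the preset scenarios (32 sites,
60–80 species, 300–499 nulls); the study-scale pipeline runs 166 species ×
64 sites with 1000 nulls and 199–999 permutations and completes in
seconds.  Every stochastic stage takes an explicit seed; a pipeline run is
byte-reproducible given (inputs, config, seed), and the manifest records
every convention listed above.

## Known limitations

- Hull-mode functional beta has no multi-site summary and requires k+1
  species per site.
- The label-shuffle null is the only null family; occurrence-matrix swaps
  are intentionally out of scope.
- Sørensen-family (presence/absence) beta only; no Jaccard or
  abundance-based (Bray–Curtis) decomposition.
- PCNM axis selection is by eigenvalue sign only (no Moran's-I screening);
  forward selection over the axes is available but off by default.
- Quadrat pooling is left to the user: each input row is treated as one
  community.
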