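# Methods

`assemblyscope` quantifies how a set of microbial communities was assembled:
how much of the turnover between samples is due to selection (deterministic
environmental filtering), dispersal (limitation or homogenization), and drift.
It bundles the analyses that a gut-microbiome habitat-comparison study runs on
an OTU table — alpha/beta diversity, the Sloan neutral community model, AVD
community stability, betaNTI/RC_Bray process partitioning, Levins niche
breadth, indicator species, and correlation networks — together with a
synthetic-community generator that gives every statistic a known ground truth.

## Data model and conventions

OTUs are rows, samples are columns, everywhere. Count tables are TSV with a
`#OTU_ID` header; trees are Newick with branch lengths; metadata and
environment tables are TSV keyed by `sample_id`. Relative abundances come from
total-sum scaling; no rarefaction is applied by default because the analyses
here either operate on proportions or condition on read depth, but
`rarefy(counts, depth, seed)` (and `rarefy_depth` in the pipeline config) is
available for sensitivity checks. OTU ids missing from the tree raise an
error; `Phylogeny.prune_to` performs explicit pruning with a logged count.

## The synthetic generator

The generator realizes the processes the downstream statistics are meant to
detect, at the scale used throughout the calibration experiments (500 taxa, 30
samples, 1000 reads per sample unless a specific experiment says otherwise):

- **Source pool.** Relative abundances follow a Fisher log-series (shape
  0.999), the classic neutral-theory abundance distribution for a large
  metacommunity; both the distribution and its parameter are configurable.
- **Neutral assembly** (`simulate_neutral_communities`). Each sample is an
  individual-based Moran community of N individuals: a death-replacement
  process in which each replacement is an immigrant drawn from the pool with
  probability m, otherwise the offspring of a uniformly chosen local
  individual. The burn-in defaults to `max(10, ceil(3/m)) * N` events because
  the chain relaxes to its stationary composition on the immigration
  timescale of ~N/m events; a migration-independent burn-in visibly
  under-equilibrates at m = 0.1. At m = 1 the process reduces exactly to a
  multinomial draw from the pool.
- **Habitat filtering** (`simulate_filtered_communities`). Sampling weights
  are `p_i * exp(-(t_i - e)^2 / (2 w^2))` with traits t simulated by Brownian
  motion on the tree (variance 1 per unit branch length) or supplied; small w
  is strong filtering, w -> infinity recovers the neutral multinomial.
- **Dispersal limitation** (`make_group_subpools`). Each group draws from its
  own sub-pool of the metacommunity; a configurable fraction of taxa forms a
  shared core. The three-habitat study (`simulate_three_habitat_study`) uses
  two fully separate river pools (overlap 0) and one panmictic pond: with
  partial overlap the regime is only *sometimes* dispersal-limited, because
  whether the log-series dominants land in the shared core is a coin flip per
  realization, and when they do the between-river contrast vanishes.
- **Environment tables.** Per-sample values are Normal(group mean, sd) for
  TEM (deg C), DO (mg/L), pH, TN and TP (mg/L), with group-level mean
  differences mirroring a warm eutrophic pond vs cooler, better-oxygenated
  rivers.

What the generator does **not** emulate: sequencing error, chimeras, copy-
number variation, compositional read-depth artifacts, or within-host dynamics.
Passing calibration here shows the statistics behave correctly under their own
model assumptions — not that any particular real dataset satisfies them.

## Core statistics

**Sloan neutral community model.** For each OTU, the mean relative abundance
p and the occurrence frequency f (fraction of samples where detected) are
computed; the neutral prediction is `P[Beta(N_T m p, N_T m (1-p)) > d]` with
N_T the mean read depth and detection limit d = 1/N_T (both configurable). m
is fit by bounded least squares on (1e-6, 1]; R^2 = 1 - SSE/SST may be
negative and is reported as-is. The 95% band around the fitted curve uses
Wilson binomial intervals at n = number of samples; OTUs are partitioned
above/within/below the band. *Known bias:* with N_T = 1000 and a log-series
community, the threshold-detection approximation (`P[x > d]` vs the exact
finite-community presence probability) inflates fitted Nm by ~25% even on
exactly stationary communities, and the finite-m Moran correction
I = m(N-1)/(1-m) adds ~10% at m = 0.1; the calibration experiment therefore
recovers m = 0.1 as ~0.14. The R^2 contrast (neutral >> filtered) is
unaffected.

**AVD.** Within each group, each OTU with nonzero variance contributes
|x - mu|/sigma (sd with denominator k-1); a sample's AVD is the mean over
contributing OTUs, a group's AVD the mean over its samples. Lower AVD = more
stable. Constant OTUs are dropped and counted; sd below 1e-12 counts as
constant (float residue).

**betaMNTD / betaNTI.** betaMNTD(j,k) is the abundance-weighted mean distance
from each taxon to its nearest relative in the other sample (weights are
relative abundances; an unweighted presence-based variant is available). The
null shuffles taxon positions across all tips of the tree, leaving abundances
untouched — equivalently a simultaneous row/column permutation of the
patristic distance matrix, which makes 999 draws cheap. betaNTI is the
z-score; pairs with null sd = 0 (e.g. identical samples) are flagged
degenerate, given betaNTI = 0, and excluded from partition denominators.
betaNTI is invariant to rescaling all branch lengths.

**RC_Bray.** Null communities preserve each sample's richness and read total:
taxa are chosen without replacement with probability proportional to
occupancy, each chosen taxon receives one read, and the remainder is
multinomial with mean-relative-abundance weights. Draws are made per sample
per replicate (samples are independent under this null) and Bray-Curtis is
computed for all pairs in the replicate — marginally identical to per-pair
assembly at a fraction of the cost. RC = 2*(fraction of null BC below
observed, ties counting half) - 1, clamped to [-1, 1]. *Caveat:* this null is
not the multinomial sampling process; on plain multinomial communities most
pairs exceed |RC| > 0.95. The metric is calibrated against its own null (the
self-calibration experiment iterates the null generator to its weight fixed
point and finds ~5-8% exceedance), and its role in the partition is the
conventional one.

**Process partition.** betaNTI > 2 -> heterogeneous selection; < -2 ->
homogeneous selection; otherwise RC > 0.95 -> dispersal limitation,
RC < -0.95 -> homogenizing dispersal, |RC| <= 0.95 -> undominated (drift and
weak processes). Thresholds are inclusive toward the weaker class and
configurable. Fractions sum to 1 over non-degenerate pairs.

**Levins niche breadth.** B = 1/sum(q^2) over the OTU's distribution across
samples, computed from column-normalized tables so depth differences do not
masquerade as niche signal. Classification compares B to 2.5/97.5 percentiles
of its distribution under independent fixed-fixed tables (Patefield's
algorithm, the classical `r2dtable` null, equivalent to shuffling read-level
sample labels). A swap-chain null was rejected during development: its mixing
time scales with total reads and fails calibration on structured tables.
Group-level niche breadth for group comparisons is computed within group
subsets (`niche_breadth_by_group`), with the global table as the
classification default.

**IndVal.** Classical Dufrene-Legendre: specificity A (group share of the
OTU's mean abundance), fidelity B (occurrence fraction within the group),
IndVal = A*B on [0, 1]. The permutation test permutes group labels and
compares each OTU's max-over-groups IndVal; p = (exceedances + 1)/(n_perm+1).

**Networks.** Spearman correlations (average ranks for ties, two-sided t
approximation) among OTUs passing a 20% prevalence filter (double-zero
protection; configurable). BH adjustment spans all pairs; default edge
thresholds |rho| >= 0.8 and q < 0.001 — the adjusted q is thresholded because
the FDR step exists to suppress false positives; `use_q=False` reproduces a
raw-p reading. Weighted degree uses |rho| weights; betweenness is computed on
the binarized graph, normalized. Taxa-environment networks correlate
aggregated taxa with z-scored environment variables, skip constant variables,
and BH-adjust across all taxon-by-variable tests.

**PERMANOVA.** Implemented directly from the distance-based sum-of-squares
decomposition so the result carries R^2 and the (count + 1)/(n_perm + 1)
p-value convention; the scikit-bio implementation serves as an independent
cross-check in the tests. NMDS is non-metric (Kruskal stress-1) with 20
random restarts and a fixed seed.

## Reproducibility

Every stochastic routine takes an explicit seed; the pipeline spawns a named
substream per stage from one master seed (`numpy.random.SeedSequence`), so
adding a stage never perturbs earlier stages' draws, and re-running with the
same seed is bit-identical. The pipeline writes a `report.json` validated
against `report_schema.json` (a small built-in validator covers the schema
subset used).

## Calibration experiments and their scales

`assemblyscope.calibration` contains the experiments run by both the test
suite and `scripts/acceptance.py`. Problem sizes were chosen so each
experiment carries statistical weight while the full battery completes in
well under a minute on one core: NCM recovery at the generator's default
scale over 10 seeds; betaNTI null calibration over 5 trees x 190 pairs with
199 nulls; RC self-calibration over 3 seeds x 190 pairs; the homogeneous-
selection control over 4 replicates of 12 samples on 800-tip trees (the
supplied trait is patristic distance to an anchor taxon — perfect niche
conservatism — because a scalar Brownian trait band yields only intermediate
clustering, betaNTI ~ -1 to -2, a finding worth knowing when interpreting
field data); the dispersal control on two disjoint 8-sample groups; type-I
error over 500 null simulations with 99 permutations each.

## Known limitations

- The NCM migration-rate estimate carries the ~+30-40% bias described above
  at moderate read depths; treat fitted m as an index, not an unbiased rate.
- RC_Bray values are meaningful relative to the occupancy-based null, not as
  absolute dissimilarity probabilities.
- The tip-shuffle betaNTI null assumes the tree is exchangeable across taxa;
  strongly unbalanced trees with few deep clades weaken its power.
- No compositional (log-ratio) correction is applied in the network module;
  proportional data can induce spurious negative correlations among dominant
  taxa.
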