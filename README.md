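# assemblyscope

Community-assembly analysis for microbiome OTU tables: who shaped the
community — selection, dispersal, or drift?

Comparative microbiome studies (for example, fish gut communities sampled
from different river and pond habitats) routinely ask whether differences
between habitats reflect deterministic environmental filtering or stochastic
processes. `assemblyscope` implements the full analysis battery such studies
run, as one tested Python package:

- **Diversity**: observed richness, bias-corrected Chao1, ACE, Faith's PD;
  Bray-Curtis and unweighted/weighted UniFrac distances; NMDS ordination;
  PERMANOVA with R² and permutation p-values; shared/unique OTU (Venn)
  summaries.
- **Assembly (the core)**: the Sloan neutral community model (NCM) — fitting
  the migration rate *m* so that `P[Beta(N_T m p, N_T m (1−p)) > d]` matches
  each taxon's occurrence frequency, with R² as the neutrality score; AVD
  community stability; βMNTD/βNTI phylogenetic turnover against a tip-shuffle
  null; Raup-Crick on Bray-Curtis (RC); and the five-process partition
  (βNTI > 2 heterogeneous selection, βNTI < −2 homogeneous selection, then
  RC > 0.95 dispersal limitation, RC < −0.95 homogenizing dispersal,
  |RC| ≤ 0.95 undominated).
- **Niche**: Levins' niche breadth B = 1/Σq² with generalist/specialist
  calls against an exact fixed-fixed (Patefield/r2dtable) null.
- **Indicators**: Dufrêne-Legendre IndVal = specificity × fidelity with a
  group-label permutation test.
- **Networks**: Spearman co-occurrence networks with BH-FDR thresholds
  (|ρ| ≥ 0.8, q < 0.001 by default) and taxa-environment bipartite edges.
- **Synthetic communities**: an individual-based neutral (Moran) generator
  with tunable migration, Gaussian trait-environment filtering on a
  phylogeny, group-specific source pools for dispersal limitation, and
  environment tables — so every statistic can be validated against a known
  generating process.

See `docs/methods.md` for the models, defaults, numerical choices and known
limitations.

## Worked example

Simulate a three-habitat study — two river groups (DJ, XJ) drawing from
separate source pools (dispersal limitation) and one panmictic pond group
(PC), all assembling neutrally within habitat — then ask the package which
processes it detects:

```python
from assemblyscope import (simulate_three_habitat_study, to_relative_abundance,
                           fit_ncm, turnover_pairs, partition_processes,
                           compute_avd)

study = simulate_three_habitat_study(seed=7, n_taxa=150, n_per_group=10,
                                     reads=1000)
counts, tree, groups = study.counts, study.tree, study.groups

fit = fit_ncm(counts)
print(f"NCM: m = {fit.m:.3f}, Nm = {fit.Nm:.0f}, R2 = {fit.R2:.3f}")

avd = compute_avd(to_relative_abundance(counts), groups)
print("AVD by group:", {g: round(v, 3) for g, v in avd.per_group.items()})

pairs = turnover_pairs(counts, tree, n_null=199, seed=7)
label = dict(groups.mapping)
wild = pairs[pairs.sample_a.map(label).isin({"DJ", "XJ"})
             & pairs.sample_b.map(label).isin({"DJ", "XJ"})]
part = partition_processes(wild)
for k, v in part.fractions.items():
    print(f"  {k:24s} {v:.3f}")
print("stochastic fraction:", round(part.stochastic_fraction, 3))
```

Output:

```
NCM: m = 0.049, Nm = 49, R2 = 0.580
AVD by group: {'DJ': 0.719, 'XJ': 0.714, 'PC': 0.702}
  heterogeneous_selection  0.058
  homogeneous_selection    0.000
  dispersal_limitation     0.511
  homogenizing_dispersal   0.395
  undominated              0.037
stochastic fraction: 0.942
```

Read: the pooled table is moderately neutral (R² = 0.58 — the mixed pools
depress the fit relative to a single-pool community); group stability (AVD)
is similar across habitats; and among the wild-river pairs the partition is
overwhelmingly stochastic (0.94), split between dispersal limitation (the
between-river pairs, 0.51) and homogenizing dispersal (the within-river
pairs, 0.40) — exactly the regime the generator was told to produce.

The same analysis is available from the shell:

```bash
assemblyscope simulate --regime dispersal --seed 7 --out study/
assemblyscope assembly --counts study/counts.tsv --tree study/tree.nwk \
    --metadata study/metadata.tsv --n-null 199 --seed 7 --out results/
assemblyscope run --config run.yaml     # full five-stage pipeline + report.json
```

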