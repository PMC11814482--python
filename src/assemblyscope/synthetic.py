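"""Synthetic community generator with known assembly regimes.

Every downstream statistic in this package is exercised against tables whose
generating process is known: a neutral metacommunity sampled through a Hubbell
/ Sloan death-replacement process with migration rate ``m``, habitat filtering
through Gaussian trait-environment matching with phylogenetically conserved
(Brownian) traits, dispersal limitation through group-specific source pools,
and a small environment table with group-level mean differences.
"""

from __future__ import annotations

import io
import random as _pyrandom
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from skbio import TreeNode

from .core_io import CountMatrix, EnvTable, GroupMap, Phylogeny

__all__ = [
    "SourcePool",
    "SimConfig",
    "log_series_pool",
    "random_phylogeny",
    "brownian_traits",
    "simulate_neutral_communities",
    "simulate_filtered_communities",
    "simulate_env_table",
    "make_group_subpools",
    "simulate_three_habitat_study",
]


@dataclass
class SourcePool:
    """Source metacommunity: taxon ids, relative abundances, optional trait values."""

    taxon_ids: list
    p: np.ndarray
    traits: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.taxon_ids = list(map(str, self.taxon_ids))
        p = np.asarray(self.p, dtype=float)
        if (p <= 0).any():
            raise ValueError("pool abundances must be strictly positive")
        if abs(p.sum() - 1.0) > 1e-12:
            p = p / p.sum()
        if len(p) != len(self.taxon_ids):
            raise ValueError("taxon_ids and p length mismatch")
        self.p = p
        if self.traits is not None:
            self.traits = np.asarray(self.traits, dtype=float)
            if self.traits.shape != p.shape:
                raise ValueError("traits must match pool size")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)


@dataclass
class SimConfig:
    """Study-scale simulation settings.

    Defaults mirror the scale used throughout the calibration experiments:
    500 taxa, 30 samples per group, 1000 reads per sample, migration rate 0.1,
    filtering width 1.0 (trait units). The burn-in defaults to
    ``max(10, ceil(3/m)) * N`` replacement events: the local community relaxes
    to its stationary composition on the immigration timescale of about N/m
    events, so a migration-independent burn-in under-equilibrates at small m.
    """

    n_taxa: int = 500
    n_samples: int = 30
    reads: int = 1000
    m: float = 0.1
    w: float = 1.0
    burnin_factor: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_taxa", "n_samples", "reads"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.m <= 1):
            raise ValueError("migration rate m must lie in (0, 1]")
        if self.w <= 0:
            raise ValueError("filtering width w must be positive")
        if self.burnin_factor is None:
            self.burnin_factor = max(10, int(np.ceil(3.0 / self.m)))
        if self.burnin_factor <= 0:
            raise ValueError("burnin_factor must be positive")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def log_series_pool(n_taxa: int, seed: int, logseries_p: float = 0.999) -> SourcePool:
    """Source pool with Fisher log-series abundances (classic neutral-theory SAD)."""
    rng = np.random.default_rng(seed)
    abund = rng.logseries(logseries_p, size=n_taxa).astype(float)
    ids = [f"OTU{i:04d}" for i in range(n_taxa)]
    return SourcePool(ids, abund / abund.sum())


def random_phylogeny(taxon_ids, seed: int, birth_rate: float = 1.0) -> Phylogeny:
    """Random pure-birth (Yule) tree over ``taxon_ids``, branch lengths in time units."""
    taxon_ids = list(taxon_ids)
    t = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=len(taxon_ids),
        rng=_pyrandom.Random(int(seed)),
    )
    for leaf, name in zip(t.leaf_node_iter(), taxon_ids):
        leaf.taxon.label = name
    newick = t.as_string(schema="newick", suppress_rooting=True)
    return Phylogeny(TreeNode.read(io.StringIO(newick), format="newick"))


def brownian_traits(phy: Phylogeny, seed: int, sigma2: float = 1.0) -> pd.Series:
    """Brownian-motion trait values on the tree (variance ``sigma2`` per unit branch)."""
    rng = np.random.default_rng(seed)
    values = {id(phy.tree): 0.0}
    for node in phy.tree.preorder(include_self=False):
        parent_val = values[id(node.parent)]
        bl = node.length or 0.0
        values[id(node)] = parent_val + rng.normal(0.0, np.sqrt(sigma2 * bl))
    return pd.Series({t.name: values[id(t)] for t in phy.tree.tips()})


def _moran_sample(pool_p: np.ndarray, n_reads: int, m: float, burnin: int,
                  rng: np.random.Generator) -> np.ndarray:
    """One local community: death-replacement with immigration probability m.

    The community is an array of individual taxon labels; each event kills a
    uniformly chosen individual and replaces it with an immigrant from the pool
    (probability m) or the offspring of a uniformly chosen local individual.
    """
    n_taxa = len(pool_p)
    cdf = np.cumsum(pool_p)
    comm = np.searchsorted(cdf, rng.random(n_reads))  # start from the pool
    deaths = rng.integers(0, n_reads, size=burnin)
    births = rng.integers(0, n_reads, size=burnin)
    migrate = rng.random(burnin) < m
    immigrants = np.searchsorted(cdf, rng.random(burnin))
    for t in range(burnin):
        if migrate[t]:
            comm[deaths[t]] = immigrants[t]
        else:
            comm[deaths[t]] = comm[births[t]]
    return np.bincount(comm, minlength=n_taxa)


def simulate_neutral_communities(pool: SourcePool, cfg: SimConfig,
                                 sample_prefix: str = "S") -> CountMatrix:
    """Neutral local communities under the Sloan migration model.

    Each sample holds ``cfg.reads`` individuals evolved by death-replacement
    for ``cfg.burnin_factor * reads`` events; replacements immigrate from the
    pool with probability ``cfg.m``, otherwise reproduce locally.
    """
    if not (0 < cfg.m <= 1):
        raise ValueError("migration rate m must lie in (0, 1]")
    rng = np.random.default_rng(cfg.seed)
    burnin = cfg.burnin_factor * cfg.reads
    cols = [
        _moran_sample(pool.p, cfg.reads, cfg.m, burnin, rng)
        for _ in range(cfg.n_samples)
    ]
    sample_ids = [f"{sample_prefix}{j:03d}" for j in range(cfg.n_samples)]
    return CountMatrix(pool.taxon_ids, sample_ids, np.column_stack(cols))


def simulate_filtered_communities(pool: SourcePool, tree: Phylogeny | None,
                                  env: np.ndarray, cfg: SimConfig,
                                  sample_prefix: str = "S") -> CountMatrix:
    """Habitat-filtered communities: multinomial with Gaussian trait matching.

    Sample with environment value ``e`` draws ``cfg.reads`` reads with weights
    proportional to ``p_i * exp(-(t_i - e)^2 / (2 w^2))``; traits come from the
    pool or are simulated by Brownian motion on ``tree``. Small ``w`` means
    strong filtering; ``w -> inf`` recovers a neutral multinomial.
    """
    if cfg.w <= 0:
        raise ValueError("filtering width w must be positive")
    env = np.asarray(env, dtype=float)
    if env.shape != (cfg.n_samples,):
        raise ValueError("env must provide one value per sample")
    if pool.traits is not None:
        traits = pool.traits
    else:
        if tree is None:
            raise ValueError("need either pool.traits or a tree to simulate traits")
        tr = brownian_traits(tree, seed=cfg.seed + 1)
        traits = tr.loc[pool.taxon_ids].to_numpy()
    rng = np.random.default_rng(cfg.seed)
    cols = []
    for e in env:
        logw = np.log(pool.p) - (traits - e) ** 2 / (2.0 * cfg.w**2)
        logw -= logw.max()
        wgt = np.exp(logw)
        cols.append(rng.multinomial(cfg.reads, wgt / wgt.sum()))
    sample_ids = [f"{sample_prefix}{j:03d}" for j in range(cfg.n_samples)]
    return CountMatrix(pool.taxon_ids, sample_ids, np.column_stack(cols))


def simulate_env_table(groups: GroupMap, group_means: dict, sd: float,
                       seed: int) -> EnvTable:
    """Environment table with Normal(group mean, sd) values per sample.

    ``group_means`` maps variable name -> {group label -> mean}.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    variables = list(group_means)
    for var, means in group_means.items():
        unknown = set(groups.groups()) - set(means)
        if unknown:
            raise ValueError(
                f"variable {var!r} has no mean for group(s): {', '.join(sorted(unknown))}"
            )
    data = {
        var: [
            rng.normal(group_means[var][groups.mapping[s]], sd)
            for s in groups.sample_ids
        ]
        for var in variables
    }
    return EnvTable(pd.DataFrame(data, index=groups.sample_ids))


def make_group_subpools(pool: SourcePool, n_groups: int, overlap: float,
                        seed: int) -> list:
    """Dispersal limitation via group-specific sub-pools.

    A fraction ``overlap`` of taxa form a shared core available to every group;
    the remaining taxa are partitioned exclusively among groups. Abundances are
    renormalized within each sub-pool.
    """
    if not (0 <= overlap <= 1):
        raise ValueError("overlap must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = pool.n_taxa
    order = rng.permutation(n)
    n_core = int(round(overlap * n))
    core = set(order[:n_core].tolist())
    exclusive = np.array_split(order[n_core:], n_groups)
    pools = []
    for g in range(n_groups):
        members = sorted(core | set(exclusive[g].tolist()))
        idx = np.array(members, dtype=int)
        traits = pool.traits[idx] if pool.traits is not None else None
        pools.append(
            SourcePool(
                [pool.taxon_ids[i] for i in idx],
                pool.p[idx] / pool.p[idx].sum(),
                traits,
            )
        )
    return pools


def _embed_counts(counts: CountMatrix, all_taxa, sample_ids) -> np.ndarray:
    """Lift a sub-pool count table onto the full taxon list (zeros elsewhere)."""
    out = np.zeros((len(all_taxa), len(sample_ids)), dtype=np.int64)
    row = {t: i for i, t in enumerate(all_taxa)}
    for i, t in enumerate(counts.otu_ids):
        out[row[t], :] = counts.counts[i, :]
    return out


@dataclass
class StudyData:
    """Bundle returned by :func:`simulate_three_habitat_study`."""

    counts: CountMatrix
    tree: Phylogeny
    groups: GroupMap
    env: EnvTable
    pool: SourcePool
    config: SimConfig


def simulate_three_habitat_study(
    seed: int,
    n_taxa: int = 150,
    n_per_group: int = 10,
    reads: int = 1000,
    m: float = 0.1,
    overlap: float = 0.0,
    group_labels=("DJ", "XJ", "PC"),
) -> StudyData:
    """Three-habitat study: two dispersal-limited wild groups and one panmictic pond.

    The wild groups (first two labels) draw from largely disjoint sub-pools
    (shared core fraction ``overlap``), emulating between-river dispersal
    limitation; the pond group draws from the full metacommunity. All groups
    assemble neutrally within habitat. The environment table carries
    group-level mean differences in TEM, DO, pH, TN, TP.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(8)]
    pool = log_series_pool(n_taxa, seeds[0])
    tree = random_phylogeny(pool.taxon_ids, seeds[1])
    wild_pools = make_group_subpools(pool, 2, overlap, seeds[2])
    sub_pools = [wild_pools[0], wild_pools[1], pool]

    blocks, sample_ids, mapping = [], [], {}
    for g, (label, sub) in enumerate(zip(group_labels, sub_pools)):
        cfg = SimConfig(
            n_taxa=sub.n_taxa, n_samples=n_per_group, reads=reads, m=m,
            seed=seeds[3 + g],
        )
        tbl = simulate_neutral_communities(sub, cfg, sample_prefix=f"{label}_")
        blocks.append(_embed_counts(tbl, pool.taxon_ids, tbl.sample_ids))
        sample_ids += tbl.sample_ids
        mapping.update({s: label for s in tbl.sample_ids})

    counts = CountMatrix(pool.taxon_ids, sample_ids, np.hstack(blocks)).drop_empty_otus()
    groups = GroupMap(mapping)
    group_means = {
        "TEM": {group_labels[0]: 26.0, group_labels[1]: 25.0, group_labels[2]: 28.0},
        "DO": {group_labels[0]: 6.5, group_labels[1]: 7.5, group_labels[2]: 5.0},
        "pH": {group_labels[0]: 7.2, group_labels[1]: 7.6, group_labels[2]: 8.1},
        "TN": {group_labels[0]: 1.8, group_labels[1]: 0.9, group_labels[2]: 2.6},
        "TP": {group_labels[0]: 0.12, group_labels[1]: 0.06, group_labels[2]: 0.25},
    }
    env = simulate_env_table(groups, group_means, sd=0.3, seed=seeds[6])
    cfg = SimConfig(n_taxa=n_taxa, n_samples=n_per_group, reads=reads, m=m, seed=seed)
    return StudyData(counts, tree, groups, env, pool, cfg)
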