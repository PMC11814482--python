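"""Alpha diversity, distance matrices, NMDS ordination, PERMANOVA and OTU overlap.

Alpha estimators (observed richness, bias-corrected Chao1, ACE) and the two
UniFrac variants are delegated to scikit-bio; Bray-Curtis is computed on
total-sum-scaled proportions; PERMANOVA is implemented directly so the report
carries the R-squared and the +1/+1 permutation p-value convention.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import ace, chao1, observed_features
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd
from sklearn.manifold import MDS

from .core_io import CountMatrix, GroupMap, Phylogeny, RelAbundanceMatrix

__all__ = [
    "alpha_diversity",
    "faith_pd",
    "bray_curtis_matrix",
    "unifrac_matrix",
    "nmds",
    "permanova",
    "PermanovaResult",
    "shared_unique_otus",
]

_ALPHA_METRICS = {
    "sobs": lambda c: float(observed_features(c)),
    "chao1": lambda c: float(chao1(c, bias_corrected=True)),
    "ace": lambda c: float(ace(c, rare_threshold=10)),
}


def alpha_diversity(counts: CountMatrix, metric: str) -> pd.Series:
    """Per-sample alpha diversity: ``sobs``, ``chao1`` (bias-corrected) or ``ace``.

    Requires integer counts; abundance-based richness estimators are undefined
    on proportions.
    """
    if metric not in _ALPHA_METRICS:
        raise ValueError(f"unknown alpha metric {metric!r}; choose from {sorted(_ALPHA_METRICS)}")
    fn = _ALPHA_METRICS[metric]
    values = {}
    for j, sid in enumerate(counts.sample_ids):
        col = counts.counts[:, j]
        if col.sum() == 0:
            raise ValueError(f"sample {sid!r} has zero total count")
        values[sid] = fn(col)
    return pd.Series(values, name=metric)


def faith_pd(counts: CountMatrix, tree: Phylogeny) -> pd.Series:
    """Faith's phylogenetic diversity: branch length of the subtree spanning
    each sample's present tips and the root."""
    tree.check_covers(counts.otu_ids)
    values = {}
    for j, sid in enumerate(counts.sample_ids):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            values[sid] = float(
                _skbio_faith_pd(counts.counts[:, j], taxa=counts.otu_ids, tree=tree.tree)
            )
    return pd.Series(values, name="faith_pd")


def bray_curtis_matrix(rel: RelAbundanceMatrix) -> DistanceMatrix:
    """Bray-Curtis dissimilarity on proportions: BC(j,k) = 1 - sum_i min(x_ij, x_ik)."""
    d = pdist(rel.rel.T, metric="braycurtis")
    return DistanceMatrix(squareform(d), ids=rel.sample_ids)


def unifrac_matrix(counts: CountMatrix, tree: Phylogeny, weighted: bool,
                   normalized: bool = True) -> DistanceMatrix:
    """Unweighted or (normalized) weighted UniFrac between all sample pairs."""
    tree.check_covers(counts.otu_ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if weighted:
            return beta_diversity(
                "weighted_unifrac", counts.counts.T, ids=counts.sample_ids,
                taxa=counts.otu_ids, tree=tree.tree, normalized=normalized,
            )
        return beta_diversity(
            "unweighted_unifrac", counts.counts.T, ids=counts.sample_ids,
            taxa=counts.otu_ids, tree=tree.tree,
        )


def nmds(dist: DistanceMatrix, k: int = 2, seed: int = 0, n_starts: int = 20,
         max_iter: int = 300) -> tuple:
    """Non-metric multidimensional scaling (Kruskal stress-1, monotone regression).

    Runs ``n_starts`` random initializations and keeps the configuration with
    the lowest stress-1. Returns ``(coordinates DataFrame, stress)``.
    """
    n = len(dist.ids)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of samples ({n})")
    model = MDS(
        n_components=k, metric_mds=False, metric="precomputed", n_init=n_starts,
        max_iter=max_iter, random_state=seed, normalized_stress=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = model.fit_transform(dist.data)
    df = pd.DataFrame(coords, index=dist.ids, columns=[f"NMDS{i + 1}" for i in range(k)])
    return df, float(model.stress_)


@dataclass
class PermanovaResult:
    """Distance-based PERMANOVA decomposition (Anderson)."""

    df: int
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int

    def as_dict(self) -> dict:
        return {
            "df": self.df, "pseudo_F": self.pseudo_F, "R2": self.R2,
            "p_value": self.p_value, "n_permutations": self.n_permutations,
        }


def _permanova_f(d2: np.ndarray, group_idx: list, n: int) -> tuple:
    """Pseudo-F and R2 from squared distances and per-group sample indices."""
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for idx in group_idx:
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    ss_between = ss_total - ss_within
    a = len(group_idx)
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return f, ss_between / ss_total


def permanova(dist: DistanceMatrix, groups: GroupMap, n_perm: int = 999,
              seed: int = 0) -> PermanovaResult:
    """PERMANOVA with label permutations; p = (#perm F >= observed + 1) / (n_perm + 1)."""
    ids = list(dist.ids)
    labels = np.asarray(groups.labels_for(ids))
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    for g in uniq:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    n = len(ids)
    d2 = np.asarray(dist.data, dtype=float) ** 2
    group_idx = [np.flatnonzero(labels == g) for g in uniq]
    f_obs, r2 = _permanova_f(d2, group_idx, n)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        perm_idx = [perm[idx] for idx in group_idx]
        f_perm, _ = _permanova_f(d2, perm_idx, n)
        if f_perm >= f_obs:
            n_ge += 1
    p = (n_ge + 1) / (n_perm + 1)
    return PermanovaResult(len(uniq) - 1, float(f_obs), float(r2), float(p), n_perm)


def shared_unique_otus(counts: CountMatrix, groups: GroupMap) -> pd.DataFrame:
    """Venn-style OTU overlap: counts and union percentages per intersection region.

    An OTU belongs to a group if its summed count in that group is > 0; each
    observed OTU falls in exactly one region (its exact membership pattern), so
    region counts sum to the number of observed OTUs.
    """
    labels = groups.groups()
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    presence = {}
    for g in labels:
        idx = [counts.sample_ids.index(s) for s in groups.samples_in(g)
               if s in counts.sample_ids]
        presence[g] = counts.counts[:, idx].sum(axis=1) > 0
    any_present = np.logical_or.reduce(list(presence.values()))
    total = int(any_present.sum())
    rows = []
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            mask = np.ones(len(counts.otu_ids), dtype=bool)
            for g in labels:
                mask &= presence[g] if g in combo else ~presence[g]
            n = int(mask.sum())
            rows.append({
                "region": "&".join(combo),
                "n_otus": n,
                "pct_of_union": 100.0 * n / total if total else 0.0,
            })
    return pd.DataFrame(rows).set_index("region")
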