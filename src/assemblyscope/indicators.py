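"""Indicator-species analysis (Dufrene-Legendre IndVal) with permutation tests.

For OTU i and group g, specificity A is the group's share of the OTU's mean
abundance across groups, fidelity B is the fraction of the group's samples
where the OTU occurs, and IndVal = A * B on [0, 1]. Significance is assessed
by permuting group labels and comparing each OTU's best (max-over-groups)
IndVal to its permutation distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GroupMap, RelAbundanceMatrix

__all__ = ["IndValResult", "indval_scores", "indval_test"]


@dataclass
class IndValResult:
    """IndVal components per OTU x group plus optional permutation p-values."""

    A: pd.DataFrame          # specificity, rows OTUs, columns groups
    B: pd.DataFrame          # fidelity
    indval: pd.DataFrame     # A * B
    p: pd.Series | None = None
    n_perm: int | None = None

    def best_group(self) -> pd.Series:
        return self.indval.idxmax(axis=1)

    def table(self) -> pd.DataFrame:
        out = pd.concat(
            {"A": self.A, "B": self.B, "indval": self.indval}, axis=1
        )
        out.columns = [f"{stat}_{g}" for stat, g in out.columns]
        out["best_group"] = self.best_group()
        out["max_indval"] = self.indval.max(axis=1)
        if self.p is not None:
            out["p_value"] = self.p
        return out


def _indval_components(x: np.ndarray, group_cols: list) -> tuple:
    """A, B, IndVal arrays (n_otus x n_groups) from abundance columns per group."""
    means = np.column_stack([x[:, idx].mean(axis=1) for idx in group_cols])
    pres = np.column_stack([(x[:, idx] > 0).mean(axis=1) for idx in group_cols])
    totals = means.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(totals > 0, means / totals, 0.0)
    return a, pres, a * pres


def indval_scores(rel: RelAbundanceMatrix, groups: GroupMap) -> IndValResult:
    """IndVal = specificity x fidelity for every OTU x group (no p-values).

    OTUs absent from every sample score 0 in all groups.
    """
    labels = groups.groups()
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    group_cols = [
        np.array([rel.sample_ids.index(s) for s in groups.samples_in(g)
                  if s in rel.sample_ids])
        for g in labels
    ]
    if any(len(idx) == 0 for idx in group_cols):
        raise ValueError("every group needs at least one sample in the table")
    a, b, iv = _indval_components(rel.rel, group_cols)
    index = pd.Index(rel.otu_ids, name="otu_id")
    return IndValResult(
        A=pd.DataFrame(a, index=index, columns=labels),
        B=pd.DataFrame(b, index=index, columns=labels),
        indval=pd.DataFrame(iv, index=index, columns=labels),
    )


def indval_test(rel: RelAbundanceMatrix, groups: GroupMap, n_perm: int = 999,
                seed: int = 0) -> IndValResult:
    """IndVal with a group-label permutation test.

    p per OTU = (#permutations whose max-over-groups IndVal >= observed + 1)
    / (n_perm + 1); reproducible under the seed.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    labels = groups.groups()
    for g in labels:
        if len(groups.samples_in(g)) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    result = indval_scores(rel, groups)
    group_cols = [
        np.array([rel.sample_ids.index(s) for s in groups.samples_in(g)
                  if s in rel.sample_ids])
        for g in labels
    ]
    obs_max = result.indval.max(axis=1).to_numpy()
    n = len(rel.sample_ids)
    rng = np.random.default_rng(seed)
    n_ge = np.zeros(len(rel.otu_ids))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        perm_cols = [perm[idx] for idx in group_cols]
        _, _, iv = _indval_components(rel.rel, perm_cols)
        n_ge += iv.max(axis=1) >= obs_max - 1e-15
    p = (n_ge + 1) / (n_perm + 1)
    result.p = pd.Series(p, index=result.indval.index, name="p_value")
    result.n_perm = n_perm
    return result
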