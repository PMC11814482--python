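"""Levins' niche breadth and permutation-based habitat-niche classification.

Levins' B for an OTU is the inverse Simpson concentration of its distribution
across samples: B = 1 / sum_j q_j^2 with q_j the OTU's share of its own total
in sample j. B ranges from 1 (confined to one sample, a habitat specialist)
to the number of samples (perfectly even, a generalist). Classification
compares observed B to its distribution under a fixed-fixed null: independent
random tables with the observed row and column totals (Patefield's algorithm,
the classical r2dtable null, equivalent to shuffling read-level sample labels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import random_table

from .core_io import CountMatrix, GroupMap, RelAbundanceMatrix, to_relative_abundance

__all__ = ["levins_breadth", "NicheResult", "classify_habitat_niche",
           "niche_breadth_by_group"]


def _levins_b_rows(x: np.ndarray) -> np.ndarray:
    """B per row of a nonnegative matrix; rows with zero total -> NaN."""
    totals = x.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(totals > 0, x / totals, 0.0)
        b = 1.0 / (q**2).sum(axis=1)
    b[totals[:, 0] == 0] = np.nan
    return b


def levins_breadth(rel: RelAbundanceMatrix) -> pd.Series:
    """Levins' niche breadth per OTU; OTUs absent everywhere are dropped."""
    if len(rel.sample_ids) < 2:
        raise ValueError("niche breadth needs >= 2 samples")
    b = _levins_b_rows(rel.rel)
    out = pd.Series(b, index=pd.Index(rel.otu_ids, name="otu_id"), name="levins_B")
    return out.dropna()


def niche_breadth_by_group(rel: RelAbundanceMatrix, groups: GroupMap) -> dict:
    """B computed within each group's sample subset (one Series per group)."""
    result = {}
    for g in groups.groups():
        idx = [rel.sample_ids.index(s) for s in groups.samples_in(g)
               if s in rel.sample_ids]
        if len(idx) < 2:
            raise ValueError(f"group {g!r} needs >= 2 samples")
        sub = rel.rel[:, idx]
        # renormalize columns so the subset is itself a valid composition
        sub = sub / sub.sum(axis=0, keepdims=True)
        b = _levins_b_rows(sub)
        s = pd.Series(b, index=pd.Index(rel.otu_ids, name="otu_id"),
                      name=f"levins_B_{g}")
        result[g] = s.dropna()
    return result


@dataclass
class NicheResult:
    """Per-OTU niche classification and per-group class abundance summary."""

    table: pd.DataFrame  # B_obs, null_lower, null_upper, class
    class_abundance_by_group: pd.DataFrame | None
    n_perm: int

    def class_counts(self) -> pd.Series:
        return self.table["class"].value_counts().reindex(
            ["generalist", "neutral", "specialist"], fill_value=0
        )


def classify_habitat_niche(counts: CountMatrix, n_perm: int = 1000, seed: int = 0,
                           groups: GroupMap | None = None) -> NicheResult:
    """Classify OTUs as generalist / specialist / neutral by Levins' B against
    a fixed-fixed null.

    The null draws ``n_perm`` independent tables with the observed row (OTU)
    and column (sample) totals by Patefield's algorithm; B is computed from
    column-normalized (relative-abundance) rows, so read-depth differences do
    not masquerade as niche signal. Generalists exceed the 97.5th null
    percentile of B, specialists fall below the 2.5th ("95% confidence
    interval" bounds).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    x = counts.counts
    n_otus, n_samples = x.shape
    if n_otus < 2 or n_samples < 2:
        raise ValueError("niche classification needs >= 2 OTUs and >= 2 samples")
    nonzero_total = x.sum(axis=1) > 0
    rng = np.random.default_rng(seed)

    col_tot = x.sum(axis=0, keepdims=True).astype(float)
    b_obs = _levins_b_rows(x / col_tot)

    dist = random_table(x.sum(axis=1), x.sum(axis=0))
    null = dist.rvs(n_perm, method="patefield", random_state=rng)
    null_b = np.empty((n_perm, n_otus))
    for t in range(n_perm):
        null_b[t] = _levins_b_rows(null[t] / col_tot)
    lo = np.full(n_otus, np.nan)
    hi = np.full(n_otus, np.nan)
    lo[nonzero_total] = np.nanpercentile(null_b[:, nonzero_total], 2.5, axis=0)
    hi[nonzero_total] = np.nanpercentile(null_b[:, nonzero_total], 97.5, axis=0)
    cls = np.where(b_obs > hi, "generalist",
                   np.where(b_obs < lo, "specialist", "neutral"))
    table = pd.DataFrame(
        {"B_obs": b_obs, "null_lower": lo, "null_upper": hi, "class": cls},
        index=pd.Index(counts.otu_ids, name="otu_id"),
    ).loc[nonzero_total]

    class_ab = None
    if groups is not None:
        rel = to_relative_abundance(counts)
        rel_df = rel.df
        rows_out = {}
        for g in groups.groups():
            samples = [s for s in groups.samples_in(g) if s in rel.sample_ids]
            group_mean = rel_df[samples].mean(axis=1)
            rows_out[g] = {
                c: float(group_mean[table.index[table["class"] == c]].sum())
                for c in ("generalist", "neutral", "specialist")
            }
        class_ab = pd.DataFrame(rows_out).T
        class_ab.index.name = "group"
    return NicheResult(table=table, class_abundance_by_group=class_ab, n_perm=n_perm)
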