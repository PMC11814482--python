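"""Co-occurrence networks (Spearman + BH-FDR) and taxa-environment bipartite networks.

Edges are Spearman rank correlations between OTU abundance profiles, kept when
|rho| clears a magnitude threshold and the BH-adjusted q-value clears a
significance threshold (defaults |rho| >= 0.8, q < 0.001). Topology metrics:
weighted degree uses |rho| as edge weight; betweenness is computed on the
binarized simple graph, normalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

from .core_io import EnvTable, RelAbundanceMatrix

__all__ = ["spearman_edges", "bh_adjust", "build_network", "NetworkStats",
           "aggregate_taxa", "taxa_env_network"]

R_MIN_DEFAULT = 0.8
P_MAX_DEFAULT = 0.001


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman_edges(rel: RelAbundanceMatrix, min_prevalence: float = 0.2) -> pd.DataFrame:
    """All-pairs Spearman correlations among OTUs present in >= ``min_prevalence``
    of samples.

    Ties receive average ranks; two-sided p-values use the t approximation;
    q is BH-adjusted across all returned pairs.
    """
    n_samples = len(rel.sample_ids)
    if n_samples < 4:
        raise ValueError("need >= 4 samples for meaningful correlation p-values")
    prevalence = (rel.rel > 0).mean(axis=1)
    keep = np.flatnonzero(prevalence >= min_prevalence)
    if keep.size < 2:
        raise ValueError("fewer than 2 OTUs pass the prevalence filter")
    ids = [rel.otu_ids[i] for i in keep]
    x = rel.rel[keep]
    rho, p = spearmanr(x, axis=1)
    if np.ndim(rho) == 0:  # spearmanr collapses the 2-variable case to scalars
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    iu = np.triu_indices(len(ids), k=1)
    edges = pd.DataFrame({
        "node_a": [ids[i] for i in iu[0]],
        "node_b": [ids[j] for j in iu[1]],
        "rho": rho[iu],
        "p_raw": p[iu],
    })
    edges["q"] = bh_adjust(edges["p_raw"].to_numpy())
    edges["sign"] = np.where(edges["rho"] >= 0, "positive", "negative")
    return edges


@dataclass
class NetworkStats:
    """Topology summary of a co-occurrence network."""

    n_nodes: int
    n_edges: int
    mean_weighted_degree: float
    mean_betweenness: float
    positive_edge_fraction: float

    def as_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes, "n_edges": self.n_edges,
            "mean_weighted_degree": self.mean_weighted_degree,
            "mean_betweenness": self.mean_betweenness,
            "positive_edge_fraction": self.positive_edge_fraction,
        }


def build_network(edges: pd.DataFrame, r_min: float = R_MIN_DEFAULT,
                  p_max: float = P_MAX_DEFAULT, use_q: bool = True) -> tuple:
    """Threshold an edge list into a graph and compute topology statistics.

    Keeps edges with |rho| >= ``r_min`` and (by default) BH-adjusted
    q < ``p_max``; ``use_q=False`` thresholds the raw p instead. An empty
    result is a valid empty graph with zeroed statistics.
    """
    pcol = "q" if use_q else "p_raw"
    kept = edges.loc[(edges["rho"].abs() >= r_min) & (edges[pcol] < p_max)]
    g = nx.Graph()
    for row in kept.itertuples(index=False):
        g.add_edge(row.node_a, row.node_b, rho=float(row.rho),
                   weight=abs(float(row.rho)), sign=row.sign)
    if g.number_of_edges() == 0:
        return g, NetworkStats(0, 0, 0.0, 0.0, 0.0)
    wdeg = [d for _, d in g.degree(weight="weight")]
    btw = nx.betweenness_centrality(g, normalized=True)
    pos_frac = float(np.mean([a["sign"] == "positive" for *_, a in g.edges(data=True)]))
    return g, NetworkStats(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        mean_weighted_degree=float(np.mean(wdeg)),
        mean_betweenness=float(np.mean(list(btw.values()))),
        positive_edge_fraction=pos_frac,
    )


def aggregate_taxa(rel: RelAbundanceMatrix, taxon_map: dict) -> pd.DataFrame:
    """Sum OTU relative abundances into higher taxa (e.g. phyla) per sample.

    ``taxon_map`` maps OTU id -> taxon label; unmapped OTUs go to
    ``"Unassigned"``. Columns still sum to 1.
    """
    labels = [taxon_map.get(o, "Unassigned") for o in rel.otu_ids]
    df = rel.df.copy()
    df.index = pd.Index(labels, name="taxon")
    return df.groupby(level=0).sum()


def taxa_env_network(taxa_rel: pd.DataFrame, env: EnvTable,
                     r_min: float = 0.6, p_max: float = 0.05) -> pd.DataFrame:
    """Bipartite taxa-environment edges: Spearman of each taxon vs each variable.

    Environment variables are z-scored (rank correlation is unaffected; kept
    for reporting on a common scale); constant variables are skipped with a
    warning; BH adjustment spans all taxon x variable tests; edges passing
    |rho| >= r_min and q < p_max are returned with their sign.
    """
    samples = list(taxa_rel.columns)
    env_df = env.require_complete(samples)
    rows = []
    for var in env_df.columns:
        v = env_df[var].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            warnings.warn(f"environment variable {var!r} is constant; skipped",
                          stacklevel=2)
            continue
        z = (v - v.mean()) / v.std()
        for taxon in taxa_rel.index:
            rho, p = spearmanr(taxa_rel.loc[taxon].to_numpy(), z)
            rows.append({"taxon": taxon, "variable": var,
                         "rho": float(rho), "p_raw": float(p)})
    if not rows:
        return pd.DataFrame(columns=["taxon", "variable", "rho", "p_raw", "q", "sign"])
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p_raw"].to_numpy())
    table["sign"] = np.where(table["rho"] >= 0, "positive", "negative")
    return table.loc[(table["rho"].abs() >= r_min) & (table["q"] < p_max)].reset_index(
        drop=True
    )
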