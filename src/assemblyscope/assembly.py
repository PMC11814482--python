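"""Community-assembly machinery: Sloan neutral model, AVD stability,
betaMNTD/betaNTI phylogenetic turnover, Raup-Crick on Bray-Curtis, and the
five-process partition.

The neutral community model (NCM) predicts a taxon's occurrence frequency
across samples from its mean relative abundance, given the community size
``N_T`` (mean reads per sample) and a migration rate ``m``; the fit quality
R-squared measures how neutral the metacommunity looks. betaNTI is the
z-score of the observed between-community mean nearest-taxon distance
(betaMNTD) against a tip-shuffle null; |betaNTI| > 2 signals selection.
RC_Bray rescales a null Bray-Curtis comparison to [-1, 1]; |RC| > 0.95
separates dispersal processes from drift among the non-selected pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist
from scipy.stats import beta as beta_dist
from skbio import DistanceMatrix
from statsmodels.stats.proportion import proportion_confint

from .core_io import CountMatrix, GroupMap, Phylogeny, RelAbundanceMatrix

__all__ = [
    "NCMFit",
    "fit_ncm",
    "AVDResult",
    "compute_avd",
    "beta_mntd",
    "beta_nti",
    "rc_bray",
    "turnover_pairs",
    "ProcessPartition",
    "partition_processes",
]

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


# ---------------------------------------------------------------------------
# Sloan neutral community model


@dataclass
class NCMFit:
    """Fitted Sloan neutral community model.

    ``table`` holds one row per OTU with mean relative abundance ``p``,
    observed occurrence frequency ``freq``, the neutral prediction and its 95%
    CI, and the partition (above / within / below the prediction band).
    """

    m: float
    N_T: float
    R2: float
    d: float
    n_samples: int
    table: pd.DataFrame

    @property
    def Nm(self) -> float:
        return self.N_T * self.m

    def partition_fractions(self) -> pd.Series:
        return self.table["partition"].value_counts(normalize=True).reindex(
            ["above", "within", "below"], fill_value=0.0
        )

    def summary(self) -> dict:
        return {
            "m": self.m, "N_T": self.N_T, "Nm": self.Nm, "R2": self.R2,
            "detection_limit": self.d, "n_samples": self.n_samples,
            "n_otus": int(len(self.table)),
            "partition_counts": self.table["partition"].value_counts().to_dict(),
        }


def _ncm_predict(m: float, p: np.ndarray, n_t: float, d: float) -> np.ndarray:
    """Neutral occurrence-frequency prediction: P[Beta(N_T m p, N_T m (1-p)) > d]."""
    nm = n_t * m
    return beta_dist.sf(d, np.maximum(nm * p, 1e-12), np.maximum(nm * (1.0 - p), 1e-12))


def _fit_m(p: np.ndarray, freq: np.ndarray, n_t: float, d: float) -> tuple:
    """Least-squares migration rate on (mean abundance, occurrence frequency).

    Returns ``(m_hat, R2)``; R2 may be negative when the points are farther
    from the fitted curve than from a flat mean.
    """

    def sse(m: float) -> float:
        resid = freq - _ncm_predict(m, p, n_t, d)
        return float(resid @ resid)

    res = minimize_scalar(sse, bounds=(1e-6, 1.0), method="bounded",
                          options={"xatol": 1e-10})
    if not res.success:
        raise RuntimeError(f"NCM optimizer failed to converge: {res.message}")
    sst = float(((freq - freq.mean()) ** 2).sum())
    r2 = 1.0 - res.fun / sst if sst > 0 else float("nan")
    return float(res.x), float(r2)


def fit_ncm(counts: CountMatrix, d: float | None = None) -> NCMFit:
    """Fit the Sloan neutral model by least squares of occurrence frequency on
    mean relative abundance.

    The detection limit defaults to ``1 / N_T`` with ``N_T`` the mean read
    depth. The migration rate is found on ``m in (1e-6, 1]``; R2 may be
    negative when the data are farther from the curve than a flat mean, which
    is reported as-is.
    """
    n_samples = len(counts.sample_ids)
    if n_samples < 10:
        warnings.warn(f"NCM fit on only {n_samples} samples; estimates unstable",
                      stacklevel=2)
    totals = counts.sample_sums().astype(float)
    if (totals == 0).any():
        raise ValueError("all samples must have positive read totals")
    rel = counts.counts / totals
    p = rel.mean(axis=1)
    freq = (counts.counts > 0).mean(axis=1)
    present = p > 0
    p, freq = p[present], freq[present]
    otu_ids = [o for o, keep in zip(counts.otu_ids, present) if keep]
    n_varying = int(((freq > 0) & (freq < 1)).sum())
    if n_varying < 5:
        raise ValueError(
            f"only {n_varying} OTUs with varying detection; need >= 5 for a stable fit"
        )
    n_t = float(totals.mean())
    d = 1.0 / n_t if d is None else float(d)
    m_hat, r2 = _fit_m(p, freq, n_t, d)
    pred = _ncm_predict(m_hat, p, n_t, d)
    lo, hi = proportion_confint(np.round(pred * n_samples), n_samples,
                                alpha=0.05, method="wilson")
    partition = np.where(freq > hi, "above", np.where(freq < lo, "below", "within"))
    table = pd.DataFrame(
        {"p": p, "freq": freq, "predicted": pred, "ci_lower": lo, "ci_upper": hi,
         "partition": partition},
        index=pd.Index(otu_ids, name="otu_id"),
    )
    return NCMFit(m=m_hat, N_T=n_t, R2=float(r2), d=d, n_samples=n_samples, table=table)


# ---------------------------------------------------------------------------
# AVD community stability


@dataclass
class AVDResult:
    """Average variation degree per sample and per group; lower = more stable."""

    per_sample: pd.Series
    per_group: pd.Series
    n_otus_used: dict
    n_otus_dropped: dict


def compute_avd(rel: RelAbundanceMatrix, groups: GroupMap) -> AVDResult:
    """Mean absolute z-score of OTU relative abundances within each group.

    Within a group, each OTU with non-zero variance contributes
    ``|x_ij - mu_i| / sigma_i`` (sd with denominator k-1); a sample's AVD is
    the mean of these over the OTUs used; zero-variance OTUs are dropped and
    counted.
    """
    per_sample, n_used, n_dropped = {}, {}, {}
    for g in groups.groups():
        samples = [s for s in groups.samples_in(g) if s in rel.sample_ids]
        if len(samples) < 2:
            raise ValueError(f"group {g!r} needs >= 2 samples for AVD")
        if len(samples) < 3:
            warnings.warn(f"group {g!r} has only {len(samples)} samples; AVD noisy",
                          stacklevel=2)
        idx = [rel.sample_ids.index(s) for s in samples]
        x = rel.rel[:, idx]
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=1, keepdims=True)
        keep = sd[:, 0] > 1e-12  # tolerance: constant rows leave float residue
        if not keep.any():
            raise ValueError(f"all OTUs have zero variance within group {g!r}")
        z = np.abs(x[keep] - mu[keep]) / sd[keep]
        avd_j = z.mean(axis=0)
        for s, v in zip(samples, avd_j):
            per_sample[s] = float(v)
        n_used[g] = int(keep.sum())
        n_dropped[g] = int((~keep).sum())
    per_sample = pd.Series(per_sample, name="AVD")
    per_group = pd.Series(
        {g: per_sample[[s for s in groups.samples_in(g) if s in per_sample.index]].mean()
         for g in groups.groups()},
        name="AVD",
    )
    return AVDResult(per_sample, per_group, n_used, n_dropped)


# ---------------------------------------------------------------------------
# betaMNTD / betaNTI


def _weights_matrix(rel: RelAbundanceMatrix, weighted: bool) -> np.ndarray:
    x = rel.rel
    if (x.sum(axis=0) <= 0).any():
        raise ValueError("every sample needs at least one taxon present")
    if weighted:
        return x
    pres = (x > 0).astype(float)
    return pres / pres.sum(axis=0, keepdims=True)


def _betamntd_from_distances(dist: np.ndarray, x: np.ndarray,
                             present: list) -> np.ndarray:
    """All-pairs betaMNTD from a taxon distance matrix and weight columns.

    ``M[i, k]`` is the distance from taxon i to its nearest taxon present in
    sample k; betaMNTD(j, k) = 0.5 * (x_j . M[:, k] + x_k . M[:, j]).
    """
    n_taxa, n_samples = x.shape
    mins = np.empty((n_taxa, n_samples))
    for k in range(n_samples):
        mins[:, k] = dist[:, present[k]].min(axis=1)
    g = x.T @ mins
    bm = 0.5 * (g + g.T)
    np.fill_diagonal(bm, 0.0)
    return bm


def beta_mntd(rel: RelAbundanceMatrix, tree: Phylogeny,
              weighted: bool = True) -> DistanceMatrix:
    """Between-community mean nearest-taxon distance (abundance-weighted by default)."""
    tree.check_covers(rel.otu_ids)
    dist = tree.tip_distance_matrix(order=rel.otu_ids).to_numpy()
    x = _weights_matrix(rel, weighted)
    present = [np.flatnonzero(x[:, k] > 0) for k in range(x.shape[1])]
    bm = _betamntd_from_distances(dist, x, present)
    return DistanceMatrix(bm, ids=rel.sample_ids)


def beta_nti(rel: RelAbundanceMatrix, tree: Phylogeny, n_null: int = 999,
             seed: int = 0, weighted: bool = True,
             shuffle_all_tips: bool = True) -> pd.DataFrame:
    """betaNTI: z-score of observed betaMNTD against a tip-label-shuffle null.

    The null shuffles taxon positions across the whole tree (all tips by
    default; optionally only the observed taxa), leaving abundances untouched.
    Pairs whose null sd is 0 get betaNTI = 0 and ``degenerate = True``.
    Returns one row per unordered sample pair.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99 for stable z-scores")
    tree.check_covers(rel.otu_ids)
    x = _weights_matrix(rel, weighted)
    n_taxa, n_samples = x.shape
    present = [np.flatnonzero(x[:, k] > 0) for k in range(n_samples)]

    if shuffle_all_tips:
        tip_order = tree.tip_names
    else:
        tip_order = list(rel.otu_ids)
    full = tree.tip_distance_matrix(order=tip_order).to_numpy()
    pos = np.array([tip_order.index(o) for o in rel.otu_ids])
    obs = _betamntd_from_distances(full[np.ix_(pos, pos)], x, present)

    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n_samples, k=1)
    null_sum = np.zeros(len(iu[0]))
    null_sq = np.zeros(len(iu[0]))
    n_tips = len(tip_order)
    for _ in range(n_null):
        perm = rng.permutation(n_tips)
        taxa_pos = perm[pos]  # pos is the identity when tip_order == otu_ids
        d_null = full[np.ix_(taxa_pos, taxa_pos)]
        bm = _betamntd_from_distances(d_null, x, present)[iu]
        null_sum += bm
        null_sq += bm**2
    mean = null_sum / n_null
    var = null_sq / n_null - mean**2
    sd = np.sqrt(np.maximum(var, 0.0))
    obs_pairs = obs[iu]
    degenerate = sd < 1e-12
    bnti = np.zeros_like(obs_pairs)
    ok = ~degenerate
    bnti[ok] = (obs_pairs[ok] - mean[ok]) / sd[ok]
    return pd.DataFrame({
        "sample_a": [rel.sample_ids[i] for i in iu[0]],
        "sample_b": [rel.sample_ids[j] for j in iu[1]],
        "betaMNTD_obs": obs_pairs,
        "null_mean": mean,
        "null_sd": sd,
        "betaNTI": bnti,
        "degenerate": degenerate,
    })


# ---------------------------------------------------------------------------
# Raup-Crick on Bray-Curtis


def rc_bray(counts: CountMatrix, n_null: int = 999, seed: int = 0) -> pd.DataFrame:
    """Raup-Crick metric on Bray-Curtis, rescaled to [-1, 1].

    Null communities preserve each sample's richness and read total: taxa are
    chosen without replacement with probability proportional to occupancy
    (number of samples occupied), each chosen taxon gets one read, and the
    remaining reads are allocated by a multinomial weighted by mean relative
    abundance. RC = 2 * (fraction of null BC below observed, ties counting
    half) - 1.
    """
    x = counts.counts
    n_taxa, n_samples = x.shape
    occupied = (x > 0).sum(axis=1).astype(float)
    pool = np.flatnonzero(occupied > 0)
    if pool.size < 2:
        raise ValueError("need at least 2 taxa observed somewhere")
    totals = x.sum(axis=0)
    richness = (x > 0).sum(axis=0)
    rel = x / totals
    mean_rel = rel.mean(axis=1)
    occ_p = occupied[pool] / occupied[pool].sum()
    abund_w = np.maximum(mean_rel[pool], 1e-12)

    obs_bc = pdist(rel.T, metric="braycurtis")
    rng = np.random.default_rng(seed)
    below = np.zeros_like(obs_bc)
    ties = np.zeros_like(obs_bc)
    null_rel = np.empty((n_samples, pool.size))
    for _ in range(n_null):
        for j in range(n_samples):
            r, n_reads = int(richness[j]), int(totals[j])
            chosen = rng.choice(pool.size, size=min(r, pool.size), replace=False,
                                p=occ_p)
            vec = np.zeros(pool.size)
            vec[chosen] = 1.0
            extra = n_reads - chosen.size
            if extra > 0:
                w = abund_w[chosen]
                vec[chosen] += rng.multinomial(extra, w / w.sum())
            null_rel[j] = vec / n_reads
        bc = pdist(null_rel, metric="braycurtis")
        below += bc < obs_bc - 1e-12
        ties += np.abs(bc - obs_bc) <= 1e-12
    rc = 2.0 * (below + 0.5 * ties) / n_null - 1.0
    rc = np.clip(rc, -1.0, 1.0)
    iu = np.triu_indices(n_samples, k=1)
    return pd.DataFrame({
        "sample_a": [counts.sample_ids[i] for i in iu[0]],
        "sample_b": [counts.sample_ids[j] for j in iu[1]],
        "BC_obs": obs_bc,
        "RC": rc,
    })


def turnover_pairs(counts: CountMatrix, tree: Phylogeny, n_null: int = 999,
                   seed: int = 0, weighted: bool = True) -> pd.DataFrame:
    """betaNTI and RC_Bray for every sample pair, merged into one table."""
    from .core_io import to_relative_abundance

    ss = np.random.SeedSequence(seed)
    s_nti, s_rc = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2))
    rel = to_relative_abundance(counts)
    nti = beta_nti(rel, tree, n_null=n_null, seed=s_nti, weighted=weighted)
    rc = rc_bray(counts, n_null=n_null, seed=s_rc)
    return nti.merge(rc, on=["sample_a", "sample_b"], validate="one_to_one")


# ---------------------------------------------------------------------------
# five-process partition


@dataclass
class ProcessPartition:
    """Fractions of sample pairs assigned to each ecological process (sum to 1)."""

    heterogeneous_selection: float
    homogeneous_selection: float
    dispersal_limitation: float
    homogenizing_dispersal: float
    undominated: float
    n_pairs: int
    n_excluded_degenerate: int = 0

    def as_dict(self) -> dict:
        return {
            "heterogeneous_selection": self.heterogeneous_selection,
            "homogeneous_selection": self.homogeneous_selection,
            "dispersal_limitation": self.dispersal_limitation,
            "homogenizing_dispersal": self.homogenizing_dispersal,
            "undominated": self.undominated,
            "n_pairs": self.n_pairs,
            "n_excluded_degenerate": self.n_excluded_degenerate,
        }

    @property
    def fractions(self) -> dict:
        return {k: v for k, v in self.as_dict().items()
                if k not in ("n_pairs", "n_excluded_degenerate")}

    @property
    def stochastic_fraction(self) -> float:
        """Dispersal limitation + homogenizing dispersal + undominated."""
        return (self.dispersal_limitation + self.homogenizing_dispersal
                + self.undominated)


def partition_processes(pairs: pd.DataFrame,
                        bnti_threshold: float = BNTI_THRESHOLD,
                        rc_threshold: float = RC_THRESHOLD) -> ProcessPartition:
    """Assign each pair to one of five processes from its betaNTI and RC values.

    betaNTI > 2: heterogeneous selection; betaNTI < -2: homogeneous selection;
    |betaNTI| <= 2 with RC > 0.95: dispersal limitation; RC < -0.95:
    homogenizing dispersal; |RC| <= 0.95: undominated (drift and weak
    processes). Pairs flagged degenerate are excluded from the denominator.
    """
    required = {"betaNTI", "RC"}
    if pairs is None or len(pairs) == 0:
        raise ValueError("empty pair list")
    if not required <= set(pairs.columns):
        raise ValueError(f"pairs must have columns {sorted(required)}")
    work = pairs
    n_excluded = 0
    if "degenerate" in pairs.columns:
        n_excluded = int(pairs["degenerate"].sum())
        work = pairs.loc[~pairs["degenerate"].astype(bool)]
        if len(work) == 0:
            raise ValueError("all pairs are degenerate; no partition possible")
    bnti = work["betaNTI"].to_numpy(dtype=float)
    rc = work["RC"].to_numpy(dtype=float)
    het = bnti > bnti_threshold
    hom = bnti < -bnti_threshold
    sel_free = ~(het | hom)
    disp_lim = sel_free & (rc > rc_threshold)
    hom_disp = sel_free & (rc < -rc_threshold)
    undom = sel_free & ~(disp_lim | hom_disp)
    n = len(work)
    return ProcessPartition(
        heterogeneous_selection=float(het.sum()) / n,
        homogeneous_selection=float(hom.sum()) / n,
        dispersal_limitation=float(disp_lim.sum()) / n,
        homogenizing_dispersal=float(hom_disp.sum()) / n,
        undominated=float(undom.sum()) / n,
        n_pairs=n,
        n_excluded_degenerate=n_excluded,
    )
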