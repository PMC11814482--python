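import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from assemblyscope.assembly import (_ncm_predict, beta_mntd, beta_nti,
                                    compute_avd, fit_ncm, partition_processes,
                                    rc_bray, turnover_pairs)
from assemblyscope.core_io import (CountMatrix, GroupMap, Phylogeny,
                                   RelAbundanceMatrix)

# ---------------------------------------------------------------------------
# Sloan neutral model


def test_ncm_noiseless_self_consistency():
    """Occurrence frequencies generated exactly on the curve at m = 0.2 are
    refit to m = 0.2 within 1e-4, with R2 ~ 1."""
    from assemblyscope.assembly import _fit_m

    rng = np.random.default_rng(0)
    n_t, m_true = 1000.0, 0.2
    p = np.sort(rng.dirichlet(np.ones(80) * 0.3))
    freq = _ncm_predict(m_true, p, n_t, 1.0 / n_t)
    m_hat, r2 = _fit_m(p, freq, n_t, 1.0 / n_t)
    assert m_hat == pytest.approx(m_true, abs=1e-4)
    assert r2 >= 0.999


def test_ncm_shuffled_frequencies_destroy_fit():
    """Frequencies unrelated to abundances (shuffled) give R2 <= 0.2."""
    from assemblyscope.assembly import _fit_m

    rng = np.random.default_rng(5)
    n_t = 1000.0
    p = np.sort(rng.dirichlet(np.ones(120) * 0.3))
    freq = _ncm_predict(0.2, p, n_t, 1.0 / n_t)
    shuffled = rng.permutation(freq)
    _, r2 = _fit_m(p, shuffled, n_t, 1.0 / n_t)
    assert r2 <= 0.2


def test_ncm_partition_consistent_with_ci():
    from assemblyscope.synthetic import SimConfig, log_series_pool, \
        simulate_neutral_communities

    pool = log_series_pool(100, seed=1)
    cfg = SimConfig(n_taxa=100, n_samples=20, reads=500, m=0.3, seed=2)
    fit = fit_ncm(simulate_neutral_communities(pool, cfg).drop_empty_otus())
    t = fit.table
    assert ((t["partition"] == "above") == (t["freq"] > t["ci_upper"])).all()
    assert ((t["partition"] == "below") == (t["freq"] < t["ci_lower"])).all()
    assert 0 < fit.m <= 1
    assert fit.Nm == pytest.approx(fit.m * fit.N_T)


def test_ncm_too_few_varying_otus():
    counts = np.ones((4, 12), dtype=np.int64)
    cm = CountMatrix(list("abcd"), [f"s{i}" for i in range(12)], counts)
    with pytest.raises(ValueError, match="varying detection"):
        fit_ncm(cm)


# ---------------------------------------------------------------------------
# AVD


def test_avd_hand_computation():
    """One OTU, two samples (0.25, 0.75): sd = 0.35355 (ddof=1), z = 0.7071."""
    rel = RelAbundanceMatrix(["a", "b"], ["s1", "s2"],
                             np.array([[0.25, 0.75], [0.75, 0.25]]))
    groups = GroupMap({"s1": "G", "s2": "G"})
    with pytest.warns(UserWarning, match="AVD noisy"):
        res = compute_avd(rel, groups)
    assert res.per_sample["s1"] == pytest.approx(np.sqrt(0.5), abs=1e-9)
    assert res.per_group["G"] == pytest.approx(np.sqrt(0.5), abs=1e-9)


def test_avd_drops_constant_otus_and_scale_invariance():
    x = np.array([[0.2, 0.2, 0.2], [0.5, 0.3, 0.4], [0.3, 0.5, 0.4]])
    rel = RelAbundanceMatrix(list("abc"), ["s1", "s2", "s3"], x)
    groups = GroupMap({s: "G" for s in ["s1", "s2", "s3"]})
    res = compute_avd(rel, groups)
    assert res.n_otus_dropped["G"] == 1  # constant OTU a
    assert res.n_otus_used["G"] == 2

    # scaling all abundances by a constant leaves the z-scores unchanged
    z = np.abs(x[1:] - x[1:].mean(axis=1, keepdims=True)) / \
        x[1:].std(axis=1, ddof=1, keepdims=True)
    np.testing.assert_allclose(res.per_sample.to_numpy(), z.mean(axis=0))


# ---------------------------------------------------------------------------
# betaMNTD / betaNTI


def betamntd_oracle(rel, tree, j, k):
    """Exhaustive double loop over taxa present in each sample."""
    d = tree.tip_distance_matrix(order=rel.otu_ids).to_numpy()
    x = rel.rel
    pres_j = np.flatnonzero(x[:, j] > 0)
    pres_k = np.flatnonzero(x[:, k] > 0)
    term_j = sum(x[i, j] * min(d[i, i2] for i2 in pres_k) for i in pres_j)
    term_k = sum(x[i, k] * min(d[i, i2] for i2 in pres_j) for i in pres_k)
    return 0.5 * (term_j + term_k)


def test_beta_mntd_identical_samples_zero(toy_rel, toy_tree):
    rel = RelAbundanceMatrix(toy_rel.otu_ids, ["s1", "s2"],
                             np.column_stack([toy_rel.rel[:, 0]] * 2))
    dm = beta_mntd(rel, toy_tree)
    assert dm["s1", "s2"] == pytest.approx(0.0, abs=1e-12)


def test_beta_mntd_two_tip_hand_value():
    tree = Phylogeny(TreeNode.read(io.StringIO("(A:1,B:1);")))
    rel = RelAbundanceMatrix(["A", "B"], ["s1", "s2"],
                             np.array([[1.0, 0.0], [0.0, 1.0]]))
    assert beta_mntd(rel, tree)["s1", "s2"] == pytest.approx(2.0)


def test_beta_mntd_matches_brute_force(toy_rel, toy_tree):
    dm = beta_mntd(toy_rel, toy_tree)
    for j in range(6):
        for k in range(j + 1, 6):
            expect = betamntd_oracle(toy_rel, toy_tree, j, k)
            assert dm[toy_rel.sample_ids[j], toy_rel.sample_ids[k]] == \
                pytest.approx(expect, abs=1e-12)


def test_beta_nti_degenerate_identical_pair(toy_tree):
    rel = RelAbundanceMatrix(["A", "B", "C", "D"], ["s1", "s2"],
                             np.array([[0.25] * 2] * 4))
    out = beta_nti(rel, toy_tree, n_null=99, seed=0)
    assert bool(out.loc[0, "degenerate"])
    assert out.loc[0, "betaNTI"] == 0.0


def test_beta_nti_branch_scale_invariance(toy_rel, toy_tree):
    """Multiplying all branch lengths by a constant cancels in the z-score."""
    a = beta_nti(toy_rel, toy_tree, n_null=199, seed=11)
    scaled = Phylogeny(toy_tree.tree.copy())
    for node in scaled.tree.traverse(include_self=False):
        node.length *= 13.0
    b = beta_nti(toy_rel, scaled, n_null=199, seed=11)
    np.testing.assert_allclose(a["betaNTI"], b["betaNTI"], atol=1e-9)


def test_beta_nti_seed_reproducible(toy_rel, toy_tree):
    a = beta_nti(toy_rel, toy_tree, n_null=99, seed=5)
    b = beta_nti(toy_rel, toy_tree, n_null=99, seed=5)
    pd.testing.assert_frame_equal(a, b)
    with pytest.raises(ValueError, match="n_null"):
        beta_nti(toy_rel, toy_tree, n_null=50)


# ---------------------------------------------------------------------------
# RC_Bray


def test_rc_identical_pair_is_minus_one():
    rng = np.random.default_rng(3)
    col = rng.multinomial(500, rng.dirichlet(np.ones(40)))
    counts = np.column_stack([col, col, rng.multinomial(500, np.ones(40) / 40)])
    cm = CountMatrix([f"o{i}" for i in range(40)], ["s1", "s2", "s3"], counts)
    rc = rc_bray(cm, n_null=199, seed=1)
    pair = rc[(rc.sample_a == "s1") & (rc.sample_b == "s2")]["RC"].iloc[0]
    assert pair <= -0.99


def test_rc_seed_reproducible_and_bounds(toy_counts):
    a = rc_bray(toy_counts, n_null=99, seed=2)
    b = rc_bray(toy_counts, n_null=99, seed=2)
    pd.testing.assert_frame_equal(a, b)
    assert a["RC"].between(-1, 1).all()


def test_turnover_pairs_merges_both_metrics(toy_counts, toy_tree):
    pairs = turnover_pairs(toy_counts, toy_tree, n_null=99, seed=0)
    assert len(pairs) == 15
    assert {"betaNTI", "RC", "BC_obs", "betaMNTD_obs"} <= set(pairs.columns)


# ---------------------------------------------------------------------------
# process partition


def test_partition_worked_example():
    pairs = pd.DataFrame({
        "betaNTI": [0.0, 0.0, 0.0, 3.0, -3.0],
        "RC": [0.99, -0.99, 0.0, 0.0, 0.0],
    })
    part = partition_processes(pairs)
    assert part.dispersal_limitation == pytest.approx(0.2)
    assert part.homogenizing_dispersal == pytest.approx(0.2)
    assert part.undominated == pytest.approx(0.2)
    assert part.heterogeneous_selection == pytest.approx(0.2)
    assert part.homogeneous_selection == pytest.approx(0.2)
    assert sum(part.fractions.values()) == pytest.approx(1.0, abs=1e-12)


def test_partition_all_homogeneous():
    pairs = pd.DataFrame({"betaNTI": [-3.0] * 4, "RC": [0.0] * 4})
    assert partition_processes(pairs).homogeneous_selection == 1.0


def test_partition_boundaries_and_degenerates():
    # |betaNTI| = 2 and |RC| = 0.95 are inclusive of the weaker class
    pairs = pd.DataFrame({
        "betaNTI": [2.0, -2.0, 0.0],
        "RC": [0.0, 0.0, 0.95],
        "degenerate": [False, False, True],
    })
    part = partition_processes(pairs)
    assert part.n_pairs == 2
    assert part.n_excluded_degenerate == 1
    assert part.undominated == 1.0
    with pytest.raises(ValueError, match="empty"):
        partition_processes(pd.DataFrame(columns=["betaNTI", "RC"]))
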