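import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from assemblyscope.core_io import CountMatrix, GroupMap, to_relative_abundance
from assemblyscope.diversity import (alpha_diversity, bray_curtis_matrix,
                                     faith_pd, nmds, permanova,
                                     shared_unique_otus, unifrac_matrix)

# ---------------------------------------------------------------------------
# independent oracles


def chao1_oracle(col):
    sobs = int((col > 0).sum())
    f1 = int((col == 1).sum())
    f2 = int((col == 2).sum())
    return sobs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def ace_oracle(col, rare_threshold=10):
    col = col[col > 0]
    rare = col[col <= rare_threshold]
    s_abund = int((col > rare_threshold).sum())
    s_rare = len(rare)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    c_ace = 1.0 - f1 / n_rare
    top = sum(i * (i - 1) * int((rare == i).sum()) for i in range(1, rare_threshold + 1))
    gamma = max(s_rare / c_ace * top / (n_rare * (n_rare - 1.0)) - 1.0, 0.0)
    return s_abund + s_rare / c_ace + f1 / c_ace * gamma


def faith_oracle(tree, present):
    """Sum of branch lengths of edges whose subtree contains a present tip."""
    total = 0.0
    for node in tree.tree.traverse(include_self=False):
        tips = {t.name for t in node.tips()} or {node.name}
        if tips & set(present):
            total += node.length
    return total


def unifrac_oracle(tree, counts, j, k, weighted):
    """Branch-by-branch tabulation over every edge of the tree."""
    col_j = dict(zip(counts.otu_ids, counts.counts[:, j]))
    col_k = dict(zip(counts.otu_ids, counts.counts[:, k]))
    tot_j, tot_k = sum(col_j.values()), sum(col_k.values())
    num = den = 0.0
    wsum = 0.0
    for node in tree.tree.traverse(include_self=False):
        tips = {t.name for t in node.tips()} or {node.name}
        a = sum(col_j.get(t, 0) for t in tips) / tot_j
        b = sum(col_k.get(t, 0) for t in tips) / tot_k
        length = node.length
        if weighted:
            num += length * abs(a - b)
            wsum += length * (a + b)
        else:
            if (a > 0) != (b > 0):
                num += length
            if a > 0 or b > 0:
                den += length
    return num / wsum if weighted else num / den


def permanova_f_oracle(d, labels):
    """Direct sum-of-squares pseudo-F (Anderson) from the definition."""
    n = len(labels)
    groups = sorted(set(labels))
    ss_total = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in groups:
        idx = [i for i, l in enumerate(labels) if l == g]
        ss_within += sum(d[i, j] ** 2 for i in idx for j in idx if i < j) / len(idx)
    ss_between = ss_total - ss_within
    a = len(groups)
    return (ss_between / (a - 1)) / (ss_within / (n - a))


# ---------------------------------------------------------------------------
# alpha diversity


def test_sobs(toy_counts):
    vals = alpha_diversity(toy_counts, "sobs")
    assert vals["s0"] == 3  # counts (5,2,0,1)
    assert vals["s4"] == 2


def test_chao1_formula():
    # S_obs = 5, F1 = 3, F2 = 2 -> 5 + 3*2/(2*3) = 6.0
    col = np.array([1, 1, 1, 2, 2])
    cm = CountMatrix([f"o{i}" for i in range(5)], ["s"], col[:, None])
    assert alpha_diversity(cm, "chao1")["s"] == pytest.approx(6.0)
    assert chao1_oracle(col) == pytest.approx(6.0)


def test_ace_matches_oracle():
    col = np.array([1, 1, 2, 5, 30, 12])
    cm = CountMatrix([f"o{i}" for i in range(6)], ["s"], col[:, None])
    assert alpha_diversity(cm, "ace")["s"] == pytest.approx(ace_oracle(col))


def test_alpha_estimators_bound_richness():
    rng = np.random.default_rng(0)
    for _ in range(20):
        col = rng.integers(0, 20, size=30)
        if (col > 0).sum() < 2 or (col == 1).sum() == col[col > 0].size:
            continue
        cm = CountMatrix([f"o{i}" for i in range(30)], ["s"], col[:, None])
        sobs = alpha_diversity(cm, "sobs")["s"]
        assert alpha_diversity(cm, "chao1")["s"] >= sobs - 1e-9
        assert alpha_diversity(cm, "ace")["s"] >= sobs - 1e-9


def test_alpha_errors(toy_counts):
    with pytest.raises(ValueError, match="unknown alpha metric"):
        alpha_diversity(toy_counts, "shannon")
    zero = CountMatrix(["a"], ["s1", "s2"], np.array([[1, 0]]))
    with pytest.raises(ValueError, match="zero total"):
        alpha_diversity(zero, "sobs")


# ---------------------------------------------------------------------------
# Faith's PD


def test_faith_pd_star_tree(star_tree):
    cm = CountMatrix(["A", "B", "C", "D"], ["s1", "s2"],
                     np.array([[1, 1], [1, 1], [2, 1], [0, 1]]))
    pd_vals = faith_pd(cm, star_tree)
    assert pd_vals["s1"] == pytest.approx(3.0)
    assert pd_vals["s2"] == pytest.approx(star_tree.total_branch_length())


def test_faith_pd_matches_brute_force(toy_counts, toy_tree):
    pd_vals = faith_pd(toy_counts, toy_tree)
    for j, sid in enumerate(toy_counts.sample_ids):
        present = [o for o, c in zip(toy_counts.otu_ids, toy_counts.counts[:, j])
                   if c > 0]
        assert pd_vals[sid] == pytest.approx(faith_oracle(toy_tree, present),
                                             abs=1e-10)


# ---------------------------------------------------------------------------
# distances


def test_bray_curtis_hand_values():
    cm = CountMatrix(["a", "b", "c"], ["s1", "s2", "s3", "s4"],
                     np.array([[1, 1, 2, 0], [1, 0, 2, 0], [0, 1, 0, 4]]))
    rel = to_relative_abundance(cm)
    dm = bray_curtis_matrix(rel)
    # (0.5,0.5,0) vs (0.5,0,0.5) -> 1 - 0.5
    assert dm["s1", "s2"] == pytest.approx(0.5)
    assert dm["s1", "s3"] == pytest.approx(0.0)  # identical columns
    assert dm["s1", "s4"] == pytest.approx(1.0)  # disjoint support
    assert (dm.data >= 0).all() and (dm.data <= 1).all()
    np.testing.assert_allclose(dm.data, dm.data.T, atol=1e-12)


def test_unifrac_matches_branch_oracle(toy_counts, toy_tree):
    for weighted in (False, True):
        dm = unifrac_matrix(toy_counts, toy_tree, weighted=weighted)
        for j in range(6):
            for k in range(j + 1, 6):
                expect = unifrac_oracle(toy_tree, toy_counts, j, k, weighted)
                got = dm[toy_counts.sample_ids[j], toy_counts.sample_ids[k]]
                assert got == pytest.approx(expect, abs=1e-10), (j, k, weighted)


def test_unifrac_identical_and_disjoint(star_tree):
    cm = CountMatrix(["A", "B", "C", "D"], ["s1", "s2", "s3"],
                     np.array([[2, 2, 0], [1, 1, 0], [0, 0, 3], [0, 0, 1]]))
    for weighted in (False, True):
        dm = unifrac_matrix(cm, star_tree, weighted=weighted)
        assert dm["s1", "s2"] == pytest.approx(0.0, abs=1e-12)
    assert unifrac_matrix(cm, star_tree, weighted=False)["s1", "s3"] == \
        pytest.approx(1.0)


# ---------------------------------------------------------------------------
# NMDS


def test_nmds_embeddable_points_low_stress():
    rng = np.random.default_rng(1)
    pts = rng.normal(size=(5, 2))
    from scipy.spatial.distance import pdist, squareform

    dm = DistanceMatrix(squareform(pdist(pts)), ids=list("abcde"))
    coords, stress = nmds(dm, k=2, seed=0)
    assert stress <= 0.01
    assert coords.shape == (5, 2)


def test_nmds_identical_samples_coincide():
    d = np.array([[0, 0, 1.0], [0, 0, 1.0], [1.0, 1.0, 0]])
    dm = DistanceMatrix(d, ids=["a", "b", "c"])
    coords, _ = nmds(dm, k=2, seed=0)
    gap = np.linalg.norm(coords.loc["a"] - coords.loc["b"])
    spread = np.linalg.norm(coords.loc["a"] - coords.loc["c"])
    assert gap < 0.05 * spread


def test_nmds_seed_reproducible_and_k_bound():
    rng = np.random.default_rng(2)
    from scipy.spatial.distance import pdist, squareform

    dm = DistanceMatrix(squareform(pdist(rng.normal(size=(6, 3)))),
                        ids=list("abcdef"))
    c1, s1 = nmds(dm, seed=3)
    c2, s2 = nmds(dm, seed=3)
    assert s1 == s2 and c1.equals(c2)
    with pytest.raises(ValueError, match="must be smaller"):
        nmds(dm, k=6)


# ---------------------------------------------------------------------------
# PERMANOVA


def test_permanova_matches_oracles():
    rng = np.random.default_rng(4)
    pts = rng.normal(size=(6, 3))
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(pts))
    ids = list("abcdef")
    dm = DistanceMatrix(d, ids=ids)
    groups = GroupMap(dict(zip(ids, ["g1"] * 3 + ["g2"] * 3)))
    res = permanova(dm, groups, n_perm=99, seed=0)
    assert res.pseudo_F == pytest.approx(
        permanova_f_oracle(d, ["g1"] * 3 + ["g2"] * 3), abs=1e-10)
    skres = skbio_permanova(dm, grouping=["g1"] * 3 + ["g2"] * 3, permutations=99)
    assert res.pseudo_F == pytest.approx(float(skres["test statistic"]), abs=1e-10)
    assert res.df == 1
    assert 0 < res.R2 < 1


def test_permanova_perfect_separation_floor():
    """Two tight, well-separated clusters: p hits the 1/(B+1) floor."""
    rng = np.random.default_rng(5)
    a = rng.normal(0, 1e-3, size=(8, 2))
    b = rng.normal(10, 1e-3, size=(8, 2))
    from scipy.spatial.distance import pdist, squareform

    pts = np.vstack([a, b])
    ids = [f"s{i}" for i in range(16)]
    dm = DistanceMatrix(squareform(pdist(pts)), ids=ids)
    groups = GroupMap(dict(zip(ids, ["A"] * 8 + ["B"] * 8)))
    res = permanova(dm, groups, n_perm=999, seed=1)
    assert res.p_value == pytest.approx(1 / 1000)
    assert res.R2 > 0.99


def test_permanova_errors():
    d = np.zeros((3, 3))
    dm = DistanceMatrix(d, ids=["a", "b", "c"])
    with pytest.raises(ValueError, match="fewer than 2"):
        permanova(dm, GroupMap({"a": "g1", "b": "g1", "c": "g2"}))
    with pytest.raises(ValueError, match="at least 2 groups"):
        permanova(dm, GroupMap({"a": "g1", "b": "g1", "c": "g1"}))


# ---------------------------------------------------------------------------
# OTU overlap


def test_shared_unique_otus_partition(toy_counts, toy_groups):
    venn = shared_unique_otus(toy_counts, toy_groups)
    # A: G1-only? A has counts in s5 (G2) -> shared; C absent from G1? C in s2.
    assert venn["n_otus"].sum() == 4
    assert venn.loc["G1&G2", "n_otus"] == 4  # every toy OTU occurs in both
    cm = CountMatrix(["x", "y"], ["s0", "s3"], np.array([[3, 0], [0, 2]]))
    gm = GroupMap({"s0": "G1", "s3": "G2"})
    venn2 = shared_unique_otus(cm, gm)
    assert venn2.loc["G1", "n_otus"] == 1
    assert venn2.loc["G2", "n_otus"] == 1
    assert venn2.loc["G1&G2", "n_otus"] == 0
    assert venn2["pct_of_union"].sum() == pytest.approx(100.0)
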