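"""Diversity metrics and permutation tests against independent oracles."""

import itertools
import math

import numpy as np
import pytest
import skbio
from skbio.diversity import alpha_diversity, beta_diversity
from skbio.stats.distance import permanova as skbio_permanova

from scavtrace import (
    beta_distance,
    bh_fdr,
    faith_pd,
    generate_tree,
    indval,
    permanova,
    permdisp,
    prevalence_filter,
    richness,
)
from scavtrace.stats import DistanceMatrix, indval_stat

from conftest import make_table, random_table


def two_group_table(rng, n_per_group=5, n_asvs=18, shift=0.0):
    """Random table with an optional compositional shift in group two."""
    counts = rng.integers(0, 6, size=(2 * n_per_group, n_asvs))
    if shift:
        counts[n_per_group:, : n_asvs // 2] = np.maximum(
            0, counts[n_per_group:, : n_asvs // 2] + int(shift)
        )
    counts[:, 0] = np.maximum(counts[:, 0], 1)
    types = ["rat_feces"] * n_per_group + ["rat_stomach"] * n_per_group
    return make_table(counts, sample_type=types), np.array(types)


class TestAlpha:
    def test_richness_counts_nonzero(self):
        table = make_table([[0, 3, 1], [2, 0, 0]])
        assert richness(table).tolist() == [2, 1]

    def test_pd_single_leaf_path(self):
        tree = skbio.TreeNode.read(["(a:0.7,b:0.3):0;"])
        table = make_table([[1, 0]], asv_ids=["a", "b"])
        assert faith_pd(table, tree).iloc[0] == pytest.approx(0.7)

    def test_pd_star_tree_all_observed(self):
        tree = skbio.TreeNode.read(["(a:1.0,b:1.0,c:1.0);"]).root_at_midpoint()
        table = make_table([[1, 1, 1]], asv_ids=["a", "b", "c"])
        assert faith_pd(table, tree).iloc[0] == pytest.approx(3.0)

    def test_pd_matches_edge_union_brute_force(self):
        rng = np.random.default_rng(2)
        asvs = [f"a{j}" for j in range(8)]
        tree = generate_tree(asvs, seed=6)
        table = random_table(rng, n_samples=6, n_asvs=8, asv_ids=asvs)
        mine = faith_pd(table, tree)
        presence = table.presence()
        for sample in table.sample_ids:
            observed = [a for a in asvs if presence.at[sample, a]]
            edges = set()
            for tip_name in observed:
                node = tree.find(tip_name)
                while node.parent is not None:
                    edges.add(id(node))
                    node = node.parent
            oracle = sum(
                n.length or 0
                for n in tree.traverse(include_self=False)
                if id(n) in edges
            )
            assert mine[sample] == pytest.approx(oracle)

    def test_pd_matches_skbio(self):
        rng = np.random.default_rng(4)
        asvs = [f"a{j}" for j in range(12)]
        tree = generate_tree(asvs, seed=9)
        table = random_table(rng, n_samples=8, n_asvs=12, asv_ids=asvs)
        mine = faith_pd(table, tree)
        oracle = alpha_diversity(
            "faith_pd", table.counts.to_numpy(), ids=table.sample_ids,
            tree=tree, taxa=asvs,
        )
        assert np.allclose(mine.values, oracle.values)

    def test_missing_leaf_named(self):
        tree = skbio.TreeNode.read(["(a:1,b:1);"])
        table = make_table([[1, 1]], asv_ids=["a", "zzz"])
        with pytest.raises(ValueError, match="zzz"):
            faith_pd(table, tree)


class TestBeta:
    def test_identical_samples_distance_zero(self):
        asvs = ["a", "b", "c"]
        tree = generate_tree(asvs, seed=1)
        table = make_table([[1, 2, 0], [1, 2, 0]], asv_ids=asvs)
        for metric in ("jaccard", "bray_curtis", "unweighted_unifrac"):
            dm = beta_distance(table, metric, tree=tree)
            assert dm.data[0, 1] == pytest.approx(0.0)

    def test_disjoint_samples_on_star_tree(self):
        tree = skbio.TreeNode.read(["((a:1.0):0.0,(b:1.0):0.0);"])
        table = make_table([[3, 0], [0, 5]], asv_ids=["a", "b"])
        assert beta_distance(table, "jaccard").data[0, 1] == pytest.approx(1.0)
        assert beta_distance(table, "unweighted_unifrac", tree=tree).data[0, 1] == pytest.approx(1.0)

    def test_unifrac_hand_worked_cherry(self):
        # ((a:1,b:2):0.5,(c:1,d:3):0.25);  sample1={a,c}, sample2={a,d}
        # shared: a's branch 1 + both cherry stems 0.75 -> 1.75
        # unique: c 1 + d 3 -> 4; observed total 5.75
        tree = skbio.TreeNode.read(["((a:1,b:2):0.5,(c:1,d:3):0.25);"])
        table = make_table([[1, 0, 1, 0], [1, 0, 0, 1]], asv_ids=list("abcd"))
        dm = beta_distance(table, "unweighted_unifrac", tree=tree)
        assert dm.data[0, 1] == pytest.approx(4 / 5.75)

    def test_bray_curtis_uses_proportions(self):
        # raw counts differ 10x but proportions are identical
        table = make_table([[10, 30], [1, 3]])
        assert beta_distance(table, "bray_curtis").data[0, 1] == pytest.approx(0.0)

    def test_matches_skbio_on_random_tables(self):
        rng = np.random.default_rng(8)
        asvs = [f"a{j}" for j in range(15)]
        tree = generate_tree(asvs, seed=3)
        table = random_table(rng, n_samples=9, n_asvs=15, asv_ids=asvs)
        counts = table.counts.to_numpy()
        uni = beta_distance(table, "unweighted_unifrac", tree=tree)
        sk_uni = beta_diversity(
            "unweighted_unifrac", counts, ids=table.sample_ids, tree=tree, taxa=asvs
        )
        assert np.allclose(uni.data, sk_uni.data)
        jac = beta_distance(table, "jaccard")
        sk_jac = beta_diversity("jaccard", (counts > 0).astype(int), ids=table.sample_ids)
        assert np.allclose(jac.data, sk_jac.data)

    def test_unifrac_without_tree_errors(self):
        table = make_table([[1, 0], [0, 1]])
        with pytest.raises(ValueError, match="tree"):
            beta_distance(table, "unweighted_unifrac")

    def test_triangle_inequality_presence_metrics(self):
        rng = np.random.default_rng(12)
        asvs = [f"a{j}" for j in range(10)]
        tree = generate_tree(asvs, seed=5)
        table = random_table(rng, n_samples=6, n_asvs=10, asv_ids=asvs)
        for metric in ("jaccard", "unweighted_unifrac"):
            d = beta_distance(table, metric, tree=tree).data
            n = d.shape[0]
            for i, j, k in itertools.permutations(range(n), 3):
                assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestPermanova:
    def test_perfect_separation_exact_p(self):
        # two internally-identical, mutually-distant triples
        d = np.ones((6, 6))
        d[:3, :3] = 0.0
        d[3:, 3:] = 0.0
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix([f"s{i}" for i in range(6)], d, "jaccard")
        res = permanova(dm, ["g1"] * 3 + ["g2"] * 3)
        assert res.method == "exact" and res.n_permutations == 20
        # only the observed split and its mirror image reach the maximal F
        assert res.p_value == pytest.approx(2 / 20)

    def test_exact_enumeration_equals_exhaustive_monte_carlo(self):
        rng = np.random.default_rng(3)
        table, groups = two_group_table(rng, n_per_group=3, n_asvs=10)
        dm = beta_distance(table, "jaccard")
        exact = permanova(dm, groups)
        # oracle: recompute over all label orderings by hand
        labels = list(groups)
        f_obs = exact.pseudo_F
        seen = 0
        total = 0
        for perm in set(itertools.permutations(labels)):
            total += 1
            forced = permanova(
                DistanceMatrix(dm.ids, dm.data, dm.metric),
                list(perm),
                n_perm=0,
                enumeration_limit=0,
                seed=0,
            )
            if forced.pseudo_F >= f_obs - 1e-12:
                seen += 1
        assert exact.n_permutations == total == math.comb(6, 3)
        assert exact.p_value == pytest.approx(seen / total)

    def test_statistic_matches_skbio(self):
        rng = np.random.default_rng(6)
        table, groups = two_group_table(rng, n_per_group=6, shift=4)
        dm = beta_distance(table, "bray_curtis")
        mine = permanova(dm, groups, n_perm=99, seed=1, enumeration_limit=1)
        oracle = skbio_permanova(dm.to_skbio(), grouping=groups, permutations=99)
        assert mine.pseudo_F == pytest.approx(oracle["test statistic"])
        assert 0 <= mine.r2 <= 1

    def test_degenerate_grouping_rejected(self):
        d = np.zeros((3, 3))
        dm = DistanceMatrix(["a", "b", "c"], d, "jaccard")
        with pytest.raises(ValueError):
            permanova(dm, ["g1", "g1", "g1"])
        with pytest.raises(ValueError):
            permanova(dm, ["g1", "g1", "g2"])


class TestPermdisp:
    def test_symmetric_groups_high_p(self):
        # two groups with identical internal geometry, far apart
        d = np.full((8, 8), 0.9)
        d[:4, :4] = 0.2
        d[4:, 4:] = 0.2
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix([f"s{i}" for i in range(8)], d, "jaccard")
        labels = np.array(["g1"] * 4 + ["g2"] * 4)
        from scavtrace.stats import _centroid_distances

        z = _centroid_distances(dm, labels)
        # every sample sits equally far from its group centroid
        assert np.allclose(z, z[0])
        res = permdisp(dm, labels, n_perm=199, seed=2)
        assert res.p_value > 0.3

    def test_tight_vs_diffuse_group_detected(self):
        rng = np.random.default_rng(9)
        tight = rng.normal(0, 0.02, size=(10, 3))
        diffuse = rng.normal(0, 0.6, size=(10, 3))
        points = np.vstack([tight, diffuse])
        d = np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1))
        d = d / d.max()
        dm = DistanceMatrix([f"s{i}" for i in range(20)], d, "jaccard")
        res = permdisp(dm, ["t"] * 10 + ["d"] * 10, n_perm=199, seed=3)
        assert res.p_value < 0.05

    def test_seed_reproducible(self):
        rng = np.random.default_rng(10)
        table, groups = two_group_table(rng, n_per_group=4)
        dm = beta_distance(table, "jaccard")
        r1 = permdisp(dm, groups, n_perm=99, seed=7)
        r2 = permdisp(dm, groups, n_perm=99, seed=7)
        assert (r1.statistic, r1.p_value) == (r2.statistic, r2.p_value)


class TestIndval:
    def test_perfect_indicator(self):
        table = make_table([[1], [1], [0], [0]], asv_ids=["x"])
        res = indval(table, ["g1", "g1", "g2", "g2"], n_perm=99, seed=1)
        assert res.loc["x", "stat"] == pytest.approx(1.0)

    def test_printed_partial_indicator_value(self):
        """7/11 presence in one group vs 2/20 in the other gives 0.74."""
        presence = np.zeros((31, 1), dtype=bool)
        presence[:7] = True
        presence[11:13] = True
        mask1 = np.zeros(31, dtype=bool)
        mask1[:11] = True
        stat, best = indval_stat(presence, mask1)
        assert round(float(stat[0]), 2) == 0.74
        assert best[0] == 0

    def test_ubiquitous_taxon_equal_groups(self):
        table = make_table(np.ones((8, 1), dtype=int), asv_ids=["x"])
        res = indval(table, ["g1"] * 4 + ["g2"] * 4, n_perm=99, seed=4)
        assert res.loc["x", "stat"] == pytest.approx(math.sqrt(0.5))
        assert res.loc["x", "p_value"] == 1.0

    def test_more_than_two_groups_unsupported(self):
        table = make_table([[1], [1], [1]], asv_ids=["x"])
        with pytest.raises(ValueError, match="two groups"):
            indval(table, ["a", "b", "c"], n_perm=9, seed=0)

    def test_prevalence_filter(self):
        counts = np.zeros((10, 2), dtype=int)
        counts[:2, 0] = 1  # 20% prevalence
        counts[:1, 1] = 1  # 10% prevalence
        table = make_table(counts)
        kept = prevalence_filter(table, min_prevalence=0.15)
        assert kept.asv_ids == ["asv00"]


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_hand_computed_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_q_at_least_p_and_monotone(self):
        rng = np.random.default_rng(5)
        p = rng.random(50)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(6)
        p = rng.random(30)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_fdr(p), q_sm)
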