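import math

import numpy as np
import pandas as pd
import pytest

from herdscan import relate, simulate
from herdscan.cohort import AlleleCount, Cohort, MISSING, make_samples, make_variants
from .conftest import random_cohort


class TestHudsonSite:
    def test_fixed_difference(self):
        ac1 = AlleleCount(np.array([0]), np.array([10]))
        ac2 = AlleleCount(np.array([10]), np.array([0]))
        n, d = relate.hudson_site(ac1, ac2)
        assert n[0] == pytest.approx(1.0) and d[0] == pytest.approx(1.0)

    def test_balanced_frequencies_known_value(self):
        ac = AlleleCount(np.array([5]), np.array([5]))
        n, d = relate.hudson_site(ac, ac)
        # (p1-p2)^2 = 0 minus two sampling corrections 0.25/9 each
        assert n[0] == pytest.approx(-0.05556, abs=1e-4)
        assert d[0] == pytest.approx(0.5)

    def test_monomorphic_site_contributes_nothing(self):
        ac = AlleleCount(np.array([10]), np.array([0]))
        n, d = relate.hudson_site(ac, ac)
        assert n[0] == 0.0 and d[0] == 0.0

    def test_small_sample_excluded(self):
        ac1 = AlleleCount(np.array([1]), np.array([0]))
        ac2 = AlleleCount(np.array([5]), np.array([5]))
        n, d = relate.hudson_site(ac1, ac2)
        assert n[0] == 0.0 and d[0] == 0.0


class TestFstGenomewide:
    def test_split_halves_of_one_population_near_zero(self):
        cfg = simulate.SimConfig(
            n_pops=1, n_per_pop=50, chrom_lengths={"1": 5_000_000},
            density=1e-3, pop_f=(0.0,), seed=13,
        )
        c, _ = simulate.sim_balding_nichols(cfg)
        relabel = c.samples.copy()
        relabel["population"] = ["A"] * 25 + ["B"] * 25
        c = Cohort(c.variants, relabel, c.genotypes, c.haplotypes, c.phased)
        assert abs(relate.fst_genomewide(c, "A", "B")) < 0.01

    def test_opposite_fixation_is_one(self):
        g = np.array([[0, 0, 2, 2]] * 5, dtype=np.int8)
        c = Cohort(
            variants=make_variants("1", np.arange(1, 6) * 100),
            samples=make_samples(list("abcd"), ["A", "A", "B", "B"]),
            genotypes=g,
        )
        assert relate.fst_genomewide(c, "A", "B") == pytest.approx(1.0)

    def test_allele_label_swap_invariance(self, bn_cohort):
        c = bn_cohort[0]
        est = relate.fst_genomewide(c, "P1", "P2")
        flipped = Cohort(
            c.variants, c.samples, (2 - c.genotypes).astype(np.int8)
        )
        assert relate.fst_genomewide(flipped, "P1", "P2") == pytest.approx(
            est, abs=1e-12
        )

    def test_parameter_recovery(self, bn_cohort):
        c, truth = bn_cohort
        est = relate.fst_genomewide(c, "P1", "P2")
        assert est == pytest.approx(truth.pop_fst["P1,P2"], abs=0.03)


class TestFstMatrixAndWindows:
    def test_matrix_sorted_and_rank_recovery(self):
        cfg = simulate.SimConfig(
            n_pops=3, n_per_pop=25, chrom_lengths={"1": 5_000_000},
            density=1e-3, pop_f=(0.0, 0.06, 0.16), seed=17,
        )
        c, _ = simulate.sim_balding_nichols(cfg)
        table = relate.fst_matrix(c, "P1", ["P2", "P3"])
        assert table["population"].tolist() == ["P2", "P3"]
        assert table["fst"].is_monotonic_increasing

    def test_sample_permutation_invariance(self, bn_cohort, rng):
        c = bn_cohort[0]
        est = relate.fst_genomewide(c, "P1", "P2")
        perm = rng.permutation(c.n_samples)
        assert relate.fst_genomewide(
            c.take_samples(perm), "P1", "P2"
        ) == pytest.approx(est, abs=1e-12)

    def test_window_min_snps_rule(self, bn_cohort):
        c = bn_cohort[0]
        win4 = relate.fst_windows(c, "P1", "P2", window_bp=3_000, min_snps=5)
        # every reported window really holds >= 5 usable variants
        assert (win4["n_snps"] >= 5).all()

    def test_windows_match_per_window_ratio(self, bn_cohort):
        c = bn_cohort[0]
        win = relate.fst_windows(c, "P1", "P2", window_bp=10_000, min_snps=1)
        sub = relate.segregating_subset(c, ["P1", "P2"])
        num, den = relate.hudson_site(
            sub.allele_counts("P1"), sub.allele_counts("P2")
        )
        pos = sub.variants["pos"].to_numpy()
        for row in win.itertuples(index=False):
            m = (pos >= row.start) & (pos <= row.end)
            assert row.value == pytest.approx(
                num[m].sum() / den[m].sum(), abs=1e-12
            )


class TestTopFractionWindows:
    def window_table(self, values):
        n = len(values)
        return pd.DataFrame(
            {
                "chrom": ["1"] * n,
                "start": np.arange(n) * 10_000 + 1,
                "end": (np.arange(n) + 1) * 10_000,
                "n_snps": [9] * n,
                "value": values,
            }
        )

    def test_ceiling_rule_small_n(self, rng):
        thr, regions = relate.top_fraction_windows(
            self.window_table(rng.random(10)), top_fraction=1e-4
        )
        assert regions["n_windows"].sum() == 1

    def test_adjacent_windows_merge_into_20kb_region(self):
        vals = [0.01] * 6
        vals[2] = 0.9
        vals[3] = 0.8
        thr, regions = relate.top_fraction_windows(
            self.window_table(vals), top_fraction=0.33
        )
        assert len(regions) == 1
        r = regions.iloc[0]
        assert (r.start, r.end) == (20_001, 40_000)
        assert r.end - r.start + 1 == 20_000

    def test_non_adjacent_stay_separate(self):
        vals = [0.0] * 9
        vals[1] = vals[7] = 1.0
        thr, regions = relate.top_fraction_windows(
            self.window_table(vals), top_fraction=0.23
        )
        assert len(regions) == 2


class TestManhattan:
    def test_identical_and_simple_distances(self):
        g = np.array([[0, 0, 2], [2, 2, 0]], dtype=np.int8)
        c = Cohort(
            variants=make_variants("1", [10, 20]),
            samples=make_samples(list("abc"), ["X"] * 3),
            genotypes=g,
        )
        d, labels = relate.manhattan_matrix(c)
        assert d[0, 1] == 0.0
        assert d[0, 2] == 4.0
        assert np.allclose(d, d.T) and np.all(np.diag(d) == 0)

    def test_missingness_rescaling(self, rng):
        c = random_cohort(rng, n_sites=400, n_samples=6)
        d_full, _ = relate.manhattan_matrix(c)
        g = c.genotypes.copy()
        g[rng.random(g.shape) < 0.1] = MISSING
        d_miss, _ = relate.manhattan_matrix(Cohort(c.variants, c.samples, g))
        ratio = d_miss[0, 1:] / d_full[0, 1:]
        assert np.all(np.abs(ratio - 1) < 0.05)


def reference_upgma(dist, labels):
    """Naive O(n^3) UPGMA recomputing cluster distances from the raw matrix."""
    clusters = [[i] for i in range(len(labels))]
    nodes = [relate.Node(label=labels[i]) for i in range(len(labels))]
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean(
                    [dist[i, j] for i in clusters[a] for j in clusters[b]]
                )
                key = (
                    d,
                    tuple(
                        sorted(
                            (
                                min(labels[i] for i in clusters[a]),
                                min(labels[j] for j in clusters[b]),
                            )
                        )
                    ),
                )
                if best is None or key < best[0]:
                    best = (key, a, b)
        (d, _), a, b = best
        node = relate.Node(height=d / 2, children=(nodes[a], nodes[b]))
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
        nodes = [n for k, n in enumerate(nodes) if k not in (a, b)] + [node]
    return nodes[0]


def tree_signature(node):
    if node.is_leaf:
        return ("L", node.label)
    subs = sorted(tree_signature(c) for c in node.children)
    return ("N", round(float(node.height), 9), tuple(subs))


class TestUpgma:
    def test_two_leaves(self):
        t = relate.upgma(np.array([[0.0, 4.0], [4.0, 0.0]]), ["A", "B"])
        assert t.height == 2.0
        assert sorted(t.leaves()) == ["A", "B"]

    def test_matches_naive_reference_on_random_matrices(self, rng):
        for _ in range(25):
            n = 12
            x = rng.random((n, n))
            d = np.triu(x, 1)
            d = d + d.T
            labels = [f"t{i:02d}" for i in range(n)]
            got = relate.upgma(d, labels)
            want = reference_upgma(d, labels)
            assert tree_signature(got) == tree_signature(want)

    def test_tie_handling_matches_reference(self, rng):
        for _ in range(10):
            n = 8
            d = rng.integers(1, 4, size=(n, n)).astype(float)  # many ties
            d = np.triu(d, 1)
            d = d + d.T
            labels = [f"t{i}" for i in range(n)]
            assert tree_signature(relate.upgma(d, labels)) == tree_signature(
                reference_upgma(d, labels)
            )

    def test_ultrametric_property(self, rng):
        n = 10
        x = rng.random((n, n))
        d = np.triu(x, 1)
        d = d + d.T
        t = relate.upgma(d, [f"t{i}" for i in range(n)])

        # leaf-to-root distance = root height for every leaf (exact)
        def depth_to_root(node, h):
            if node.is_leaf:
                return [h]
            out = []
            for c in node.children:
                out += depth_to_root(c, h)
            return out

        assert np.allclose(depth_to_root(t, t.height), t.height)


class TestNewick:
    def test_two_leaf_output(self):
        t = relate.upgma(np.array([[0.0, 4.0], [4.0, 0.0]]), ["A", "B"])
        assert relate.to_newick(t) == "(A:2,B:2);"

    @staticmethod
    def assert_trees_close(a, b, tol=1e-9):
        assert a.is_leaf == b.is_leaf
        if a.is_leaf:
            assert a.label == b.label
            return
        assert abs(a.height - b.height) < tol
        key = lambda n: sorted(n.leaves())
        for ca, cb in zip(
            sorted(a.children, key=key), sorted(b.children, key=key)
        ):
            TestNewick.assert_trees_close(ca, cb, tol)

    def test_round_trip_random_trees(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 12))
            x = rng.random((n, n)) * 10
            d = np.triu(x, 1)
            d = d + d.T
            t = relate.upgma(d, [f"t{i}" for i in range(n)])
            back = relate.from_newick(relate.to_newick(t))
            self.assert_trees_close(back, t)

    def test_dendropy_cross_check(self, rng):
        import dendropy

        n = 8
        x = rng.random((n, n)) * 5
        d = np.triu(x, 1)
        d = d + d.T
        labels = [f"t{i}" for i in range(n)]
        nwk = relate.to_newick(relate.upgma(d, labels))
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert sorted(l.taxon.label for l in tree.leaf_node_iter()) == labels
        # ultrametric: root-to-leaf path lengths all equal
        depths = [l.distance_from_root() for l in tree.leaf_node_iter()]
        assert max(depths) - min(depths) < 1e-9

    def test_unbalanced_parenthesis_raises(self):
        with pytest.raises(relate.NewickError):
            relate.from_newick("((A:1,B:1):1;")


class TestPruneOutliers:
    def breed_tree(self):
        # ((a1,a2),((b1,b2),a3)) : breed A splits 2 + 1
        a1, a2, a3 = (relate.Node(label=x) for x in ("a1", "a2", "a3"))
        b1, b2 = (relate.Node(label=x) for x in ("b1", "b2"))
        inner_a = relate.Node(height=1.0, children=(a1, a2))
        inner_b = relate.Node(height=1.0, children=(b1, b2))
        mid = relate.Node(height=2.0, children=(inner_b, a3))
        root = relate.Node(height=3.0, children=(inner_a, mid))
        breed_of = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B"}
        return root, breed_of

    def test_minority_cluster_removed(self):
        root, breed_of = self.breed_tree()
        kept, removed, collapsed = relate.prune_outlier_animals(root, breed_of)
        assert removed == ["a3"]
        assert kept == ["a1", "a2", "b1", "b2"]

    def test_collapsed_tree_has_one_leaf_per_breed(self):
        root, breed_of = self.breed_tree()
        _, _, collapsed = relate.prune_outlier_animals(root, breed_of)
        assert sorted(collapsed.leaves()) == ["A", "B"]

    def test_pure_breed_untouched(self):
        a1, a2 = relate.Node(label="a1"), relate.Node(label="a2")
        b1 = relate.Node(label="b1")
        root = relate.Node(
            height=2.0, children=(relate.Node(height=1.0, children=(a1, a2)), b1)
        )
        kept, removed, _ = relate.prune_outlier_animals(
            root, {"a1": "A", "a2": "A", "b1": "B"}
        )
        assert removed == []


class TestGrm:
    @staticmethod
    def with_duplicated_first_sample(cohort):
        idx = np.array([0, 0, 1, 2, 3, 4, 5, 6, 7, 8])
        geno = cohort.genotypes[:, idx]
        samples = make_samples(
            [f"s{i}" for i in range(10)], ["X"] * 10
        )
        return Cohort(cohort.variants, samples, geno)

    def test_duplicate_sample_relationship(self, bn_cohort):
        c = bn_cohort[0].take_samples(np.arange(10))
        dup = self.with_duplicated_first_sample(c)
        g, labels = relate.grm(dup)
        assert g[0, 1] == pytest.approx(g[0, 0], rel=1e-9)
        assert np.allclose(g, g.T)

    def test_unrelated_hwe_pairs_centred_at_zero(self):
        cfg = simulate.SimConfig(
            n_pops=1, n_per_pop=20, chrom_lengths={"1": 3_000_000},
            density=1e-3, pop_f=(0.0,), seed=23,
        )
        c, _ = simulate.sim_balding_nichols(cfg)
        g, _ = relate.grm(c)
        n = c.n_samples
        off = g[np.triu_indices_from(g, 1)]
        # centering by sample frequencies forces E[off-diagonal] = -1/(n-1)
        assert off.mean() == pytest.approx(-1 / (n - 1), abs=0.01)
        assert g.diagonal().mean() == pytest.approx(1.0, abs=0.05)

    def test_permutation_invariance(self, bn_cohort, rng):
        c = bn_cohort[0].take_samples(np.arange(8))
        g, labels = relate.grm(c)
        perm = rng.permutation(8)
        g2, labels2 = relate.grm(c.take_samples(perm))
        for i in range(8):
            for j in range(8):
                assert g2[i, j] == pytest.approx(
                    g[perm[i], perm[j]], abs=1e-12
                )


class TestLeastRelatedSubset:
    def test_k_equals_n_returns_everyone(self):
        g = np.eye(4)
        out = relate.least_related_subset(g, list("abcd"), k=4, seed=0)
        assert sorted(out) == list("abcd")

    def test_clone_pair_not_both_selected(self, bn_cohort):
        c = bn_cohort[0].take_samples(np.arange(10))
        clone = TestGrm.with_duplicated_first_sample(c)
        g, labels = relate.grm(clone)
        out = relate.least_related_subset(g, labels, k=8, seed=1)
        assert not {"s0", "s1"} <= set(out)

    def test_deterministic_given_seed(self, bn_cohort):
        c = bn_cohort[0]
        g, labels = relate.grm(c)
        a = relate.least_related_subset(g, labels, k=10, seed=5)
        b = relate.least_related_subset(g, labels, k=10, seed=5)
        assert a == b

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            relate.least_related_subset(np.eye(3), list("abc"), k=4, seed=0)


class TestF3:
    def simulate_trio(self, seed, admixed):
        rng = np.random.default_rng(seed)
        n_sites = 20_000
        pos = {"1": np.sort(rng.choice(40_000_000, n_sites, replace=False)) + 1}
        p0 = rng.uniform(0.05, 0.95, n_sites)
        F = 0.1
        pa = rng.beta(p0 * (1 - F) / F, (1 - p0) * (1 - F) / F)
        pb = rng.beta(p0 * (1 - F) / F, (1 - p0) * (1 - F) / F)
        if admixed:
            pc = 0.5 * pa + 0.5 * pb
        else:
            pc = rng.beta(p0 * (1 - F) / F, (1 - p0) * (1 - F) / F)
        return simulate.cohort_from_pop_freqs(
            {"A": pa, "B": pb, "C": pc}, pos, 20, rng
        )

    def test_admixed_target_negative(self):
        res = relate.f3(self.simulate_trio(31, True), "C", "A", "B", 5_000)
        assert res.f3 < 0 and res.z < -3

    def test_drifted_target_positive(self):
        res = relate.f3(self.simulate_trio(32, False), "C", "A", "B", 5_000)
        assert res.f3 > 0

    def test_self_comparison_near_zero(self, bn_cohort):
        c = bn_cohort[0]
        half = c.samples.copy()
        half["population"] = ["A"] * 10 + ["C"] * 10 + ["B"] * 20
        c2 = Cohort(c.variants, half, c.genotypes)
        res = relate.f3(c2, "C", "A", "B", block_variants=500)
        assert abs(res.z) < 4

    def test_too_few_blocks_rejected(self, bn_cohort):
        with pytest.raises(ValueError):
            relate.f3(bn_cohort[0], "P1", "P2", "P2", block_variants=10**7)
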