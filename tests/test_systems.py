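import itertools

import numpy as np
import pytest

import mihc
from mihc.selection import NonNoiseSystem

from conftest import naive_bag_distance


def _make_annot(pairs):
    return mihc.AnnotationMap.from_pairs(pairs)


class TestGnc:
    def test_under_populated_chain_propagates(self, chain_dag):
        am = _make_annot([(f"g{i}", "leaf") for i in range(5)])
        # leaf (5 genes) < 10 -> mid -> still 5 < 10 -> root -> root dropped
        with pytest.raises(ValueError):
            mihc.gnc(am, chain_dag, lam=10)
        ls = mihc.gnc(am, chain_dag, lam=5)
        # leaf already holds exactly 5 genes: nothing moves
        assert [c.label for c in ls.classes] == ["leaf", "mid", "root"] or \
            any("leaf" in c.label for c in ls.classes)

    def test_exact_lam_is_fixed_point(self, chain_dag):
        am = _make_annot([(f"g{i}", "leaf") for i in range(3)])
        ls = mihc.gnc(am, chain_dag, lam=3)
        leaf_classes = [c for c in ls.classes if "leaf" in c.term_ids]
        assert leaf_classes and leaf_classes[0].genes == frozenset({"g0", "g1", "g2"})

    def test_multi_parent_fan_out(self):
        dag = mihc.GoDag.from_edges(
            [("leaf", "p1"), ("leaf", "p2"), ("p1", "root"), ("p2", "root")])
        am = _make_annot([(f"g{i}", "leaf") for i in range(6)]
                         + [(f"p1g{i}", "p1") for i in range(4)]
                         + [(f"p2g{i}", "p2") for i in range(4)])
        ls = mihc.gnc(am, dag, lam=10)
        by_term = {next(iter(c.term_ids)): c.genes for c in ls.classes}
        assert {"p1", "p2"} <= set(by_term)
        for p in ("p1", "p2"):
            assert {f"g{i}" for i in range(6)} <= by_term[p]

    def test_every_class_holds_at_least_lam(self, default_synthetic):
        _, dag, annot, _ = default_synthetic
        for lam in (5, 10, 20):
            ls = mihc.gnc(annot, dag, lam=lam)
            assert all(len(c.genes) >= lam for c in ls.classes)

    def test_lam_one_keeps_leaves(self, chain_dag):
        am = _make_annot([("g0", "leaf")])
        ls = mihc.gnc(am, chain_dag, lam=1)
        assert any("leaf" in c.term_ids for c in ls.classes)


class TestGolc:
    def _diamond(self):
        # root <- a <- c, root <- b <- c  (c has two level-2... wait, two level-1 ancestors)
        return mihc.GoDag.from_edges(
            [("a", "root"), ("b", "root"), ("c", "a"), ("c", "b")])

    def test_single_ancestor(self, chain_dag):
        am = _make_annot([("g", "leaf")])
        ls = mihc.golc(am, chain_dag, iota=1)
        assert len(ls.classes) == 1
        assert ls.classes[0].term_ids == frozenset({"mid"})
        assert ls.classes[0].genes == frozenset({"g"})

    def test_identity_at_target_level(self, chain_dag):
        am = _make_annot([("g", "mid")])
        ls = mihc.golc(am, chain_dag, iota=1)
        assert ls.classes[0].term_ids == frozenset({"mid"})

    def test_two_ancestors_duplicate_gene(self):
        dag = self._diamond()
        am = _make_annot([("g", "c")])
        ls = mihc.golc(am, dag, iota=1)
        assert {next(iter(c.term_ids)) for c in ls.classes} == {"a", "b"}
        assert all(c.genes == frozenset({"g"}) for c in ls.classes)

    def test_all_classes_at_level_iota(self, default_synthetic):
        _, dag, annot, _ = default_synthetic
        for iota in (1, 2):
            ls = mihc.golc(annot, dag, iota=iota)
            for c in ls.classes:
                for t in c.term_ids:
                    assert mihc.term_level(dag, t) == iota

    def test_annotation_above_level_contributes_nothing(self, chain_dag):
        am = _make_annot([("g", "root")])
        with pytest.raises(ValueError):
            mihc.golc(am, chain_dag, iota=1)


class TestBagDistance:
    def _bags(self, seed=0, n=3, m=4, t=10):
        rng = np.random.default_rng(seed)
        return rng.normal(size=(n, t)), rng.normal(size=(m, t))

    def test_identical_bags_zero(self):
        a, _ = self._bags()
        assert mihc.bag_distance(a, a, "avg_hausdorff") == pytest.approx(0.0)

    def test_singletons_reduce_to_instance_distance(self):
        a, b = self._bags(n=1, m=1)
        expected = 1 - mihc.pearson_r(a[0], b[0])
        for mode in ("avg_hausdorff", "max_hausdorff", "min_hausdorff"):
            assert mihc.bag_distance(a, b, mode) == pytest.approx(expected)

    def test_two_vs_one_hand_formula(self):
        # a = {p, q}, b = {p}: avg = (0 + d(p,q) + 0) / 3
        rng = np.random.default_rng(4)
        p, q = rng.normal(size=(2, 12))
        d_pq = 1 - mihc.pearson_r(p, q)
        got = mihc.bag_distance(np.vstack([p, q]), p[None, :], "avg_hausdorff")
        assert got == pytest.approx(d_pq / 3)

    @pytest.mark.parametrize("mode", ["avg_hausdorff", "max_hausdorff", "min_hausdorff"])
    def test_symmetric_nonnegative_matches_naive(self, mode):
        for seed in range(5):
            a, b = self._bags(seed=seed)
            ab = mihc.bag_distance(a, b, mode)
            ba = mihc.bag_distance(b, a, mode)
            assert ab == pytest.approx(ba)
            assert ab >= 0
            assert ab == pytest.approx(naive_bag_distance(a, b, mode))

    def test_constant_profile_maximal(self):
        a = np.ones((1, 8))
        b = np.random.default_rng(0).normal(size=(1, 8))
        assert mihc.bag_distance(a, b) == pytest.approx(2.0)


def _nns_from_bags(bags):
    """Build a NonNoiseSystem whose terms are synthetic bags of profiles."""
    genes, rows, cliques, pairs = [], [], {}, []
    for t, bag in enumerate(bags):
        term = f"T{t}"
        members = []
        for i, prof in enumerate(bag):
            gid = f"T{t}_g{i}"
            genes.append(gid)
            rows.append(prof)
            members.append(gid)
            pairs.append((gid, term))
        cliques[term] = frozenset(members)
    expr = mihc.TimeCourseMatrix(genes, np.arange(len(rows[0]), dtype=float),
                                 np.array(rows))
    return NonNoiseSystem(cliques, expr, mihc.AnnotationMap.from_pairs(pairs))


def naive_mihc_merges(bags, stop_tau, mode="avg_hausdorff"):
    """Oracle: recompute all pairwise bag distances from scratch each step."""
    clusters = {i: np.array(b) for i, b in enumerate(bags)}
    merges = []
    next_id = len(bags)
    while len(clusters) > 1:
        keys = sorted(clusters)
        h, a, b = min(
            (naive_bag_distance(clusters[i], clusters[j], mode), i, j)
            for i, j in itertools.combinations(keys, 2)
        )
        if h > stop_tau:
            break
        merged = np.vstack([clusters.pop(a), clusters.pop(b)])
        clusters[next_id] = merged
        merges.append((a, b, h, next_id))
        next_id += 1
    return merges


class TestMihc:
    def _random_bags(self, seed, n_bags=5, max_inst=4, t=12):
        rng = np.random.default_rng(seed)
        return [rng.normal(size=(int(rng.integers(1, max_inst + 1)), t))
                for _ in range(n_bags)]

    @pytest.mark.parametrize("seed", range(5))
    def test_merge_sequence_matches_naive_oracle(self, seed):
        bags = self._random_bags(seed)
        nns = _nns_from_bags(bags)
        ls, dendro = mihc.mihc(nns, stop_tau=np.inf)
        expected = naive_mihc_merges(bags, np.inf)
        assert len(dendro.merges) == len(expected)
        for got, exp in zip(dendro.merges, expected):
            assert got[:2] == exp[:2]
            assert got[2] == pytest.approx(exp[2], abs=1e-9)
            assert got[3] == exp[3]

    def test_merge_heights_equal_current_minimum(self, default_synthetic):
        expr, _, annot, _ = default_synthetic
        nns = mihc.build_non_noise_system(mihc.preprocess(expr), annot)
        _, dendro = mihc.mihc(nns, stop_tau=np.inf)
        # replay: every recorded height must be the matrix minimum at its step
        terms = nns.terms
        gene_idx = {g: i for i, g in enumerate(nns.expression.gene_ids)}
        bags = {i: [gene_idx[g] for g in nns.term_cliques[t]] for i, t in enumerate(terms)}
        active = set(bags)
        for a, b, h, new in dendro.merges:
            cur_min = min(
                naive_bag_distance(nns.expression.values[bags[i]],
                                   nns.expression.values[bags[j]])
                for i, j in itertools.combinations(sorted(active), 2)
            )
            assert h == pytest.approx(cur_min, abs=1e-9)
            bags[new] = sorted(set(bags[a]) | set(bags[b]))
            active -= {a, b}
            active.add(new)

    def test_tau_zero_no_merges(self, seed=0):
        bags = self._random_bags(seed)
        nns = _nns_from_bags(bags)
        ls, dendro = mihc.mihc(nns, stop_tau=0.0)
        assert dendro.merges == []
        assert ls.n_classes == len(bags)

    def test_tau_inf_single_class(self):
        bags = self._random_bags(1)
        nns = _nns_from_bags(bags)
        ls, _ = mihc.mihc(nns, stop_tau=np.inf)
        assert ls.n_classes == 1
        assert ls.classes[0].genes == frozenset(nns.expression.gene_ids)

    def test_gene_set_conserved(self, default_synthetic):
        expr, _, annot, _ = default_synthetic
        nns = mihc.build_non_noise_system(mihc.preprocess(expr), annot)
        ls, _ = mihc.mihc(nns)
        union = set().union(*(c.genes for c in ls.classes))
        assert union == set(nns.expression.gene_ids)

    def test_single_term_system(self, tiny_expr):
        nns = NonNoiseSystem(
            {"only": frozenset({"g1", "g2"})},
            tiny_expr.subset(["g1", "g2"]),
            mihc.AnnotationMap.from_pairs([("g1", "only"), ("g2", "only")]),
        )
        ls, dendro = mihc.mihc(nns)
        assert ls.n_classes == 1
        assert dendro.merges == []

    def test_planted_groups_recovered(self):
        rng = np.random.default_rng(11)
        t = np.arange(18)
        base1 = np.sin(2 * np.pi * t / 18)
        base2 = np.sin(4 * np.pi * t / 18)
        bags = [np.vstack([b + rng.normal(0, 0.1, 18) for _ in range(3)])
                for b in (base1, base1, base2, base2)]
        nns = _nns_from_bags(bags)
        ls, _ = mihc.mihc(nns, stop_tau=0.5)
        groups = {frozenset(c.term_ids) for c in ls.classes}
        assert groups == {frozenset({"T0", "T1"}), frozenset({"T2", "T3"})}

    def test_newick_well_formed(self, default_synthetic):
        expr, _, annot, _ = default_synthetic
        nns = mihc.build_non_noise_system(mihc.preprocess(expr), annot)
        _, dendro = mihc.mihc(nns, stop_tau=np.inf)
        nwk = dendro.to_newick()
        assert nwk.endswith(";")
        for leaf in dendro.leaf_names:
            assert leaf in nwk


class TestLabelMatrix:
    def test_matches_class_membership(self, default_synthetic):
        _, dag, annot, _ = default_synthetic
        ls = mihc.golc(annot, dag, iota=1)
        Y = ls.label_matrix
        for j, c in enumerate(ls.classes):
            for i, g in enumerate(ls.gene_ids):
                assert Y[i, j] == int(g in c.genes)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            mihc.LearningSystem(
                classes=[mihc.SystemClass(frozenset({"t"}), frozenset())],
                gene_ids=[], method_tag="GNC")
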