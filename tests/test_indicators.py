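"""Indicator statistics for genera and phylogeny nodes."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from evoregions import (
    AssemblageMatrix,
    indicator_nodes,
    indval,
    indval_genera,
    read_newick,
    site_by_node_matrix,
)

from conftest import make_random_matrix, make_random_tree, naive_indval


def matrix_with_labels(occ, labels, genera=None):
    occ = np.asarray(occ)
    genera = genera or [f"g{j}" for j in range(occ.shape[1])]
    m = AssemblageMatrix(pd.DataFrame(
        occ, index=[f"s{i}" for i in range(occ.shape[0])], columns=genera))
    return m, np.asarray(labels)


class TestIndvalGenera:
    def test_perfect_indicator(self):
        # g0 fills group 1 and is absent from group 2
        occ = [[1, 1], [1, 0], [0, 1], [0, 0]]
        m, labels = matrix_with_labels(occ, [1, 1, 2, 2])
        table = indval_genera(m, labels)
        row = table.best[table.best["unit"] == "g0"].iloc[0]
        assert row["combo"] == (1,)
        assert (row["A"], row["B"], row["stat"]) == (1.0, 1.0, 1.0)

    def test_ubiquitous_genus_gets_smallest_combo_by_tie_rule(self):
        occ = [[1], [1], [1], [1]]
        m, labels = matrix_with_labels(occ, [1, 1, 2, 2])
        table = indval_genera(m, labels)
        row = table.best.iloc[0]
        # B = 1 for every combo; A maximal (and tied) for singletons
        assert row["combo"] == (1,)

    def test_absent_genus_excluded(self):
        occ = [[1, 0], [1, 0], [0, 0], [1, 0]]
        m, labels = matrix_with_labels(occ, [1, 1, 2, 2])
        table = indval_genera(m, labels)
        assert "g1" not in set(table.best["unit"])

    def test_combo_never_full_group_set(self):
        m, labels = matrix_with_labels(
            np.ones((6, 3), dtype=int), [1, 1, 2, 2, 3, 3])
        table = indval_genera(m, labels)
        assert all(len(c) < 3 for c in table.per_combo["combo"])

    def test_stat_squared_equals_a_times_b(self):
        tree = make_random_tree(0, n_tips=10)
        m = make_random_matrix(tree, 0, n_sites=12)
        labels = np.array([1, 2, 3] * 4)
        table = indval_genera(m, labels)
        np.testing.assert_allclose(table.per_combo["stat"] ** 2,
                                   table.per_combo["A"]
                                   * table.per_combo["B"], atol=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_contingency_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        occ = (rng.random((12, 8)) < 0.4).astype(int)
        m, labels = matrix_with_labels(occ, rng.integers(1, 4, 12))
        if len(np.unique(labels)) < 2:
            pytest.skip("degenerate draw")
        table = indval_genera(m, labels)
        groups = sorted(np.unique(labels))
        combos = [c for r in range(1, len(groups))
                  for c in combinations(groups, r)]
        expected = naive_indval(m.data, labels, combos)
        for _, row in table.per_combo.iterrows():
            A, B, stat = expected[(row["unit"], row["combo"])]
            assert row["A"] == pytest.approx(A, abs=1e-12)
            assert row["B"] == pytest.approx(B, abs=1e-12)
            assert row["stat"] == pytest.approx(stat, abs=1e-12)

    def test_site_reordering_invariance(self):
        rng = np.random.default_rng(3)
        occ = (rng.random((10, 6)) < 0.5).astype(int)
        m, labels = matrix_with_labels(occ, [1, 2] * 5)
        t1 = indval_genera(m, labels)
        perm = rng.permutation(10)
        m2 = AssemblageMatrix(m.data.iloc[perm])
        t2 = indval_genera(m2, labels[perm])
        merged = t1.best.merge(t2.best, on="unit", suffixes=("_a", "_b"))
        assert (merged["stat_a"] == merged["stat_b"]).all()
        assert (merged["combo_a"] == merged["combo_b"]).all()

    def test_group_with_zero_sites_rejected(self):
        m, labels = matrix_with_labels([[1], [1]], [1, 1])
        with pytest.raises(ValueError):
            indval_genera(m, labels)


class TestSiteByNodeMatrix:
    def test_root_column_all_ones(self):
        tree = make_random_tree(1, n_tips=10)
        m = make_random_matrix(tree, 1, n_sites=6)
        pa = site_by_node_matrix(tree, m)
        assert (pa[tree.root] == 1).all()

    def test_cherry_is_or_of_children(self, basic_tree):
        m, _ = matrix_with_labels(
            [[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 0]],
            [1, 1, 2, 2], genera=["A", "B", "C"])
        pa = site_by_node_matrix(basic_tree, m)
        cherry = basic_tree.parent[basic_tree.tip_id("A")]
        np.testing.assert_array_equal(pa[cherry].to_numpy(), [1, 1, 0, 1])

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_descendant_set_oracle(self, seed):
        tree = make_random_tree(seed, n_tips=12)
        m = make_random_matrix(tree, seed, n_sites=7)
        pa = site_by_node_matrix(tree, m)
        tipsets = tree.descendant_tips()
        for node in pa.columns:
            for i, site in enumerate(m.site_ids):
                expected = int(bool(tipsets[node] & m.tips_at(site)))
                assert pa.iloc[i][node] == expected


class TestIndicatorNodes:
    def test_perfect_clade_selects_mrca_only(self):
        tree = read_newick(
            "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);")
        # group 1 sites hold exactly the ABCD clade, group 2 the EFGH clade
        occ = np.zeros((6, 8), dtype=int)
        occ[:3, :4] = 1
        occ[3:, 4:] = 1
        m, labels = matrix_with_labels(occ, [1, 1, 1, 2, 2, 2],
                                       genera=list("ABCDEFGH"))
        _, selection, _ = indicator_nodes(tree, m, labels)
        tipsets = tree.descendant_tips()
        for combo in [(1,), (2,)]:
            rows = selection[selection["combo"] == combo]
            perfect = rows[rows["stat"] >= 1.0 - 1e-12]
            assert len(perfect) == 1
            node = int(perfect.iloc[0]["node"])
            assert tipsets[node] in ({"A", "B", "C", "D"},
                                     {"E", "F", "G", "H"})

    def test_two_disjoint_perfect_clades_both_selected(self):
        tree = read_newick(
            "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);")
        # group 1 sites hold the AB and EF cherries; group 2 the rest
        occ = np.zeros((6, 8), dtype=int)
        cols = list("ABCDEFGH")
        for s in range(3):
            occ[s, [0, 1, 4, 5]] = 1
        for s in range(3, 6):
            occ[s, [2, 3, 6, 7]] = 1
        m, labels = matrix_with_labels(occ, [1, 1, 1, 2, 2, 2], genera=cols)
        _, selection, _ = indicator_nodes(tree, m, labels)
        tipsets = tree.descendant_tips()
        g1 = selection[(selection["combo"] == (1,))
                       & (selection["stat"] >= 1.0 - 1e-12)]
        chosen = {frozenset(tipsets[int(n)]) for n in g1["node"]}
        assert {frozenset("AB"), frozenset("EF")} <= chosen

    @pytest.mark.parametrize("seed", range(4))
    def test_selection_is_maximal_stat_antichain(self, seed):
        """The kept nodes form an antichain, and every skipped node is
        nested with some kept node of greater or equal stat."""
        tree = make_random_tree(seed, n_tips=12)
        m = make_random_matrix(tree, seed, n_sites=10)
        labels = np.array([1, 2] * 5)
        table, selection, skipped = indicator_nodes(tree, m, labels)
        tipsets = tree.descendant_tips()

        def nested(a, b):
            return tipsets[a] <= tipsets[b] or tipsets[b] <= tipsets[a]

        stat = dict(zip(table.best["unit"], table.best["stat"]))
        combo = dict(zip(table.best["unit"], table.best["combo"]))
        for c in set(selection["combo"]):
            kept = [int(n) for n in
                    selection[selection["combo"] == c]["node"]]
            for a, b in combinations(kept, 2):
                assert not nested(a, b)
            for node in skipped:
                if combo[node] != c:
                    continue
                better = [k for k in kept
                          if nested(node, k) and stat[k] >= stat[node] - 1e-12]
                assert better, f"node {node} skipped without cause"
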