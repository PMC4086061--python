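import numpy as np
import pytest

from basenet import (build_table, enumerate_trees, filter_redundant,
                     hit_unions, make_query, match_pattern, scan,
                     tree_from_edges)
from conftest import make_base, make_bond, random_bond_table
from oracles import exhaustive_matches, subtree_census


def path_table(n, code="G"):
    """n bases in a line, one bond per edge (geometry-free)."""
    nodes = [make_base("A", 10 + k, code, k) for k in range(n)]
    donors = {"G": "N1", "A": "N6", "C": "N4", "U": "N3"}
    accept = {"G": "N7", "A": "N7", "C": "O2", "U": "O2"}
    bonds = [make_bond(nodes[k], donors[code], nodes[k + 1], accept[code])
             for k in range(n - 1)]
    return build_table(bonds)


def star_table(n_leaves=3):
    centre = make_base("A", 10, "G", 0)
    leaves = [make_base("A", 12 + 2 * k, "G", k + 1) for k in range(n_leaves)]
    donors = ["N1", "N2"]
    bonds = []
    for k, leaf in enumerate(leaves):
        if k < 2:
            bonds.append(make_bond(centre, donors[k], leaf, "N7"))
        else:
            bonds.append(make_bond(leaf, "N1", centre, "N7"))
    return build_table(bonds)


class TestMatchPattern:
    def test_triple_query_finds_the_triple(self, triple_table):
        path = tree_from_edges([(0, 1), (1, 2)])
        q = make_query(path, ["A", "A", "U"], [2, 2])
        matches = match_pattern(triple_table, q)
        assert len(matches) >= 1
        assert matches[0].base_set == frozenset(
            {("A", 9, ""), ("A", 12, ""), ("A", 23, "")})

    def test_empty_table(self):
        q = make_query(tree_from_edges([(0, 1)]))
        assert match_pattern(build_table([]), q) == []

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("induced", [False, True])
    def test_equals_exhaustive_oracle(self, seed, induced):
        rng = np.random.default_rng(900 + seed)
        table = random_bond_table(rng, max_nodes=8)
        for n in (2, 3, 4):
            for tree in enumerate_trees(n):
                labels = [str(rng.choice(["*", "A", "C", "G", "U"]))
                          for _ in range(n)]
                q = make_query(tree, labels)
                got = sorted(m.assignment for m in
                             match_pattern(table, q, induced=induced))
                want = exhaustive_matches(table, q, induced=induced)
                assert got == want

    def test_monomorphism_allows_extra_edges(self):
        # triangle-free query on a multiply-connected table
        tri = [make_base("A", 10 + k, "G", k) for k in range(3)]
        bonds = [make_bond(tri[0], "N1", tri[1], "N7"),
                 make_bond(tri[1], "N1", tri[2], "N7"),
                 make_bond(tri[2], "N1", tri[0], "N7")]
        table = build_table(bonds)
        q = make_query(tree_from_edges([(0, 1), (1, 2)]))
        assert len(match_pattern(table, q)) == 6          # all orientations
        assert match_pattern(table, q, induced=True) == []  # closing edge bans

    def test_exact_count_constraints(self, triple_table):
        path = tree_from_edges([(0, 1), (1, 2)])
        none = make_query(path, ["A", "A", "U"], [1, 1])  # edges carry 2 bonds
        assert match_pattern(triple_table, none) == []
        at_least = make_query(path, ["A", "A", "U"], [">=1", ">=2"])
        assert len(match_pattern(triple_table, at_least)) == 1

    def test_label_tightening_shrinks_hits(self):
        rng = np.random.default_rng(42)
        table = random_bond_table(rng)
        tree = tree_from_edges([(0, 1), (1, 2)])
        wild = {h.base_set for h in
                filter_redundant(match_pattern(table, make_query(tree)))}
        for code in ("A", "C", "G", "U"):
            tight = {h.base_set for h in filter_redundant(
                match_pattern(table, make_query(tree, [code, "*", "*"])))}
            assert tight <= wild

    def test_relaxing_edge_constraint_grows_hits(self):
        rng = np.random.default_rng(43)
        table = random_bond_table(rng)
        tree = tree_from_edges([(0, 1)])
        exact = {h.base_set for h in filter_redundant(
            match_pattern(table, make_query(tree, None, [2])))}
        anyc = {h.base_set for h in filter_redundant(
            match_pattern(table, make_query(tree)))}
        assert exact <= anyc


class TestRedundancyFilter:
    def test_symmetric_path_collapses(self):
        table = path_table(3)
        q = make_query(tree_from_edges([(0, 1), (1, 2)]))
        matches = match_pattern(table, q)
        assert len(matches) == 2  # two traversal orders
        hits = filter_redundant(matches)
        assert len(hits) == 1

    def test_star_automorphisms_collapse(self):
        table = star_table(3)
        star = tree_from_edges([(0, 1), (0, 2), (0, 3)])
        matches = match_pattern(table, make_query(star))
        assert len(matches) == 6  # 3! leaf permutations
        hits = filter_redundant(matches)
        assert len(hits) == 1
        assert hits[0].multiplicity == 6

    def test_unique_matches_pass_through(self, triple_table):
        q = make_query(tree_from_edges([(0, 1), (1, 2)]), ["A", "A", "U"], [2, 2])
        matches = match_pattern(triple_table, q)
        hits = filter_redundant(matches)
        assert len(hits) == len(matches) == 1

    def test_representative_is_lexicographically_smallest(self):
        table = path_table(3)
        q = make_query(tree_from_edges([(0, 1), (1, 2)]))
        hit = filter_redundant(match_pattern(table, q))[0]
        assert hit.representative.sort_key() == \
            min(m.sort_key() for m in match_pattern(table, q))


class TestScan:
    def test_empty_table_all_zero(self):
        result = scan(build_table([]))
        assert result.total() == 0
        assert len(result.hits) == 1 + 1 + 2 + 3 + 6

    def test_octuple_scan_star_quadruples(self, octuple_table):
        result = scan(octuple_table, sizes=(4,))
        star = next(t for t in result.hits if t.degree_sequence == (3, 1, 1, 1))
        hits = result.hits[star]
        assert len(hits) == 2
        assert sorted(h.composition() for h in hits) == ["CCUU", "GGGG"]
        unions = hit_unions(octuple_table, hits)
        assert len(unions) == 1
        assert unions[0]["size"] == 8 and len(unions[0]["hits"]) == 2

    def test_path5_census_matches_brute_force(self):
        table = path_table(5)
        host_edges = [(k, k + 1) for k in range(4)]
        result = scan(table)
        for tree, hits in result.hits.items():
            want = subtree_census(host_edges, 5, list(tree.edges), tree.n)
            assert len(hits) == want, tree.name

    def test_quintuple_path_found_exactly_once(self):
        table = path_table(5)
        path5 = tree_from_edges([(k, k + 1) for k in range(4)])
        hits = filter_redundant(match_pattern(table, make_query(path5)))
        assert len(hits) == 1
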