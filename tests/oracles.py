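"""Independent oracles used by the tests.

Deliberately naive implementations: free-tree enumeration through Prüfer
sequences, subgraph matching through exhaustive injective assignment.
They share no code with the package's enumerator or Ullmann matcher.
"""

from __future__ import annotations

import itertools

from basenet.bases import WILDCARD


def prufer_free_tree_count(n: int) -> int:
    """Count free trees on n nodes by generating every labeled tree from
    its Prüfer sequence and collapsing isomorphs by a canonical form
    (Weisfeiler-Lehman hashing, which is exact on trees)."""
    if n <= 2:
        return 1
    shapes = set()
    for seq in itertools.product(range(n), repeat=n - 2):
        edges = _prufer_to_edges(n, seq)
        shapes.add(_canon(n, edges))
    return len(shapes)


def _prufer_to_edges(n: int, seq) -> list[tuple[int, int]]:
    degree = [1] * n
    for v in seq:
        degree[v] += 1
    edges = []
    seq = list(seq)
    leaves = sorted(v for v in range(n) if degree[v] == 1)
    for v in seq:
        leaf = leaves.pop(0)
        edges.append((leaf, v))
        degree[v] -= 1
        if degree[v] == 1:
            # insert keeping sorted order
            import bisect
            bisect.insort(leaves, v)
    edges.append((leaves[0], leaves[1]))
    return edges


def _canon(n: int, edges) -> str:
    """Canonical form via the 1-WL colour-refinement hash, which decides
    isomorphism exactly on trees."""
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    return nx.weisfeiler_lehman_graph_hash(g, iterations=n)


def exhaustive_matches(table, query, induced=False):
    """All injective query-node -> table-irn assignments, by brute force."""
    irns = table.irns
    n = query.tree.n
    out = []
    for perm in itertools.permutations(irns, n):
        ok = True
        for q in range(n):
            label = query.node_labels[q]
            if label != WILDCARD and table.node(perm[q]).base_code != label:
                ok = False
                break
        if not ok:
            continue
        for (a, b) in query.tree.edges:
            cnt = table.bond_count(perm[a], perm[b])
            if cnt == 0 or not query.constraint((a, b)).satisfied_by(cnt):
                ok = False
                break
        if ok and induced:
            qedges = {frozenset(e) for e in query.tree.edges}
            for a, b in itertools.combinations(range(n), 2):
                if frozenset((a, b)) in qedges:
                    continue
                if table.bond_count(perm[a], perm[b]) > 0:
                    ok = False
                    break
        if ok:
            out.append(tuple(perm))
    return sorted(out)


def subtree_census(adj_edges: list[tuple[int, int]], n_nodes: int,
                   tree_edges: list[tuple[int, int]], k: int) -> int:
    """Number of distinct k-node subsets of a host graph that contain the
    query tree as a (monomorphic) sub-tree; brute force."""
    host = {frozenset(e) for e in adj_edges}
    count = 0
    for subset in itertools.combinations(range(n_nodes), k):
        found = False
        for perm in itertools.permutations(subset):
            if all(frozenset((perm[a], perm[b])) in host for a, b in tree_edges):
                found = True
                break
        if found:
            count += 1
    return count
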