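"""Subgraph matching of query patterns against connection tables.

The matcher is an Ullmann-style backtracking search: a boolean
compatibility matrix over (query node, table node) pairs is first pruned
to a fixpoint -- a pair survives only if every query neighbour of the
query node can still be mapped to some table neighbour of the table node
through an edge whose bond count satisfies the query constraint -- and a
depth-first assignment then extends partial injective mappings in
ascending-IRN order, which makes the output order deterministic.

Semantics are subgraph *monomorphism*: every query edge must map onto a
satisfying table edge, but extra table edges among the matched bases are
allowed.  This is what lets two interconnected quadruples each be found
inside the larger octuple they form.  An induced mode (extra edges
forbidden) is available behind a flag.

Raw matches of a symmetric query are permutations of one another; the
redundancy filter keeps one hit per distinct base set, mirroring the
sequence-order-independent filtering of the search output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .bases import WILDCARD
from .hbond import HydrogenBond
from .patterns import QueryPattern, TreePattern, enumerate_trees, make_query
from .structure_io import BaseNode
from .table import ConnectionTable


@dataclass(frozen=True)
class Match:
    """One injective assignment of query nodes to table bases."""

    query: QueryPattern
    assignment: tuple[int, ...]  # query node index -> table irn
    table: ConnectionTable

    def base(self, qnode: int) -> BaseNode:
        return self.table.node(self.assignment[qnode])

    @property
    def bases(self) -> tuple[BaseNode, ...]:
        return tuple(self.table.node(irn) for irn in self.assignment)

    @property
    def base_set(self) -> frozenset:
        return frozenset(b.resid for b in self.bases)

    def edge_bonds(self) -> dict[tuple[int, int], list[HydrogenBond]]:
        """Realizing table bonds per query edge."""
        out = {}
        for (a, b) in self.query.tree.edges:
            out[(a, b)] = self.table.edge_bonds(
                self.assignment[a], self.assignment[b])
        return out

    def sort_key(self):
        return tuple(self.table.node(irn).resid for irn in self.assignment)


@dataclass(frozen=True)
class Hit:
    """A deduplicated match: one per distinct base set."""

    query: QueryPattern
    base_set: frozenset
    representative: Match
    multiplicity: int  # raw matches collapsed into this hit

    @property
    def bases(self) -> tuple[BaseNode, ...]:
        return self.representative.bases

    def bonds(self) -> list[HydrogenBond]:
        seen = set()
        out = []
        for blist in self.representative.edge_bonds().values():
            for b in blist:
                if b.key not in seen:
                    seen.add(b.key)
                    out.append(b)
        out.sort(key=lambda b: b.key)
        return out

    def composition(self) -> str:
        """Base composition string, e.g. ``GGGG`` or ``CCUU`` (sorted)."""
        return "".join(sorted(b.base_code for b in self.bases))


def _label_ok(label: str, base_code: str) -> bool:
    return label == WILDCARD or label == base_code


def _initial_matrix(table: ConnectionTable, query: QueryPattern):
    tree = query.tree
    irns = table.irns
    qdeg = [len(a) for a in tree.adjacency()]
    m = {}
    for q in range(tree.n):
        allowed = set()
        for irn in irns:
            node = table.node(irn)
            if not _label_ok(query.node_labels[q], node.base_code):
                continue
            if table.degree(irn) < qdeg[q]:
                continue
            allowed.add(irn)
        m[q] = allowed
    return m


def _refine(table: ConnectionTable, query: QueryPattern, m) -> bool:
    """Prune to fixpoint; False when some query node has no candidates."""
    adj = query.tree.adjacency()
    changed = True
    while changed:
        changed = False
        for q in range(query.tree.n):
            drop = []
            for irn in m[q]:
                for u in adj[q]:
                    cons = query.constraint((q, u))
                    ok = any(
                        v in m[u] and cons.satisfied_by(table.bond_count(irn, v))
                        for v in table.partners(irn)
                    )
                    if not ok:
                        drop.append(irn)
                        break
            if drop:
                changed = True
                m[q] -= set(drop)
                if not m[q]:
                    return False
    return True


def match_pattern(table: ConnectionTable, query: QueryPattern,
                  induced: bool = False) -> list[Match]:
    """All injective assignments of the query into the table.

    Monomorphism semantics by default; ``induced=True`` additionally
    rejects assignments in which two unconnected query nodes land on
    bonded table bases.
    """
    tree = query.tree
    if not table.nodes:
        return []
    m = _initial_matrix(table, query)
    if not all(m.values()) or not _refine(table, query, m):
        return []

    adj = tree.adjacency()
    # Assignment order: most-constrained node first, then BFS so every
    # subsequent node has an already-assigned neighbour to check against.
    start = min(range(tree.n), key=lambda q: (len(m[q]), -len(adj[q]), q))
    order = [start]
    while len(order) < tree.n:
        frontier = [q for q in range(tree.n) if q not in order
                    and any(u in order for u in adj[q])]
        nxt = min(frontier, key=lambda q: (len(m[q]), q))
        order.append(nxt)

    matches: list[Match] = []
    assign: dict[int, int] = {}
    used: set[int] = set()

    def extend(depth: int):
        if depth == tree.n:
            matches.append(Match(
                query=query,
                assignment=tuple(assign[q] for q in range(tree.n)),
                table=table,
            ))
            return
        q = order[depth]
        for irn in sorted(m[q]):
            if irn in used:
                continue
            ok = True
            for u in adj[q]:
                if u in assign:
                    cnt = table.bond_count(irn, assign[u])
                    if cnt == 0 or not query.constraint((q, u)).satisfied_by(cnt):
                        ok = False
                        break
            if ok and induced:
                for u, v in assign.items():
                    if u not in adj[q] and table.bond_count(irn, v) > 0:
                        ok = False
                        break
            if not ok:
                continue
            assign[q] = irn
            used.add(irn)
            extend(depth + 1)
            del assign[q]
            used.discard(irn)

    extend(0)
    matches.sort(key=Match.sort_key)
    return matches


def filter_redundant(matches: list[Match]) -> list[Hit]:
    """One hit per distinct base set (sequence-order independent).

    The representative is the lexicographically smallest assignment by
    residue id.  Input matches must come from one query.
    """
    groups: dict[frozenset, list[Match]] = {}
    for match in matches:
        groups.setdefault(match.base_set, []).append(match)
    hits = []
    for base_set, group in groups.items():
        rep = min(group, key=Match.sort_key)
        hits.append(Hit(query=rep.query, base_set=base_set,
                        representative=rep, multiplicity=len(group)))
    hits.sort(key=lambda h: h.representative.sort_key())
    return hits


@dataclass
class ScanResult:
    """Post-filter hits for every tree shape of the requested sizes."""

    hits: dict[TreePattern, list[Hit]] = field(default_factory=dict)

    def counts(self) -> dict[TreePattern, int]:
        return {t: len(h) for t, h in self.hits.items()}

    def total(self) -> int:
        return sum(len(h) for h in self.hits.values())


def scan(table: ConnectionTable, sizes=(2, 3, 4, 5, 6)) -> ScanResult:
    """Run every enumerated tree, all-wildcard, any-count, over the table."""
    result = ScanResult()
    for n in sorted(set(sizes)):
        for tree in enumerate_trees(n):
            query = make_query(tree)
            result.hits[tree] = filter_redundant(match_pattern(table, query))
    return result


def hit_unions(table: ConnectionTable, hits: list[Hit]) -> list[dict]:
    """Connected unions of overlapping/interconnected hits.

    Builds the subgraph induced by the union of all hit base sets and
    reports each connected component that spans more than one hit --
    e.g. two interconnected quadruples surfacing as one octuple.
    """
    irn_of = {n.resid: n.irn for n in table.nodes}
    member_irns = set()
    for h in hits:
        member_irns |= {irn_of[r] for r in h.base_set}
    # union-find over the induced subgraph
    parent = {i: i for i in member_irns}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (i, j) in table.edges:
        if i in member_irns and j in member_irns:
            parent[find(i)] = find(j)

    comps: dict[int, set[int]] = {}
    for i in member_irns:
        comps.setdefault(find(i), set()).add(i)
    out = []
    for comp in comps.values():
        resids = {table.node(i).resid for i in comp}
        members = [h for h in hits if h.base_set <= resids]
        if len(members) > 1:
            out.append({
                "bases": sorted(resids),
                "size": len(resids),
                "hits": members,
            })
    out.sort(key=lambda d: d["bases"])
    return out
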