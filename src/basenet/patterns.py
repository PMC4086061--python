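"""Query patterns: free trees with base labels and bond-count constraints.

Base interaction clusters are searched as tree graphs.  The free
(unlabeled, unrooted) trees on n nodes number 1, 1, 2, 3, 6 for
n = 2..6 -- one shape for pairs and triples up to six distinct
arrangements for sextuples.  Each tree node carries a base label (a
library base code or the wildcard), and each edge a hydrogen-bond count
constraint: "any" (at least one bond), an exact count, or an at-least
count.

Trees are enumerated up to isomorphism by growing every (n-1)-node tree
by one leaf and deduplicating with an AHU canonical form rooted at the
tree centroid; the ordering of the resulting type ordinals is the
lexicographic order of the canonical codes (the shape's degree sequence
is always reported alongside, since ordinal numbering conventions vary).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache

from .bases import WILDCARD, BaseLibrary

Edge = tuple[int, int]


class NotATreeError(ValueError):
    """The edge list is not a connected acyclic graph."""


def _adjacency(n: int, edges: tuple[Edge, ...]) -> list[list[int]]:
    adj: list[list[int]] = [[] for _ in range(n)]
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    return adj


def _check_tree(n: int, edges: tuple[Edge, ...]) -> list[list[int]]:
    if len(edges) != n - 1:
        raise NotATreeError(f"{len(edges)} edges on {n} nodes is not a tree")
    for a, b in edges:
        if not (0 <= a < n and 0 <= b < n) or a == b:
            raise NotATreeError(f"bad edge ({a}, {b})")
    adj = _adjacency(n, edges)
    seen = {0}
    stack = [0]
    while stack:
        for w in adj[stack.pop()]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    if len(seen) != n:
        raise NotATreeError("graph is disconnected")
    return adj


def _centroids(n: int, adj: list[list[int]]) -> list[int]:
    """The 1 or 2 nodes minimizing the largest subtree they cut off."""
    if n == 1:
        return [0]
    out: list[int] = []
    best = None
    for v in range(n):
        heaviest = _heaviest_branch(v, n, adj)
        if best is None or heaviest < best:
            best, out = heaviest, [v]
        elif heaviest == best:
            out.append(v)
    return out


def _heaviest_branch(root: int, n: int, adj: list[list[int]]) -> int:
    heaviest = 0
    for child in adj[root]:
        count = 0
        stack = [(child, root)]
        while stack:
            v, parent = stack.pop()
            count += 1
            for w in adj[v]:
                if w != parent:
                    stack.append((w, v))
        heaviest = max(heaviest, count)
    return heaviest


def _rooted_code(root: int, parent: int, adj: list[list[int]]) -> str:
    children = sorted(
        _rooted_code(w, root, adj) for w in adj[root] if w != parent
    )
    return "(" + "".join(children) + ")"


def canonical_code(edges, n: int | None = None) -> str:
    """AHU canonical string of a free tree: equal iff isomorphic.

    ``edges`` is any iterable of node-index pairs; nodes are the integers
    they mention (or 0..n-1 when ``n`` is given).
    """
    edges = tuple((min(a, b), max(a, b)) for a, b in edges)
    if n is None:
        n = max((max(e) for e in edges), default=0) + 1
    adj = _check_tree(n, edges)
    return min(_rooted_code(c, -1, adj) for c in _centroids(n, adj))


@dataclass(frozen=True)
class TreePattern:
    """One free-tree shape, with a stable ordinal within its size class."""

    n: int
    edges: tuple[Edge, ...]
    canonical_code: str
    type_index: int  # 1-based rank in canonical-code order

    @property
    def degree_sequence(self) -> tuple[int, ...]:
        adj = _adjacency(self.n, self.edges)
        return tuple(sorted((len(a) for a in adj), reverse=True))

    @property
    def name(self) -> str:
        size = {2: "pair", 3: "triple", 4: "quadruple", 5: "quintuple",
                6: "sextuple", 7: "septuple"}.get(self.n, f"{self.n}-tuple")
        return f"{size} type {_roman(self.type_index)}"

    def adjacency(self) -> list[list[int]]:
        return _adjacency(self.n, self.edges)

    def ascii_sketch(self) -> str:
        adj = self.adjacency()
        lines = []
        for v in range(self.n):
            lines.append(f"{v}: " + " ".join(str(w) for w in sorted(adj[v])))
        return "\n".join(lines)


def _roman(k: int) -> str:
    numerals = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI"]
    return numerals[k - 1] if 1 <= k <= len(numerals) else str(k)


def _relabel_canonical(n: int, edges: frozenset[Edge]) -> tuple[Edge, ...]:
    """Deterministic node labelling: BFS order from a canonical centroid."""
    adj = _adjacency(n, tuple(edges))
    codes = {c: _rooted_code(c, -1, adj) for c in _centroids(n, adj)}
    root = min(codes, key=lambda c: (codes[c], c))
    label = {root: 0}
    queue = [root]
    while queue:
        v = queue.pop(0)
        # order children by their rooted code for stability
        kids = sorted(
            (w for w in adj[v] if w not in label),
            key=lambda w: (_rooted_code(w, v, adj), w),
        )
        for w in kids:
            label[w] = len(label)
            queue.append(w)
    out = sorted(
        (min(label[a], label[b]), max(label[a], label[b])) for a, b in edges
    )
    return tuple(out)


@lru_cache(maxsize=None)
def enumerate_trees(n: int) -> tuple[TreePattern, ...]:
    """All free trees on n nodes, one per isomorphism class.

    Deterministically ordered by canonical code; ``type_index`` follows
    that order.  Grown by leaf extension from the (n-1)-node trees.
    """
    if n < 2:
        raise ValueError("tree enumeration needs n >= 2")
    if n == 2:
        shapes = {canonical_code([(0, 1)]): ((0, 1),)}
    else:
        shapes = {}
        for smaller in enumerate_trees(n - 1):
            for attach in range(n - 1):
                edges = smaller.edges + ((attach, n - 1),)
                code = canonical_code(edges, n)
                if code not in shapes:
                    shapes[code] = _relabel_canonical(n, frozenset(edges))
    out = []
    for idx, code in enumerate(sorted(shapes), start=1):
        out.append(TreePattern(n=n, edges=shapes[code],
                               canonical_code=code, type_index=idx))
    return tuple(out)


# ---------------------------------------------------------------------------
# Labeled queries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EdgeConstraint:
    """Bond-count requirement on one query edge.

    mode "any": one bond or more (the default when left unspecified);
    mode "exact": exactly ``count`` bonds; mode "at_least": >= ``count``.
    """

    mode: str = "any"
    count: int = 1

    def __post_init__(self):
        if self.mode not in ("any", "exact", "at_least"):
            raise ValueError(f"unknown edge-constraint mode {self.mode!r}")
        if self.count < 1:
            raise ValueError("bond-count constraints must be positive")

    def satisfied_by(self, bond_count: int) -> bool:
        if self.mode == "exact":
            return bond_count == self.count
        if self.mode == "at_least":
            return bond_count >= self.count
        return bond_count >= 1

    @classmethod
    def parse(cls, token) -> "EdgeConstraint":
        """Accepts "any"/"*", "3" (exact), or ">=2"."""
        if isinstance(token, EdgeConstraint):
            return token
        if isinstance(token, int):
            return cls("exact", token)
        s = str(token).strip().lower()
        if s in ("any", "*", ""):
            return cls("any")
        m = re.fullmatch(r">=\s*(\d+)", s)
        if m:
            return cls("at_least", int(m.group(1)))
        if s.isdigit():
            return cls("exact", int(s))
        raise ValueError(f"cannot parse edge constraint {token!r}")

    def __str__(self) -> str:
        if self.mode == "any":
            return "any"
        return str(self.count) if self.mode == "exact" else f">={self.count}"

ANY = EdgeConstraint("any")


@dataclass(frozen=True)
class QueryPattern:
    """A tree shape plus per-node base labels and per-edge constraints."""

    tree: TreePattern
    node_labels: tuple[str, ...]
    edge_constraints: tuple[EdgeConstraint, ...]  # parallel to tree.edges

    def constraint(self, edge: Edge) -> EdgeConstraint:
        key = (min(edge), max(edge))
        for e, c in zip(self.tree.edges, self.edge_constraints):
            if e == key:
                return c
        raise KeyError(f"{edge} is not a query edge")

    def describe(self) -> str:
        labels = ",".join(self.node_labels)
        cons = ",".join(str(c) for c in self.edge_constraints)
        return f"{self.tree.name} [{labels}] edges [{cons}]"


def make_query(tree: TreePattern, labels=None, constraints=None,
               library: BaseLibrary | None = None) -> QueryPattern:
    """Validate labels/constraints against a tree and build the query.

    ``labels`` defaults to all-wildcard; ``constraints`` to all-"any".
    Labels must be library base codes or the wildcard "*"; constraint
    tokens are parsed by :meth:`EdgeConstraint.parse`.
    """
    lib = library or BaseLibrary()
    if labels is None:
        labels = (WILDCARD,) * tree.n
    labels = tuple(str(l).strip().upper() if str(l).strip() != WILDCARD else WILDCARD
                   for l in labels)
    if len(labels) != tree.n:
        raise ValueError(f"{len(labels)} labels for a {tree.n}-node tree")
    for l in labels:
        if l != WILDCARD and l not in lib:
            raise KeyError(f"label {l!r} is not in the base library")
    if constraints is None:
        constraints = (ANY,) * len(tree.edges)
    parsed = tuple(EdgeConstraint.parse(c) for c in constraints)
    if len(parsed) != len(tree.edges):
        raise ValueError(
            f"{len(parsed)} edge constraints for {len(tree.edges)} edges")
    return QueryPattern(tree=tree, node_labels=labels, edge_constraints=parsed)


def tree_from_edges(edges) -> TreePattern:
    """Wrap an explicit edge list as a TreePattern (validated, canonical
    ordinal looked up from the enumeration of its size class)."""
    edges = tuple((min(a, b), max(a, b)) for a, b in edges)
    n = max(max(e) for e in edges) + 1
    code = canonical_code(edges, n)
    for t in enumerate_trees(n):
        if t.canonical_code == code:
            return TreePattern(n=n, edges=edges, canonical_code=code,
                               type_index=t.type_index)
    raise NotATreeError("edge list does not form a known tree shape")
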