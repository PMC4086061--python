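"""Connection tables: the per-structure graph of hydrogen-bonded bases.

Nodes are bases that participate in at least one base-base hydrogen
bond, identified by an internal residue number (IRN, 1-based rank in
structure order among participating bases, with the author residue id
carried alongside).  Edges carry the bond multiplicity and, from each
endpoint's perspective, a signed atom-pair code:

    [donor element digit][donor position][acceptor element digit][acceptor position]

with 1 = nitrogen, 0 = oxygen, and a negative sign when the *partner*
base (not the listing base) is the donor.  For example, from U12's
perspective "-1604 1311" reads as: A23 N6 (nitrogen) donates to U12 O4
(oxygen), and U12 N3 donates to A23 N1.  Atoms whose position needs two
digits, or whose element is outside {N, O}, fall back to an explicit
``N6>O10``-style token.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field

from .hbond import HydrogenBond
from .structure_io import BaseNode

log = logging.getLogger(__name__)

_ELEMENT_DIGIT = {"N": "1", "O": "0"}
_DIGIT_ELEMENT = {v: k for k, v in _ELEMENT_DIGIT.items()}


class TableFormatError(ValueError):
    """Malformed connection-table text."""


@dataclass(frozen=True)
class BondCode:
    """One hydrogen bond of an edge, encoded from one endpoint's view."""

    donor_is_partner: bool
    donor_atom: str
    acceptor_atom: str

    @property
    def text(self) -> str:
        body = _encode_atom_pair(self.donor_atom, self.acceptor_atom)
        return ("-" + body) if self.donor_is_partner else body

    def __str__(self) -> str:
        return self.text


def _atom_digits(atom: str) -> str | None:
    m = re.fullmatch(r"([A-Z])(\d)", atom)
    if m is None:
        return None
    digit = _ELEMENT_DIGIT.get(m.group(1))
    if digit is None:
        return None
    return digit + m.group(2)


def _encode_atom_pair(donor_atom: str, acceptor_atom: str) -> str:
    d, a = _atom_digits(donor_atom), _atom_digits(acceptor_atom)
    if d is not None and a is not None:
        return d + a
    # Extended form for two-digit positions or exotic elements.
    log.debug("bond code fallback for %s>%s", donor_atom, acceptor_atom)
    return f"{donor_atom}>{acceptor_atom}"


def parse_bond_code(text: str) -> BondCode:
    """Inverse of :attr:`BondCode.text`."""
    text = text.strip()
    if not text:
        raise TableFormatError("empty bond code")
    negative = text.startswith("-")
    body = text[1:] if negative else text
    if ">" in body:
        donor_atom, acceptor_atom = body.split(">", 1)
        if not donor_atom or not acceptor_atom:
            raise TableFormatError(f"malformed bond code {text!r}")
        return BondCode(negative, donor_atom, acceptor_atom)
    if not re.fullmatch(r"\d{4}", body):
        raise TableFormatError(f"malformed bond code {text!r}")
    try:
        donor = _DIGIT_ELEMENT[body[0]] + body[1]
        acceptor = _DIGIT_ELEMENT[body[2]] + body[3]
    except KeyError:
        raise TableFormatError(f"unknown element digit in bond code {text!r}") from None
    return BondCode(negative, donor, acceptor)


def encode_bond(bond: HydrogenBond, perspective_base: BaseNode) -> BondCode:
    """Encode a bond as seen from one of its two endpoint bases."""
    if perspective_base.resid == bond.donor_base.resid:
        return BondCode(False, bond.donor_atom, bond.acceptor_atom)
    if perspective_base.resid == bond.acceptor_base.resid:
        return BondCode(True, bond.donor_atom, bond.acceptor_atom)
    raise ValueError(f"{perspective_base.label} is not an endpoint of {bond!r}")


def decode_bond(code: BondCode, perspective_base: BaseNode,
                partner_base: BaseNode) -> HydrogenBond:
    """Rebuild the (geometry-free) bond a code stands for."""
    donor, acceptor = ((partner_base, perspective_base) if code.donor_is_partner
                       else (perspective_base, partner_base))
    return HydrogenBond(donor, code.donor_atom, acceptor, code.acceptor_atom,
                        math.nan, math.nan, math.nan)


@dataclass
class ConnectionTable:
    """Graph of bond-participating bases.

    ``edges`` maps ordered irn pairs (i < j) to the list of hydrogen
    bonds between those two bases.
    """

    nodes: list[BaseNode] = field(default_factory=list)
    edges: dict[tuple[int, int], list[HydrogenBond]] = field(default_factory=dict)

    def __post_init__(self):
        self._by_irn = {n.irn: n for n in self.nodes}

    def node(self, irn: int) -> BaseNode:
        return self._by_irn[irn]

    @property
    def irns(self) -> list[int]:
        return [n.irn for n in self.nodes]

    def partners(self, irn: int) -> list[int]:
        out = []
        for (i, j) in self.edges:
            if i == irn:
                out.append(j)
            elif j == irn:
                out.append(i)
        return sorted(out)

    def edge_bonds(self, i: int, j: int) -> list[HydrogenBond]:
        return self.edges.get((min(i, j), max(i, j)), [])

    def bond_count(self, i: int, j: int) -> int:
        return len(self.edge_bonds(i, j))

    def degree(self, irn: int) -> int:
        return len(self.partners(irn))

    def codes(self, irn: int, partner: int) -> list[BondCode]:
        """Bond codes of edge (irn, partner) from irn's perspective."""
        node = self.node(irn)
        return [encode_bond(b, node) for b in self.edge_bonds(irn, partner)]

    @property
    def total_bonds(self) -> int:
        return sum(len(v) for v in self.edges.values())

    def all_bonds(self) -> list[HydrogenBond]:
        out = []
        for key in sorted(self.edges):
            out.extend(self.edges[key])
        return out

    def signature(self):
        """Hashable graph identity: nodes, edge multiplicities, codes."""
        nodes = tuple((n.irn, n.base_code, n.resid) for n in self.nodes)
        edges = tuple(
            (i, j, tuple(sorted(c.text for c in self.codes(i, j))))
            for (i, j) in sorted(self.edges)
        )
        return (nodes, edges)


def build_table(bonds: list[HydrogenBond]) -> ConnectionTable:
    """Assemble the connection table of a bond list.

    IRNs are assigned 1-based in structure order (the ``order_index``
    recorded on each base, ties broken by residue id), over the bases
    that participate in at least one bond.  Duplicate bond records
    (identical donor/acceptor residues and atoms) are dropped with a
    warning.
    """
    seen = set()
    unique: list[HydrogenBond] = []
    for b in bonds:
        if b.key in seen:
            log.warning("duplicate bond record dropped: %r", b)
            continue
        seen.add(b.key)
        unique.append(b)

    by_resid: dict[tuple, BaseNode] = {}
    for b in unique:
        for base in (b.donor_base, b.acceptor_base):
            by_resid.setdefault(base.resid, base)
    ordered = sorted(by_resid.values(), key=lambda n: (n.order_index, n.resid))
    irn_of: dict[tuple, int] = {}
    nodes = []
    for rank, base in enumerate(ordered, start=1):
        base.irn = rank
        irn_of[base.resid] = rank
        nodes.append(base)

    edges: dict[tuple[int, int], list[HydrogenBond]] = {}
    for b in unique:
        i = irn_of[b.donor_base.resid]
        j = irn_of[b.acceptor_base.resid]
        key = (min(i, j), max(i, j))
        edges.setdefault(key, []).append(b)
    for key in edges:
        edges[key].sort(key=lambda b: b.key)
    return ConnectionTable(nodes=nodes, edges=edges)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_HEADER = "# basenet connection table v1"


def write_table(table: ConnectionTable) -> str:
    """Plain-text rendering: one node line, then one line per partner.

    Node line:    ``irn base chain.resseq[icode] n_partners``
    Partner line: ``> partner_irn bond_count code [code ...]``
    """
    lines = [_HEADER]
    for node in table.nodes:
        partners = table.partners(node.irn)
        resid = f"{node.chain_id}.{node.res_seq}{node.icode}"
        lines.append(f"{node.irn} {node.base_code} {resid} {len(partners)}")
        for p in partners:
            codes = " ".join(c.text for c in table.codes(node.irn, p))
            lines.append(f"> {p} {table.bond_count(node.irn, p)} {codes}")
    return "\n".join(lines) + "\n"


def read_table(text: str) -> ConnectionTable:
    """Parse the text format back into a (geometry-free) table.

    Round-trips the graph exactly: node identities, edge multiplicities
    and bond codes.  Atom coordinates and distances are not stored in the
    text format and come back empty/NaN.
    """
    nodes: list[BaseNode] = []
    pending: dict[int, list[tuple[int, int, list[BondCode]]]] = {}
    current: BaseNode | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            if line.startswith(">"):
                if current is None:
                    raise TableFormatError("partner line before any node line")
                parts = line[1:].split()
                partner_irn, count = int(parts[0]), int(parts[1])
                codes = [parse_bond_code(tok) for tok in parts[2:]]
                if len(codes) != count:
                    raise TableFormatError(
                        f"bond count {count} != {len(codes)} codes listed")
                pending.setdefault(current.irn, []).append(
                    (partner_irn, count, codes))
            else:
                irn_s, base_code, resid_s, _npart = line.split()
                m = re.fullmatch(r"([^.]+)\.(-?\d+)(\D?)", resid_s)
                if m is None:
                    raise TableFormatError(f"bad residue id {resid_s!r}")
                current = BaseNode(
                    chain_id=m.group(1), res_seq=int(m.group(2)),
                    icode=m.group(3), res_name=base_code, base_code=base_code,
                    irn=int(irn_s), order_index=int(irn_s) - 1,
                )
                nodes.append(current)
        except (ValueError, IndexError, TableFormatError) as exc:
            raise TableFormatError(f"line {lineno}: {exc}") from exc

    by_irn = {n.irn: n for n in nodes}
    edges: dict[tuple[int, int], list[HydrogenBond]] = {}
    for irn, plist in pending.items():
        for partner_irn, _count, codes in plist:
            if partner_irn not in by_irn:
                raise TableFormatError(
                    f"node {irn} references unknown partner irn {partner_irn}")
            if irn < partner_irn:  # each edge materialized once
                bonds = [decode_bond(c, by_irn[irn], by_irn[partner_irn])
                         for c in codes]
                bonds.sort(key=lambda b: b.key)
                edges[(irn, partner_irn)] = bonds
    return ConnectionTable(nodes=nodes, edges=edges)


def table_to_json(table: ConnectionTable) -> str:
    """JSON twin of the text format, with atom detail and distances."""
    doc = {
        "nodes": [
            {
                "irn": n.irn,
                "base": n.base_code,
                "chain": n.chain_id,
                "res_seq": n.res_seq,
                "icode": n.icode,
                "res_name": n.res_name,
            }
            for n in table.nodes
        ],
        "edges": [
            {
                "irn_pair": [i, j],
                "bonds": [
                    {
                        "donor": {"irn": table.node(i).irn if b.donor_base.resid == table.node(i).resid else j,
                                  "atom": b.donor_atom},
                        "acceptor": {"atom": b.acceptor_atom},
                        "distance": None if math.isnan(b.da_distance) else round(b.da_distance, 3),
                        "code_from_lower_irn": encode_bond(b, table.node(i)).text,
                    }
                    for b in table.edges[(i, j)]
                ],
            }
            for (i, j) in sorted(table.edges)
        ],
    }
    return json.dumps(doc, indent=2)
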