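"""Comparing the hydrogen-bond networks of two structures.

Intended for pairs of closely related structures (mutant vs wild-type,
ligand-bound vs free): residues are matched by identical author id
(chain, residue number, insertion code) by default, or through an
explicit residue map for renumbered pairs, and bonds are then classified
as present only in A, only in B, or shared, at donor-atom/acceptor-atom
resolution.  Both networks should be computed with the same geometric
thresholds for the comparison to be meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .hbond import HydrogenBond
from .table import ConnectionTable

log = logging.getLogger(__name__)

Resid = tuple[str, int, str]
BondKey = tuple[Resid, str, Resid, str]


@dataclass
class NetworkDiff:
    """Atomic-level difference between two bond networks.

    ``only_a``/``only_b`` include bonds that touch residues absent from
    the other structure; those residues are listed in
    ``unmatched_residues_a``/``_b``.  ``shared`` pairs each bond of A
    with its counterpart in B (under the residue mapping).
    """

    only_a: list[HydrogenBond] = field(default_factory=list)
    only_b: list[HydrogenBond] = field(default_factory=list)
    shared: list[tuple[HydrogenBond, HydrogenBond]] = field(default_factory=list)
    unmatched_residues_a: list[Resid] = field(default_factory=list)
    unmatched_residues_b: list[Resid] = field(default_factory=list)

    @property
    def unmatched_residues(self) -> list[Resid]:
        """Residues present in exactly one structure (either side)."""
        return sorted(set(self.unmatched_residues_a) | set(self.unmatched_residues_b))

    def is_identical(self) -> bool:
        return not self.only_a and not self.only_b


def _bond_key(b: HydrogenBond, mapping=None) -> BondKey:
    d = b.donor_base.resid
    a = b.acceptor_base.resid
    if mapping is not None:
        d = mapping.get(d, d)
        a = mapping.get(a, a)
    return (d, b.donor_atom, a, b.acceptor_atom)


def compare_structures(table_a: ConnectionTable, table_b: ConnectionTable,
                       mapping: dict[Resid, Resid] | None = None) -> NetworkDiff:
    """Diff two connection tables built with the same bond thresholds.

    Parameters
    ----------
    mapping
        Optional residue map from A's author ids to B's, for renumbered
        pairs.  The default (None) is the identity mapping: residues
        correspond iff their (chain, res_seq, icode) match exactly.
    """
    residues_a = {n.resid for n in table_a.nodes}
    residues_b = {n.resid for n in table_b.nodes}
    map_ab = mapping or {}
    mapped_a = {map_ab.get(r, r) for r in residues_a}
    unmatched_a = sorted(r for r in residues_a if map_ab.get(r, r) not in residues_b)
    unmatched_b = sorted(r for r in residues_b if r not in mapped_a)
    if residues_a and residues_b and len(unmatched_a) == len(residues_a):
        log.warning("no residues in common between the two structures; "
                    "every bond is reported as unique to its side")

    bonds_a = table_a.all_bonds()
    bonds_b = table_b.all_bonds()
    by_key_b = {_bond_key(b): b for b in bonds_b}

    diff = NetworkDiff(unmatched_residues_a=unmatched_a,
                       unmatched_residues_b=unmatched_b)
    matched_b_keys = set()
    for b in bonds_a:
        key = _bond_key(b, map_ab)
        partner = by_key_b.get(key)
        if partner is None:
            diff.only_a.append(b)
        else:
            diff.shared.append((b, partner))
            matched_b_keys.add(key)
    for b in bonds_b:
        if _bond_key(b) not in matched_b_keys:
            diff.only_b.append(b)
    diff.only_a.sort(key=lambda b: b.key)
    diff.only_b.sort(key=lambda b: b.key)
    diff.shared.sort(key=lambda p: p[0].key)
    return diff
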