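"""Geometric detection of base-base hydrogen bonds.

A donor atom D on one base and an acceptor atom A on another base form a
hydrogen bond when

* the D-A distance is at most ``max_da_distance`` (default 3.9 A),
* the angle DD-D-A is at least ``min_ada_angle`` (DD = donor antecedent,
  the ring atom covalently bonded to D), and
* the angle D-A-AA is at least ``min_daa_angle`` (AA = acceptor
  antecedent).

The criteria act on heavy atoms only: hydrogens are stripped from every
input, so the explicit D-H...A test of hydrogen-placement methods is
replaced by the antecedent-angle proxy above.  All thresholds are
configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import yaml

from .bases import BaseLibrary
from .structure_io import BaseNode, Structure

log = logging.getLogger(__name__)

#: Cheap pair prefilter: bases whose moiety centroids are farther apart
#: than this cannot hold a <= ~4 A atom contact (base radius < 4.5 A).
_CENTROID_CUTOFF_PAD = 9.0


class LibraryError(KeyError):
    """A residue's base code has no entry in the donor/acceptor library."""


@dataclass
class HBondParams:
    """Geometric acceptance thresholds.

    Attributes
    ----------
    max_da_distance : float
        Maximum donor-acceptor distance in Angstrom.
    min_ada_angle : float
        Minimum donor-antecedent - donor - acceptor angle, degrees.
    min_daa_angle : float
        Minimum donor - acceptor - acceptor-antecedent angle, degrees.
    """

    max_da_distance: float = 3.9
    min_ada_angle: float = 90.0
    min_daa_angle: float = 90.0

    def __post_init__(self):
        if self.max_da_distance <= 0:
            raise ValueError("max_da_distance must be positive")
        for a in (self.min_ada_angle, self.min_daa_angle):
            if not 0.0 <= a <= 180.0:
                raise ValueError("angle thresholds must lie in [0, 180]")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "HBondParams":
        doc = yaml.safe_load(text) or {}
        return cls(**doc)


def default_params() -> HBondParams:
    """Default thresholds: 3.9 A distance cutoff, 90 deg angle minima."""
    return HBondParams()


@dataclass(frozen=True)
class HydrogenBond:
    """One detected donor-atom to acceptor-atom interaction."""

    donor_base: BaseNode
    donor_atom: str
    acceptor_base: BaseNode
    acceptor_atom: str
    da_distance: float
    ada_angle: float  # donor-antecedent - donor - acceptor
    daa_angle: float  # donor - acceptor - acceptor-antecedent

    @property
    def key(self):
        """Structure-independent identity of the bond (residue ids + atoms)."""
        return (self.donor_base.resid, self.donor_atom,
                self.acceptor_base.resid, self.acceptor_atom)

    def __repr__(self):
        return (f"HydrogenBond({self.donor_base.label} {self.donor_atom} -> "
                f"{self.acceptor_base.label} {self.acceptor_atom}, "
                f"{self.da_distance:.2f} A)")


def angle_deg(p1: np.ndarray, vertex: np.ndarray, p2: np.ndarray) -> float:
    """Angle p1-vertex-p2 in degrees."""
    v1 = p1 - vertex
    v2 = p2 - vertex
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _directional_bonds(donor: BaseNode, acceptor: BaseNode,
                       library: BaseLibrary, params: HBondParams):
    chem_d = library.chemistry(donor.base_code)
    chem_a = library.chemistry(acceptor.base_code)
    for d_name in chem_d.donors:
        if not donor.has_atom(d_name):
            continue
        d_ante_name = chem_d.antecedent.get(d_name)
        if d_ante_name is None or not donor.has_atom(d_ante_name):
            log.warning("%s: donor %s has no antecedent atom; skipped",
                        donor.label, d_name)
            continue
        d_pos = donor.atom(d_name).position
        d_ante = donor.atom(d_ante_name).position
        for a_name in chem_a.acceptors:
            if not acceptor.has_atom(a_name):
                continue
            a_ante_name = chem_a.antecedent.get(a_name)
            if a_ante_name is None or not acceptor.has_atom(a_ante_name):
                log.warning("%s: acceptor %s has no antecedent atom; skipped",
                            acceptor.label, a_name)
                continue
            a_pos = acceptor.atom(a_name).position
            dist = float(np.linalg.norm(d_pos - a_pos))
            if dist > params.max_da_distance:
                continue
            ada = angle_deg(d_ante, d_pos, a_pos)
            if ada < params.min_ada_angle:
                continue
            daa = angle_deg(d_pos, a_pos, acceptor.atom(a_ante_name).position)
            if daa < params.min_daa_angle:
                continue
            yield HydrogenBond(donor, d_name, acceptor, a_name, dist, ada, daa)


def detect_hbonds(structure: Structure, library: BaseLibrary | None = None,
                  params: HBondParams | None = None) -> list[HydrogenBond]:
    """All base-base hydrogen bonds in a structure.

    Every ordered (donor base, acceptor base) pair of distinct bases is
    scanned over the donor/acceptor inventories of the library.  An atom
    pair in which both atoms are donor- and acceptor-capable can appear
    in both directions, once per legal role assignment.

    Returns bonds sorted by (donor residue, donor atom, acceptor residue,
    acceptor atom); the result is invariant under input atom-record order.
    """
    lib = library or BaseLibrary()
    p = params or default_params()
    for b in structure.bases:
        if b.base_code not in lib:
            raise LibraryError(
                f"residue {b.res_name} {b.chain_id}{b.res_seq}: "
                f"base code {b.base_code!r} missing from library")

    centroids = np.array([
        np.mean([a.position for a in b.atoms], axis=0) for b in structure.bases
    ])
    cutoff = p.max_da_distance + _CENTROID_CUTOFF_PAD
    bonds: list[HydrogenBond] = []
    n = len(structure.bases)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if np.linalg.norm(centroids[i] - centroids[j]) > cutoff:
                continue
            bonds.extend(_directional_bonds(
                structure.bases[i], structure.bases[j], lib, p))
    bonds.sort(key=lambda b: b.key)
    return bonds
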