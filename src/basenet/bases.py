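"""Nucleobase chemistry library.

Defines, for every supported base, the heavy atoms of the base moiety
(ring plus exocyclic substituents -- ribose and phosphate atoms are
deliberately excluded), the hydrogen-bond donor and acceptor atoms, the
antecedent (covalently bonded ring atom) used in angle tests, and an
idealized planar template geometry used by the synthetic fixture
generator.

Modified bases are supported through a residue-name map that points each
modified residue at a parent-derived donor/acceptor inventory; the map is
extensible at run time or through a YAML config file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

WILDCARD = "*"

#: Heavy atoms retained for each canonical base (base moiety only).
MOIETY_ATOMS: dict[str, tuple[str, ...]] = {
    "A": ("N1", "C2", "N3", "C4", "C5", "C6", "N6", "N7", "C8", "N9"),
    "G": ("N1", "C2", "N2", "N3", "C4", "C5", "C6", "O6", "N7", "C8", "N9"),
    "C": ("N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"),
    "U": ("N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"),
}


@dataclass(frozen=True)
class BaseChemistry:
    """Donor/acceptor inventory of one base type."""

    code: str
    parent: str  # canonical base supplying moiety atoms and geometry
    donors: tuple[str, ...]
    acceptors: tuple[str, ...]
    antecedent: dict[str, str] = field(default_factory=dict)

    @property
    def moiety(self) -> tuple[str, ...]:
        return MOIETY_ATOMS[self.parent]


# Antecedents: the ring atom covalently bonded to each polar atom, used as
# the third point of the two approach-angle tests.  Where a ring nitrogen
# has two ring neighbours the lower-numbered carbon is used; the choice
# only rotates the reference by a few degrees and is fixed for determinism.
_ANTECEDENTS = {
    "A": {"N6": "C6", "N1": "C6", "N3": "C2", "N7": "C5"},
    "G": {"N1": "C6", "N2": "C2", "O6": "C6", "N3": "C2", "N7": "C5"},
    "C": {"N4": "C4", "O2": "C2", "N3": "C2"},
    "U": {"N3": "C2", "O2": "C2", "O4": "C4"},
}

_CANONICAL = {
    "A": BaseChemistry("A", "A", ("N6",), ("N1", "N3", "N7"), _ANTECEDENTS["A"]),
    "G": BaseChemistry("G", "G", ("N1", "N2"), ("O6", "N3", "N7"), _ANTECEDENTS["G"]),
    "C": BaseChemistry("C", "C", ("N4",), ("O2", "N3"), _ANTECEDENTS["C"]),
    "U": BaseChemistry("U", "U", ("N3",), ("O2", "O4"), _ANTECEDENTS["U"]),
}

# Pseudouridine: C-glycosidic, so N1 carries a proton and becomes a donor.
_PSU = BaseChemistry(
    "PSU", "U", ("N1", "N3"), ("O2", "O4"),
    {"N1": "C2", "N3": "C2", "O2": "C2", "O4": "C4"},
)


def _derived(code: str, parent: str, drop_donors=(), drop_acceptors=()) -> BaseChemistry:
    p = _CANONICAL[parent]
    return BaseChemistry(
        code,
        parent,
        tuple(d for d in p.donors if d not in drop_donors),
        tuple(a for a in p.acceptors if a not in drop_acceptors),
        p.antecedent,
    )


# Common modified ribonucleotides.  Methylation removes the methylated
# atom from the donor (if N-H lost) or acceptor (if lone pair blocked)
# inventory; the moiety atom list stays that of the parent because methyl
# carbons are not hydrogen-bond participants.
_MODIFIED = {
    "PSU": _PSU,
    "1MA": _derived("1MA", "A", drop_acceptors=("N1",)),
    "5MC": _derived("5MC", "C"),
    "OMC": _derived("OMC", "C"),
    "7MG": _derived("7MG", "G", drop_acceptors=("N7",)),
    "2MG": _derived("2MG", "G"),
    "M2G": _derived("M2G", "G", drop_donors=("N2",)),
    "OMG": _derived("OMG", "G"),
    "H2U": _derived("H2U", "U"),
    "5MU": _derived("5MU", "U"),
}

#: PDB residue names accepted for the four canonical ribonucleotides.
_RESIDUE_ALIASES = {
    "A": "A", "ADE": "A", "RA": "A",
    "G": "G", "GUA": "G", "RG": "G",
    "C": "C", "CYT": "C", "RC": "C",
    "U": "U", "URA": "U", "URI": "U", "RU": "U",
}

_DNA_ALIASES = {"DA": "A", "DG": "G", "DC": "C", "DT": "U"}


class BaseLibrary:
    """Registry mapping PDB residue names to base chemistry.

    Parameters
    ----------
    include_dna
        When true, DNA residues (DA/DC/DG/DT) are admitted and mapped to
        their ribo parents (T to U).  Off by default: the tool targets RNA.
    """

    def __init__(self, include_dna: bool = False):
        self._by_code: dict[str, BaseChemistry] = dict(_CANONICAL)
        self._by_code.update(_MODIFIED)
        self._residue_map: dict[str, str] = dict(_RESIDUE_ALIASES)
        for name in _MODIFIED:
            self._residue_map[name] = name
        if include_dna:
            self._residue_map.update(_DNA_ALIASES)

    def resolve_residue(self, res_name: str) -> str | None:
        """Map a PDB residue name to a base code, or None if unknown."""
        return self._residue_map.get(res_name.strip().upper())

    def __contains__(self, base_code: str) -> bool:
        return base_code in self._by_code

    def chemistry(self, base_code: str) -> BaseChemistry:
        try:
            return self._by_code[base_code]
        except KeyError:
            raise KeyError(f"base code {base_code!r} is not in the base library") from None

    def moiety(self, base_code: str) -> tuple[str, ...]:
        return self.chemistry(base_code).moiety

    def donors(self, base_code: str) -> tuple[str, ...]:
        return self.chemistry(base_code).donors

    def acceptors(self, base_code: str) -> tuple[str, ...]:
        return self.chemistry(base_code).acceptors

    def antecedent(self, base_code: str, atom: str) -> str | None:
        return self.chemistry(base_code).antecedent.get(atom)

    @property
    def base_codes(self) -> tuple[str, ...]:
        return tuple(sorted(self._by_code))

    def register(self, code: str, parent: str, donors, acceptors,
                 antecedent=None, residue_names=()) -> None:
        """Add or override a (modified) base definition."""
        if parent not in _CANONICAL:
            raise KeyError(f"parent base {parent!r} must be one of A/C/G/U")
        ante = dict(antecedent) if antecedent else dict(_CANONICAL[parent].antecedent)
        chem = BaseChemistry(code, parent, tuple(donors), tuple(acceptors), ante)
        for atom in chem.donors + chem.acceptors:
            if atom not in chem.moiety:
                raise ValueError(f"{code}: atom {atom} not in {parent} moiety")
        self._by_code[code] = chem
        self._residue_map[code] = code
        for name in residue_names:
            self._residue_map[name.strip().upper()] = code

    def apply_config(self, mapping: dict) -> None:
        """Apply a parsed config ``bases:`` section (see ``load_library``)."""
        for code, entry in mapping.items():
            self.register(
                code.upper(),
                entry["parent"].upper(),
                entry.get("donors", ()),
                entry.get("acceptors", ()),
                entry.get("antecedent"),
                entry.get("residue_names", ()),
            )


def load_library(path=None, include_dna: bool = False) -> BaseLibrary:
    """Build the default library, optionally extended from a YAML file.

    The file may contain a ``bases:`` mapping of base code to
    ``{parent, donors, acceptors, antecedent?, residue_names?}``.
    """
    lib = BaseLibrary(include_dna=include_dna)
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        lib.apply_config(doc.get("bases", {}))
    return lib


# ---------------------------------------------------------------------------
# Idealized planar template geometry (used by the fixture generator).
# ---------------------------------------------------------------------------

_RING_BOND = 1.375     # aromatic ring bond length, Angstrom
_C_O = 1.23            # exocyclic carbonyl
_C_N = 1.34            # exocyclic amine


def _hexagon() -> dict[str, np.ndarray]:
    """Regular hexagon N1,C2,N3,C4,C5,C6 in the z=0 plane, centred at 0."""
    names = ("N1", "C2", "N3", "C4", "C5", "C6")
    coords = {}
    for k, name in enumerate(names):
        ang = math.pi / 2 - k * math.pi / 3  # N1 at top, clockwise
        coords[name] = np.array(
            [_RING_BOND * math.cos(ang), _RING_BOND * math.sin(ang), 0.0]
        )
    return coords


def _exocyclic(ring: dict[str, np.ndarray], attach: str, length: float) -> np.ndarray:
    direction = ring[attach] / np.linalg.norm(ring[attach])
    return ring[attach] + length * direction


def _fuse_pentagon(ring: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Fuse the imidazole ring (N9,C8,N7) onto the C4-C5 hexagon edge."""
    p4, p5 = ring["C4"][:2], ring["C5"][:2]
    side = np.linalg.norm(p5 - p4)
    mid = (p4 + p5) / 2.0
    out = mid / np.linalg.norm(mid)  # hexagon centred at origin: outward normal
    apothem = side / (2.0 * math.tan(math.pi / 5.0))
    centre = mid + apothem * out

    def rot(p, ang):
        c, s = math.cos(ang), math.sin(ang)
        v = p - centre
        return centre + np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])

    step = 2.0 * math.pi / 5.0
    # Orientation: rotating C4 away from C5 walks towards N9, C8; rotating
    # C5 the other way gives N7.
    if np.linalg.norm(rot(p4, step) - p5) > np.linalg.norm(rot(p4, -step) - p5):
        n9, c8, n7 = rot(p4, step), rot(p4, 2 * step), rot(p5, -step)
    else:
        n9, c8, n7 = rot(p4, -step), rot(p4, -2 * step), rot(p5, step)
    to3 = lambda p: np.array([p[0], p[1], 0.0])
    return {"N9": to3(n9), "C8": to3(c8), "N7": to3(n7)}


def _build_templates() -> dict[str, dict[str, np.ndarray]]:
    hexa = _hexagon()
    pent = _fuse_pentagon(hexa)

    purine = dict(hexa)
    purine.update(pent)

    ade = dict(purine)
    ade["N6"] = _exocyclic(hexa, "C6", _C_N)

    gua = dict(purine)
    gua["O6"] = _exocyclic(hexa, "C6", _C_O)
    gua["N2"] = _exocyclic(hexa, "C2", _C_N)

    pyr = dict(hexa)
    pyr["O2"] = _exocyclic(hexa, "C2", _C_O)

    ura = dict(pyr)
    ura["O4"] = _exocyclic(hexa, "C4", _C_O)

    cyt = dict(pyr)
    cyt["N4"] = _exocyclic(hexa, "C4", _C_N)

    return {"A": ade, "G": gua, "C": cyt, "U": ura}


_TEMPLATES = _build_templates()


def template_coords(base_code: str, library: BaseLibrary | None = None) -> dict[str, np.ndarray]:
    """Idealized planar coordinates (Angstrom) for a base's moiety atoms.

    Modified bases reuse their parent's geometry.
    """
    lib = library or BaseLibrary()
    parent = lib.chemistry(base_code).parent
    return {name: pos.copy() for name, pos in _TEMPLATES[parent].items()}
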