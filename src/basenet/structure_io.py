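"""Reading RNA structures from PDB files.

Extracts the nucleobase residues of one model, keeps only base-moiety
heavy atoms (ring plus exocyclic substituents; ribose and phosphate are
dropped), strips hydrogens, and resolves alternate locations to a single
conformer (highest occupancy, ties broken towards altloc 'A' then
lexicographically).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .bases import BaseLibrary

log = logging.getLogger(__name__)

_HYDROGEN_ELEMENTS = {"H", "D", "T"}


class StructureError(ValueError):
    """Base class for structure-reading failures."""


class EmptyStructureError(StructureError):
    """No recognisable RNA base residues were found."""


class ModelNotFoundError(StructureError):
    """The requested MODEL number is absent from the file."""


class ParseError(StructureError):
    """The PDB text could not be parsed."""


@dataclass(frozen=True)
class Atom:
    """One heavy atom of a base moiety."""

    name: str
    element: str
    position: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not self.element:
            raise ValueError(f"atom {self.name}: element symbol is empty")


@dataclass
class BaseNode:
    """One nucleobase residue and its moiety atoms."""

    chain_id: str
    res_seq: int
    icode: str
    res_name: str
    base_code: str
    atoms: list[Atom] = field(default_factory=list)
    irn: int | None = None       # assigned by the connection-table builder
    order_index: int = 0         # position in structure file order

    @property
    def resid(self) -> tuple[str, int, str]:
        """Author residue identifier (chain, number, insertion code)."""
        return (self.chain_id, self.res_seq, self.icode)

    @property
    def label(self) -> str:
        """Human-readable id like ``A9`` or ``B:U12``."""
        core = f"{self.base_code}{self.res_seq}{self.icode.strip()}"
        return core if self.chain_id in ("", "A") else f"{self.chain_id}:{core}"

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"{self.label} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)


@dataclass
class Structure:
    """The RNA bases of one model of one structure file."""

    source_id: str
    model_number: int
    bases: list[BaseNode] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.bases)

    def base(self, chain_id: str, res_seq: int, icode: str = "") -> BaseNode:
        for b in self.bases:
            if b.resid == (chain_id, res_seq, icode):
                return b
        raise KeyError(f"no base {chain_id}/{res_seq}{icode}")

    def subset(self, resids) -> "Structure":
        """Structure restricted to the given (chain, res_seq, icode) ids."""
        wanted = set(resids)
        bases = [b for b in self.bases if b.resid in wanted]
        return Structure(self.source_id, self.model_number, bases)


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    """Highest occupancy wins; ties go to altloc 'A', then lexicographic."""
    def key(a: gemmi.Atom):
        alt = a.altloc if a.altloc else "A"
        return (-a.occ, alt != "A", alt)
    return sorted(atoms, key=key)[0]


def _convert_residue(res: gemmi.Residue, chain_id: str, base_code: str,
                     moiety: tuple[str, ...], order_index: int) -> BaseNode:
    by_name: dict[str, list[gemmi.Atom]] = {}
    for a in res:
        if a.element.name.upper() in _HYDROGEN_ELEMENTS:
            continue
        if a.name not in moiety:
            continue
        by_name.setdefault(a.name, []).append(a)
    atoms = []
    for name in moiety:  # deterministic, template order
        if name not in by_name:
            continue
        ga = _pick_altloc(by_name[name])
        atoms.append(Atom(
            name=name,
            element=ga.element.name,
            position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
            occupancy=ga.occ,
            altloc=ga.altloc or "",
        ))
    seqid = res.seqid
    return BaseNode(
        chain_id=chain_id,
        res_seq=seqid.num,
        icode=(seqid.icode or "").strip(),
        res_name=res.name.strip(),
        base_code=base_code,
        atoms=atoms,
        order_index=order_index,
    )


def parse_structure(pdb_text: str, model: int = 1, chains=None,
                    library: BaseLibrary | None = None,
                    source_id: str = "structure") -> Structure:
    """Parse PDB text into the RNA bases of one model.

    Parameters
    ----------
    pdb_text
        Full text of a PDB file (ATOM/HETATM/MODEL records).
    model
        MODEL number to keep; single-model files always use their only
        model regardless of numbering.
    chains
        Optional iterable of chain ids; None keeps all chains.
    library
        Base library used to recognise residues; defaults to the built-in
        RNA library (no DNA).

    Raises
    ------
    ParseError, ModelNotFoundError, EmptyStructureError
    """
    lib = library or BaseLibrary()
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"could not parse PDB text: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError("no models in input")

    picked = None
    if len(st) == 1:
        picked = st[0]
    else:
        for m in st:
            if m.num == model:
                picked = m
                break
        if picked is None:
            nums = [m.num for m in st]
            raise ModelNotFoundError(f"model {model} not found (models present: {nums})")

    chain_filter = set(chains) if chains is not None else None
    bases: list[BaseNode] = []
    order = 0
    for chain in picked:
        if chain_filter is not None and chain.name not in chain_filter:
            continue
        for res in chain:
            code = lib.resolve_residue(res.name)
            if code is None:
                continue
            node = _convert_residue(res, chain.name, code, lib.moiety(code), order)
            if not node.atoms:
                log.warning("residue %s %s%d has no moiety atoms; dropped",
                            res.name, chain.name, res.seqid.num)
                continue
            bases.append(node)
            order += 1
    if not bases:
        raise EmptyStructureError(f"{source_id}: no RNA base residues found")
    return Structure(source_id=source_id, model_number=picked.num, bases=bases)


def parse_structure_file(path, model: int = 1, chains=None,
                         library: BaseLibrary | None = None) -> Structure:
    """Read a PDB file from disk (thin wrapper over ``parse_structure``)."""
    import os
    with open(path) as fh:
        text = fh.read()
    return parse_structure(text, model=model, chains=chains, library=library,
                           source_id=os.path.basename(str(path)))


def strip_hydrogens(structure: Structure) -> Structure:
    """Return a copy with all H/D atoms removed (idempotent).

    Moiety filtering already excludes hydrogens during parsing; this is
    the explicit guarantee for structures built by other routes.
    """
    bases = []
    for b in structure.bases:
        heavy = [a for a in b.atoms if a.element.upper() not in _HYDROGEN_ELEMENTS]
        bases.append(replace(b, atoms=heavy))
    return Structure(structure.source_id, structure.model_number, bases)
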