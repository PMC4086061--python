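import numpy as np
import pytest

from basenet import (BaseLibrary, EmptyStructureError, ModelNotFoundError,
                     parse_structure, strip_hydrogens)
from basenet.fixtures import FixtureSpec, generate_fixture


def _pdb_line(serial, name, res_name, chain, seq, x, y, z, element,
              occ=1.0, altloc=" "):
    return (f"ATOM  {serial:5d} {name:<4s}{altloc}{res_name:>3s} {chain}"
            f"{seq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00"
            f"          {element:>2s}")


MINIMAL_A = "\n".join([
    _pdb_line(i + 1, n, "A", "A", 5, *xyz, n[0])
    for i, (n, xyz) in enumerate([
        ("N1", (0.0, 1.4, 0.0)), ("C2", (1.2, 0.7, 0.0)),
        ("N3", (1.2, -0.7, 0.0)), ("C4", (0.0, -1.4, 0.0)),
        ("C5", (-1.2, -0.7, 0.0)), ("C6", (-1.2, 0.7, 0.0)),
        ("N6", (-2.4, 1.4, 0.0)), ("N7", (-2.3, -1.5, 0.0)),
        ("C8", (-1.4, -2.5, 0.0)), ("N9", (-0.1, -2.8, 0.0)),
    ])
]) + "\nEND\n"


class TestParsing:
    def test_single_adenosine(self):
        st = parse_structure(MINIMAL_A)
        assert len(st.bases) == 1
        base = st.bases[0]
        assert base.base_code == "A"
        assert base.chain_id == "A" and base.res_seq == 5
        assert {a.name for a in base.atoms} == {
            "N1", "C2", "N3", "C4", "C5", "C6", "N6", "N7", "C8", "N9"}

    def test_model_selection_uses_requested_coordinates(self):
        shifted = MINIMAL_A.replace("END\n", "")
        m2 = "\n".join(
            _pdb_line(i + 1, n, "A", "A", 5, 10.0 + i, 0.0, 0.0, n[0])
            for i, n in enumerate(
                ["N1", "C2", "N3", "C4", "C5", "C6", "N6", "N7", "C8", "N9"])
        )
        text = f"MODEL        1\n{shifted}ENDMDL\nMODEL        2\n{m2}\nENDMDL\nEND\n"
        st = parse_structure(text, model=2)
        assert len(st.bases) == 1
        assert st.model_number == 2
        assert st.bases[0].atom("N1").position[0] == pytest.approx(10.0)

    def test_missing_model_raises(self):
        text = f"MODEL        1\n{MINIMAL_A.replace('END', 'ENDMDL')}MODEL        2\n{MINIMAL_A.replace('END', 'ENDMDL')}END\n"
        with pytest.raises(ModelNotFoundError):
            parse_structure(text, model=7)

    def test_no_rna_bases_raises(self):
        text = _pdb_line(1, "CA", "GLY", "A", 1, 0, 0, 0, "C") + "\nEND\n"
        with pytest.raises(EmptyStructureError):
            parse_structure(text)

    def test_unknown_residues_dropped_not_guessed(self):
        text = MINIMAL_A.replace("END\n", "") + \
            _pdb_line(20, "CA", "GLY", "A", 9, 5, 5, 5, "C") + "\nEND\n"
        st = parse_structure(text)
        assert [b.res_seq for b in st.bases] == [5]

    def test_deterministic(self):
        a = parse_structure(MINIMAL_A)
        b = parse_structure(MINIMAL_A)
        assert [x.resid for x in a.bases] == [y.resid for y in b.bases]
        assert all(
            np.array_equal(p.position, q.position)
            for x, y in zip(a.bases, b.bases)
            for p, q in zip(x.atoms, y.atoms)
        )

    def test_chain_filter(self):
        spec = FixtureSpec(bases=[("A", 1, "G"), ("B", 2, "C")],
                           intended_edges=[], seed=0)
        text = generate_fixture(spec)
        st = parse_structure(text, chains=["B"])
        assert [b.chain_id for b in st.bases] == ["B"]

    def test_non_moiety_atoms_excluded(self):
        # ribose/phosphate atoms must never survive into a BaseNode
        extra = _pdb_line(30, "O2'", "A", "A", 5, 3, 3, 3, "O") + "\n" + \
            _pdb_line(31, "P", "A", "A", 5, 4, 4, 4, "P") + "\nEND\n"
        st = parse_structure(MINIMAL_A.replace("END\n", "") + extra)
        names = {a.name for a in st.bases[0].atoms}
        assert "O2'" not in names and "P" not in names


class TestAltloc:
    def test_highest_occupancy_wins(self):
        lines = MINIMAL_A.replace("END\n", "")
        alt_a = _pdb_line(40, "N6", "A", "A", 5, -2.4, 1.4, 0.0, "N",
                          occ=0.3, altloc="A")
        alt_b = _pdb_line(41, "N6", "A", "A", 5, -9.9, 1.4, 0.0, "N",
                          occ=0.7, altloc="B")
        text = lines.replace(
            _pdb_line(7, "N6", "A", "A", 5, -2.4, 1.4, 0.0, "N"),
            alt_a + "\n" + alt_b) + "END\n"
        st = parse_structure(text)
        n6 = st.bases[0].atom("N6")
        assert n6.position[0] == pytest.approx(-9.9)

    def test_occupancy_tie_prefers_altloc_a(self):
        lines = MINIMAL_A.replace("END\n", "")
        alt_a = _pdb_line(40, "N6", "A", "A", 5, -2.4, 1.4, 0.0, "N",
                          occ=0.5, altloc="A")
        alt_b = _pdb_line(41, "N6", "A", "A", 5, -9.9, 1.4, 0.0, "N",
                          occ=0.5, altloc="B")
        text = lines.replace(
            _pdb_line(7, "N6", "A", "A", 5, -2.4, 1.4, 0.0, "N"),
            alt_b + "\n" + alt_a) + "END\n"
        st = parse_structure(text)
        assert st.bases[0].atom("N6").position[0] == pytest.approx(-2.4)


class TestStripHydrogens:
    def test_strip_is_idempotent_and_conserves_heavy_atoms(self, triple_structure):
        once = strip_hydrogens(triple_structure)
        twice = strip_hydrogens(once)
        n_before = sum(len(b.atoms) for b in triple_structure.bases)
        assert sum(len(b.atoms) for b in once.bases) == n_before
        assert [len(b.atoms) for b in twice.bases] == [len(b.atoms) for b in once.bases]
        assert not any(a.element.upper() in ("H", "D")
                       for b in once.bases for a in b.atoms)

    def test_hydrogens_removed_during_parsing(self):
        # explicit H atoms in the file must not reach the BaseNode
        text = MINIMAL_A.replace("END\n", "") + \
            _pdb_line(50, "H61", "A", "A", 5, -3.0, 1.8, 0.0, "H") + "\nEND\n"
        st = parse_structure(text)
        assert len(st.bases[0].atoms) == 10


def test_dna_excluded_by_default_and_included_on_request():
    text = MINIMAL_A.replace(" A A", "DA A").replace('"A"', '"DA"')
    # res_name "DA": column replacement above rewrites the residue field
    with pytest.raises(EmptyStructureError):
        parse_structure(text)
    st = parse_structure(text, library=BaseLibrary(include_dna=True))
    assert st.bases[0].base_code == "A"
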