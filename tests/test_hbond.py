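import numpy as np
import pytest

from basenet import (BaseLibrary, HBondParams, LibraryError, default_params,
                     detect_hbonds, parse_structure)
from basenet.fixtures import FixtureSpec, generate_fixture
from basenet.hbond import angle_deg


class TestParams:
    def test_defaults(self):
        p = default_params()
        assert p.max_da_distance == pytest.approx(3.9)
        assert p.min_ada_angle == pytest.approx(90.0)
        assert p.min_daa_angle == pytest.approx(90.0)

    def test_yaml_round_trip(self):
        p = HBondParams(max_da_distance=3.3, min_ada_angle=100, min_daa_angle=95)
        assert HBondParams.from_yaml(p.to_yaml()) == p

    @pytest.mark.parametrize("kwargs", [
        {"max_da_distance": -1.0},
        {"min_ada_angle": 181.0},
        {"min_daa_angle": -5.0},
    ])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            HBondParams(**kwargs)


@pytest.fixture(scope="module")
def engineered_pair():
    """Two bases placed with a single intended N->O bond near 2.9 A."""
    spec = FixtureSpec(bases=[("A", 1, "A"), ("A", 3, "U")],
                       intended_edges=[(0, 1, 1)],
                       pinned_bonds={(0, 1): [(0, "N6", 1, "O4")]},
                       seed=11)
    return parse_structure(generate_fixture(spec))


class TestDetection:
    def test_distant_bases_yield_nothing(self):
        spec = FixtureSpec(bases=[("A", 1, "G"), ("A", 3, "C")],
                           intended_edges=[], seed=0)
        st = parse_structure(generate_fixture(spec))
        assert detect_hbonds(st) == []

    def test_engineered_pair_found_and_geometry_verified(self, engineered_pair):
        bonds = detect_hbonds(engineered_pair)
        assert len(bonds) == 1
        b = bonds[0]
        assert (b.donor_atom, b.acceptor_atom) == ("N6", "O4")
        # recompute the geometry directly from the parsed coordinates
        donor = engineered_pair.base("A", 1)
        acceptor = engineered_pair.base("A", 3)
        d = np.linalg.norm(donor.atom("N6").position - acceptor.atom("O4").position)
        assert b.da_distance == pytest.approx(d)
        assert d == pytest.approx(2.9, abs=0.15)
        ada = angle_deg(donor.atom("C6").position, donor.atom("N6").position,
                        acceptor.atom("O4").position)
        assert b.ada_angle == pytest.approx(ada)
        assert ada >= 90.0

    def test_every_emitted_bond_satisfies_criteria(self, octuple_structure, library):
        params = default_params()
        for b in detect_hbonds(octuple_structure, library, params):
            assert b.da_distance <= params.max_da_distance
            assert b.ada_angle >= params.min_ada_angle
            assert b.daa_angle >= params.min_daa_angle
            assert b.donor_base.resid != b.acceptor_base.resid
            assert b.donor_atom in library.donors(b.donor_base.base_code)
            assert b.acceptor_atom in library.acceptors(b.acceptor_base.base_code)

    def test_output_sorted_and_order_invariant(self, triple_structure, library):
        bonds = detect_hbonds(triple_structure, library)
        keys = [b.key for b in bonds]
        assert keys == sorted(keys)
        reversed_structure = type(triple_structure)(
            triple_structure.source_id, triple_structure.model_number,
            list(reversed(triple_structure.bases)))
        assert [b.key for b in detect_hbonds(reversed_structure, library)] == keys

    def test_unknown_base_code_raises(self, triple_structure, library):
        broken = triple_structure.bases[0]
        old = broken.base_code
        try:
            broken.base_code = "XXX"
            with pytest.raises(LibraryError):
                detect_hbonds(triple_structure, library)
        finally:
            broken.base_code = old

    def test_centroid_prefilter_matches_full_scan(self, library):
        # all-pairs scan without the centroid shortcut must agree
        from basenet.hbond import _directional_bonds
        spec = FixtureSpec(
            bases=[("A", 1, "G"), ("A", 3, "C"), ("A", 5, "A"), ("A", 7, "U")],
            intended_edges=[(0, 1, 2), (1, 2, 1), (2, 3, 1)], seed=21)
        st = parse_structure(generate_fixture(spec))
        fast = detect_hbonds(st, library)
        slow = []
        for d in st.bases:
            for a in st.bases:
                if d is not a:
                    slow.extend(_directional_bonds(d, a, library, default_params()))
        assert sorted(b.key for b in slow) == [b.key for b in fast]


class TestMonotonicity:
    @pytest.mark.parametrize("seed", [101, 202, 303])
    def test_narrowing_cutoff_never_adds_bonds(self, seed, library):
        from basenet import random_fixture
        _spec, text = random_fixture(seed)
        st = parse_structure(text)
        wide = {b.key for b in detect_hbonds(st, library, HBondParams(max_da_distance=3.9))}
        for cutoff in (3.5, 3.1, 2.7):
            narrow = {b.key for b in detect_hbonds(
                st, library, HBondParams(max_da_distance=cutoff))}
            assert narrow <= wide
            wide = narrow

    def test_raising_angle_minimum_never_adds_bonds(self, triple_structure, library):
        base = {b.key for b in detect_hbonds(triple_structure, library)}
        stricter = {b.key for b in detect_hbonds(
            triple_structure, library,
            HBondParams(min_ada_angle=130, min_daa_angle=130))}
        assert stricter <= base
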