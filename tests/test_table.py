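import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from basenet import (BondCode, build_table, decode_bond, encode_bond,
                     parse_bond_code, read_table, table_to_json, write_table)
from basenet.table import TableFormatError
from conftest import make_base, make_bond, random_bond_table


@pytest.fixture()
def fig_triple_bases():
    a9 = make_base("A", 9, "A", 0)
    u12 = make_base("A", 12, "U", 1)
    a23 = make_base("A", 23, "A", 2)
    return a9, u12, a23


@pytest.fixture()
def fig_triple_bonds(fig_triple_bases):
    """The four bonds of the A9.A23.U12 triple; U12-A23 atom pairs are the
    published ones, A9-A23 uses a standard N6/N7 arrangement."""
    a9, u12, a23 = fig_triple_bases
    return [
        make_bond(a23, "N6", u12, "O4"),
        make_bond(u12, "N3", a23, "N1"),
        make_bond(a9, "N6", a23, "N7"),
        make_bond(a23, "N6", a9, "N7"),
    ]


class TestBuildTable:
    def test_empty(self):
        t = build_table([])
        assert t.nodes == [] and t.edges == {} and t.total_bonds == 0

    def test_triple_topology(self, fig_triple_bonds, fig_triple_bases):
        t = build_table(fig_triple_bonds)
        a9, u12, a23 = fig_triple_bases
        assert [n.resid for n in t.nodes] == [a9.resid, u12.resid, a23.resid]
        assert t.partners(a23.irn) == [a9.irn, u12.irn]
        assert t.bond_count(a23.irn, a9.irn) == 2
        assert t.bond_count(a23.irn, u12.irn) == 2

    def test_line_graph_degree_sequence(self):
        xs = [make_base("A", k, "G", k) for k in range(3)]
        bonds = [make_bond(xs[0], "N1", xs[1], "O6"),
                 make_bond(xs[1], "N2", xs[2], "N7"),
                 make_bond(xs[2], "N1", xs[1], "N3")]
        t = build_table(bonds)
        degrees = sorted(t.degree(n.irn) for n in t.nodes)
        assert degrees == [1, 1, 2]
        # 3 bonds among 3 bases over 2 edges
        assert t.total_bonds == 3

    def test_duplicate_bonds_deduplicated(self, fig_triple_bonds):
        t = build_table(fig_triple_bonds + [fig_triple_bonds[0]])
        assert t.total_bonds == 4

    def test_handshake_identity(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            t = random_bond_table(rng)
            per_node = sum(t.bond_count(n.irn, p)
                           for n in t.nodes for p in t.partners(n.irn))
            assert per_node == 2 * t.total_bonds

    def test_irn_is_a_stable_bijection(self):
        rng = np.random.default_rng(6)
        t = random_bond_table(rng)
        irns = [n.irn for n in t.nodes]
        assert irns == list(range(1, len(t.nodes) + 1))


class TestBondCodes:
    def test_published_codes(self, fig_triple_bonds, fig_triple_bases):
        _a9, u12, a23 = fig_triple_bases
        n6_o4, n3_n1 = fig_triple_bonds[0], fig_triple_bonds[1]
        assert encode_bond(n6_o4, u12).text == "-1604"
        assert encode_bond(n3_n1, u12).text == "1311"
        assert encode_bond(n6_o4, a23).text == "1604"

    def test_decode_published_codes(self, fig_triple_bases):
        _a9, u12, a23 = fig_triple_bases
        b = decode_bond(parse_bond_code("-1604"), u12, a23)
        assert (b.donor_base.resid, b.donor_atom) == (a23.resid, "N6")
        assert (b.acceptor_base.resid, b.acceptor_atom) == (u12.resid, "O4")
        b2 = decode_bond(parse_bond_code("1311"), u12, a23)
        assert (b2.donor_base.resid, b2.donor_atom) == (u12.resid, "N3")
        assert (b2.acceptor_base.resid, b2.acceptor_atom) == (a23.resid, "N1")

    def test_round_trip_random(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            t = random_bond_table(rng)
            for (i, j), bonds in t.edges.items():
                for b in bonds:
                    for side in (i, j):
                        node = t.node(side)
                        partner = t.node(j if side == i else i)
                        code = encode_bond(b, node)
                        back = decode_bond(parse_bond_code(code.text), node, partner)
                        assert back.key == b.key

    def test_extended_token_for_exotic_atoms(self):
        code = BondCode(False, "N10", "O4")
        assert code.text == "N10>O4"
        parsed = parse_bond_code("-N10>O4")
        assert parsed.donor_is_partner and parsed.donor_atom == "N10"

    @pytest.mark.parametrize("bad", ["", "16", "abcd", "9604", "16044"])
    def test_malformed_codes_rejected(self, bad):
        with pytest.raises(TableFormatError):
            parse_bond_code(bad)

    def test_non_endpoint_perspective_rejected(self, fig_triple_bonds):
        stranger = make_base("Z", 99, "C", 9)
        with pytest.raises(ValueError):
            encode_bond(fig_triple_bonds[0], stranger)


class TestSerialization:
    def test_triple_round_trip(self, fig_triple_bonds):
        t = build_table(fig_triple_bonds)
        assert read_table(write_table(t)).signature() == t.signature()

    def test_empty_round_trip(self):
        t = build_table([])
        assert read_table(write_table(t)).signature() == t.signature()

    def test_hand_written_two_node_table(self):
        text = "\n".join([
            "1 G A.4 1",
            "> 2 1 1113",
            "2 C A.8 1",
            "> 1 1 -1113",
        ])
        t = read_table(text)
        assert len(t.nodes) == 2
        assert t.bond_count(1, 2) == 1
        b = t.edge_bonds(1, 2)[0]
        assert (b.donor_atom, b.acceptor_atom) == ("N1", "N3")
        assert b.donor_base.resid == ("A", 4, "")

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_round_trip_is_lossless_on_random_tables(self, seed):
        t = random_bond_table(np.random.default_rng(seed))
        assert read_table(write_table(t)).signature() == t.signature()

    def test_malformed_line_reports_line_number(self):
        with pytest.raises(TableFormatError, match="line 2"):
            read_table("1 G A.4 1\n> nonsense here\n")

    def test_json_twin_contains_distances(self, triple_table):
        doc = table_to_json(triple_table)
        assert '"distance"' in doc and '"irn"' in doc
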