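import itertools

import numpy as np
import pytest

from basenet import (BaseLibrary, BaseNode, HydrogenBond, build_table,
                     detect_hbonds, parse_structure)
from basenet.synthetic import synthetic_octuple_pdb, synthetic_triple_pdb


@pytest.fixture(scope="session")
def library():
    return BaseLibrary()


@pytest.fixture(scope="session")
def triple_structure():
    """Synthetic A9.A23.U12 triple (idealized geometry, 4 bonds)."""
    return parse_structure(synthetic_triple_pdb(), source_id="triple")


@pytest.fixture(scope="session")
def triple_table(triple_structure, library):
    return build_table(detect_hbonds(triple_structure, library))


@pytest.fixture(scope="session")
def octuple_structure():
    """Two interconnected star quadruples (GGGG + CCUU)."""
    return parse_structure(synthetic_octuple_pdb(), source_id="octuple")


@pytest.fixture(scope="session")
def octuple_table(octuple_structure, library):
    return build_table(detect_hbonds(octuple_structure, library))


def make_base(chain, seq, code, order, library=None):
    """Geometry-free base node (graph tests only need identities)."""
    return BaseNode(chain_id=chain, res_seq=seq, icode="", res_name=code,
                    base_code=code, atoms=[], order_index=order)


def make_bond(donor, d_atom, acceptor, a_atom, dist=2.9):
    return HydrogenBond(donor, d_atom, acceptor, a_atom, dist, 150.0, 150.0)


def random_bond_table(rng, max_nodes=10, max_edges=15):
    """Random geometry-free connection table for graph-level tests."""
    lib = BaseLibrary()
    n = int(rng.integers(2, max_nodes + 1))
    codes = [str(rng.choice(["A", "C", "G", "U"])) for _ in range(n)]
    nodes = [make_base("A", 10 + k, codes[k], k) for k in range(n)]
    possible = list(itertools.combinations(range(n), 2))
    rng.shuffle(possible)
    n_edges = int(rng.integers(1, min(max_edges, len(possible)) + 1))
    bonds = []
    for (i, j) in possible[:n_edges]:
        chem_i, chem_j = lib.chemistry(codes[i]), lib.chemistry(codes[j])
        combos = [(i, d, j, a) for d in chem_i.donors for a in chem_j.acceptors]
        combos += [(j, d, i, a) for d in chem_j.donors for a in chem_i.acceptors]
        k = int(rng.integers(1, min(3, len(combos)) + 1))
        picks = rng.choice(len(combos), size=k, replace=False)
        for p in sorted(int(x) for x in picks):
            di, da, ai, aa = combos[p]
            bonds.append(make_bond(nodes[di], da, nodes[ai], aa))
    return build_table(bonds)
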