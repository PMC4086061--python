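"""Synthetic stand-in structures for well-known interaction motifs.

These are *constructed* fragments, not real PDB entries: each helper
builds a fixture spec whose bond network reproduces the topology of a
motif reported in real RNA structures, so the full pipeline can be
exercised without any downloads.  Geometry is idealized; only the bond
graph (and, where pinned, the specific atom pairs) mirrors the motif.
"""

from __future__ import annotations

from .fixtures import FixtureSpec, generate_fixture


def synthetic_triple_spec(seed: int = 0) -> FixtureSpec:
    """Synthetic A-A-U base triple with the tRNA A9.A23.U12 topology.

    Three bases numbered 9, 12 and 23 on chain A; four hydrogen bonds:
    two on the A23-U12 pair (A23 N6 -> U12 O4 and U12 N3 -> A23 N1,
    the reported atom pairs, pinned exactly) and two on the A9-A23 pair
    (a reverse-Hoogsteen-like N6/N7 arrangement; the motif's A-A atom
    pairs are not pinned by any published listing, so a chemically
    standard choice is used).
    """
    return FixtureSpec(
        bases=[("A", 9, "A"), ("A", 12, "U"), ("A", 23, "A")],
        intended_edges=[(1, 2, 2), (0, 2, 2)],
        pinned_bonds={
            (1, 2): [(2, "N6", 1, "O4"), (1, "N3", 2, "N1")],
            (0, 2): [(0, "N6", 2, "N7"), (2, "N6", 0, "N7")],
        },
        seed=seed,
    )


def synthetic_triple_pdb(seed: int = 0) -> str:
    return generate_fixture(synthetic_triple_spec(seed))


def synthetic_octuple_spec(seed: int = 0) -> FixtureSpec:
    """Synthetic octuple: two interconnected star quadruples.

    Reproduces the lysine-riboswitch observation of an all-guanine star
    quadruple and a 2xC + 2xU star quadruple joined by one bond into a
    single eight-base network: bases 10-16 form the G star (centre G10),
    bases 20-26 the pyrimidine star (centre U20), and one bridge bond
    links leaf G16 to leaf C22.
    """
    return FixtureSpec(
        bases=[
            ("A", 10, "G"), ("A", 12, "G"), ("A", 14, "G"), ("A", 16, "G"),
            ("A", 20, "U"), ("A", 22, "C"), ("A", 24, "C"), ("A", 26, "U"),
        ],
        intended_edges=[
            (0, 1, 1), (0, 2, 1), (0, 3, 1),   # GGGG star, centre G10
            (4, 5, 1), (4, 6, 1), (4, 7, 1),   # CCUU star, centre U20
            (3, 5, 1),                          # bridge -> octuple
        ],
        seed=seed,
    )


def synthetic_octuple_pdb(seed: int = 0) -> str:
    return generate_fixture(synthetic_octuple_spec(seed))
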