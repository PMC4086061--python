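"""Diff the hydrogen-bond networks of two closely related structures.

Builds two variants of a three-base chain -- variant B lacks one of the
two bonds present in variant A, as a mutation or ligand release might
cause -- and reports which bonds are unique to each side and which are
shared, at donor-atom/acceptor-atom resolution.
"""

from basenet import (FixtureSpec, build_table, compare_structures,
                     detect_hbonds, generate_fixture, parse_structure)

spec_a = FixtureSpec(
    bases=[("A", 1, "G"), ("A", 3, "C"), ("A", 5, "U")],
    intended_edges=[(0, 1, 1), (1, 2, 1)], seed=31,
    pinned_bonds={(0, 1): [(1, "N4", 0, "N7")],
                  (1, 2): [(2, "N3", 1, "O2")]})
spec_b = FixtureSpec(
    bases=[("A", 1, "G"), ("A", 3, "C"), ("A", 5, "U")],
    intended_edges=[(0, 1, 1)], seed=31,
    pinned_bonds={(0, 1): [(1, "N4", 0, "N7")]})


def table_of(spec):
    return build_table(detect_hbonds(parse_structure(generate_fixture(spec))))


diff = compare_structures(table_of(spec_a), table_of(spec_b))

print("bonds only in A (lost in B):")
for b in diff.only_a:
    print(f"  {b.donor_base.label} {b.donor_atom} -> "
          f"{b.acceptor_base.label} {b.acceptor_atom}  {b.da_distance:.2f} A")
print("bonds only in B (gained):", len(diff.only_b))
print("shared bonds:")
for ba, bb in diff.shared:
    print(f"  {ba.donor_base.label} {ba.donor_atom} -> "
          f"{ba.acceptor_base.label} {ba.acceptor_atom}  "
          f"{ba.da_distance:.2f} / {bb.da_distance:.2f} A")
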