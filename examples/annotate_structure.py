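"""Annotate the hydrogen-bond network of an RNA fragment.

Builds a small synthetic fragment (an A-minor-style A.A.U base triple),
detects all base-base hydrogen bonds with the default geometric criteria
(D-A distance <= 3.9 A, approach angles >= 90 deg), and prints the
connection table: one line per bonded base, one line per partner with
the bond count and the signed atom-pair codes.
"""

from basenet import build_table, detect_hbonds, parse_structure, write_table
from basenet.synthetic import synthetic_triple_pdb

structure = parse_structure(synthetic_triple_pdb(), source_id="triple")
bonds = detect_hbonds(structure)

print(f"{len(bonds)} hydrogen bonds detected:")
for b in bonds:
    print(f"  {b.donor_base.label:>4s} {b.donor_atom:<3s} -> "
          f"{b.acceptor_base.label:>4s} {b.acceptor_atom:<3s}  "
          f"{b.da_distance:.2f} A")

table = build_table(bonds)
print("\nConnection table (irn, base, author id, partner count; then")
print("partner irn, bond count, signed codes -- negative = partner donates):")
print(write_table(table))
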