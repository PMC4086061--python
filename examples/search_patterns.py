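"""Search a structure for tree-shaped base clusters.

Enumerates the free-tree query shapes (one shape for pairs and triples,
up to six for sextuples), then scans a synthetic eight-base network for
star quadruples: one base hydrogen-bonded to three others.  The fragment
contains two such quadruples -- an all-G one and a 2C+2U one -- joined
by a single bond, so the union report surfaces them as one octuple.
"""

from basenet import (build_table, detect_hbonds, enumerate_trees,
                     hit_unions, parse_structure, scan)
from basenet.synthetic import synthetic_octuple_pdb

for n in range(2, 7):
    trees = enumerate_trees(n)
    shapes = ", ".join(str(t.degree_sequence) for t in trees)
    print(f"{n} bases: {len(trees)} tree shape(s)  [{shapes}]")

table = build_table(detect_hbonds(parse_structure(synthetic_octuple_pdb())))
result = scan(table, sizes=(4,))

print("\nquadruple scan (all-wildcard, any bond count):")
all_hits = []
for tree, hits in result.hits.items():
    print(f"  {tree.name} {tree.degree_sequence}: {len(hits)} hit(s)")
    for h in hits:
        print(f"    {h.composition()}  bases "
              f"{sorted(b.res_seq for b in h.bases)}")
    all_hits.extend(hits)

for union in hit_unions(table, all_hits):
    print(f"\n{len(union['hits'])} hits interconnect into one "
          f"{union['size']}-base network (an octuple).")
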