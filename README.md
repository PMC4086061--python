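# basenet

Annotation and search of **hydrogen-bonded base interaction networks** in RNA
3D structures.

RNA tertiary structure is stabilized by clusters of nucleobases joined into
unbroken networks of base–base hydrogen bonds — base triples, quadruples, up
to sextuples and beyond. These clusters are candidate tertiary motifs, and
minute conformational changes (a mutation, ligand binding) show up as gained
or lost bonds at atomic resolution. `basenet` is a library and command-line
tool for RNA structural biologists that:

1. **detects base–base hydrogen bonds** in PDB structures from heavy-atom
   geometry: a donor atom D and acceptor atom A on distinct bases are bonded
   when *d*(D,A) ≤ 3.9 Å, ∠(DD–D–A) ≥ 90° and ∠(D–A–AA) ≥ 90°, where DD/AA
   are the covalently bonded antecedent atoms;
2. **builds connection tables**: per-structure graphs whose nodes are bonded
   bases (with internal residue numbers, IRN) and whose edges carry bond
   multiplicities and signed atom-pair codes — e.g. from U12's perspective
   `-1604 1311` reads "A23 N6 (1 = N) donates to U12 O4 (0 = O); U12 N3
   donates to A23 N1";
3. **searches** those graphs for tree-shaped base clusters by Ullmann
   subgraph matching with backtracking and compatibility-matrix refinement.
   Query nodes are base labels or wildcards; query edges are bond-count
   constraints (`any` ≥ 1, exact *k*, or ≥ *k*). The free trees on 2–6 nodes
   give 1, 1, 2, 3 and 6 query shapes. Matching uses monomorphism semantics
   (extra bonds among matched bases are allowed), and order-permuted matches
   of the same base set are collapsed to one hit;
4. **diffs** the bond networks of two closely related structures
   (mutant/wild-type, bound/unbound) into only-in-A / only-in-B / shared
   bond sets;
5. **generates synthetic fragments**: minimal PDB files whose idealized
   planar bases are rigidly placed so that a requested bond network — and
   only it — holds by construction, which makes the whole pipeline testable
   offline.

## Worked example

```sh
python examples/annotate_structure.py
```

builds a synthetic A·A·U base triple (bases A9, U12, A23 — the classic
tRNA triple topology) and prints:

```
4 hydrogen bonds detected:
    A9 N6  ->  A23 N7   2.90 A
   U12 N3  ->  A23 N1   2.96 A
   A23 N6  ->   A9 N7   2.90 A
   A23 N6  ->  U12 O4   2.85 A

# basenet connection table v1
1 A A.9 1
> 3 2 1617 -1617
2 U A.12 1
> 3 2 1311 -1604
3 A A.23 2
> 1 2 -1617 1617
> 2 2 -1311 1604
```

Base A23 (IRN 3) is connected to two other bases, A9 and U12, by two
hydrogen bonds each. On the U12 line, `1311` means U12 N3 donates to A23
N1, and `-1604` means the partner (A23) N6 donates to U12 O4. Searching
this table with the path-shaped triple query `A–A–U`, both edges exactly
2 bonds, returns exactly one hit covering {A9, U12, A23}.

`examples/search_patterns.py` scans an eight-base network containing two
interconnected star quadruples (GGGG and CCUU) and reports them as one
octuple; `examples/compare_structures.py` diffs two variants of a fragment
that differ by one bond.

## Command line

```sh
basenet patterns --n 2-6                # the enumerated query shapes
basenet hbonds structure.pdb            # bond list as TSV
basenet table structure.pdb [--json]    # connection table
basenet search structure.pdb --query q.yaml
basenet scan structure.pdb --sizes 2-6  # all shapes, wildcard queries
basenet diff a.pdb b.pdb                # bond-network difference
basenet fixture spec.yaml -o toy.pdb    # synthetic fragment
```

Multi-model (NMR) files: pick one model with `--model N`; hydrogens are
always stripped. Geometry thresholds and the modified-base donor/acceptor
library (pseudouridine and common methylated bases ship by default) are
overridable with `--config config.yaml`.

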