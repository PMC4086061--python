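# Methods

## Scope and model

`basenet` treats an RNA structure as a set of rigid nucleobases and asks a
purely graph-theoretic question: which bases are joined, directly or
transitively, by base–base hydrogen bonds? Everything downstream — the
connection table, the tree-pattern search, the two-structure diff — operates
on that graph. There is deliberately no geometric motif matching (no RMSD,
no base-pair edge/orientation classification à la Leontis–Westhof): two
clusters with the same bond graph are the same cluster here, whatever their
3D arrangement. That is what makes wildcard queries over clusters of four or
more bases tractable, where predicting 3D arrangements in advance is not.

## Hydrogen-bond criterion

All inputs are reduced to heavy atoms (hydrogens are stripped from every
structure, not only NMR models, so one criterion applies uniformly; crystal
structures rarely contain hydrogens anyway). A directed donor→acceptor pair
on two distinct bases is a bond when three conditions hold:

| parameter | default | meaning |
|---|---|---|
| `max_da_distance` | 3.9 Å | donor–acceptor distance cap |
| `min_ada_angle` | 90° | ∠(donor-antecedent, donor, acceptor) |
| `min_daa_angle` | 90° | ∠(donor, acceptor, acceptor-antecedent) |

The antecedent angles are a heavy-atom proxy for the usual D–H…A test:
without hydrogens, the direction of the covalent bond into the donor (and
into the acceptor) bounds where a hydrogen could plausibly sit. The 3.9 Å
cap is the widely used donor–acceptor cutoff of hydrogen-bond assignment
programs; all three thresholds are configurable, and every emitted bond
record carries its measured distance and both angles so the criterion is
auditable per bond.

Donor/acceptor inventories follow standard base chemistry: A — donor N6,
acceptors N1/N3/N7; G — donors N1/N2, acceptors O6/N3/N7; C — donor N4,
acceptors O2/N3; U — donor N3, acceptors O2/O4. Pseudouridine (PSU) gains
N1 as a donor (C-glycosidic isomer); common modified residues (1MA, 5MC,
7MG, 2MG, M2G, OMC, OMG, H2U, 5MU) map to parent-derived inventories with
the methylated position removed where methylation blocks it. Unknown
residues are skipped with a warning, never guessed. C–H…O interactions and
base–ribose/backbone bonds (including O2′) are out of scope: the base
moiety is ring + exocyclic substituents only.

Where a ring nitrogen has two ring neighbours, the lower-numbered carbon is
fixed as antecedent; the alternative choice rotates the reference by a few
degrees and does not change any default-threshold decision in practice.
Sequence-adjacent bases are *not* excluded. Both directions of an atom pair
are tested independently when both role assignments are chemically legal.

## Connection tables

Only bond-participating bases enter the table. IRNs are assigned 1-based in
structure (file) order over those bases; the author id (chain, residue
number, insertion code) is carried on every node, so outputs remain
unambiguous under any renumbering convention. Edge codes pack
(donor element, donor position, acceptor element, acceptor position) into a
signed four-digit token, negative when the partner base donates; atoms with
two-digit positions or elements outside {N, O} fall back to an explicit
`N10>O4`-style token. The text serialization round-trips the graph exactly
(nodes, multiplicities, codes); coordinates and distances live in the JSON
twin.

## Pattern enumeration and search

Query shapes are the free trees on 2–6 nodes (1, 1, 2, 3, 6 shapes; the
enumerator accepts larger n — 11 shapes for n = 7). Trees are grown by leaf
extension and deduplicated with an AHU canonical string rooted at the tree
centroid; type ordinals follow the lexicographic order of those strings.
Because ordinal numbering conventions vary between tools, every report
prints the degree sequence next to the ordinal so shapes can be
cross-identified (the star quadruple is the one with degree sequence
(3,1,1,1) — one base bonded to three others).

Matching is Ullmann-style: a compatibility matrix over (query node, table
node) pairs is pruned to a fixpoint — a pair survives only if every query
neighbour can still map to some table neighbour through an edge satisfying
its bond-count constraint — followed by depth-first assignment in
most-constrained-first order with ascending-IRN tie-breaks, which makes
output order deterministic. Semantics are subgraph monomorphism: extra
bonds among matched bases are allowed. This is a deliberate choice — two
quadruples joined by a bridge bond must each still be found inside the
octuple they form — and an `induced` flag provides the stricter mode.
A specified edge count means exactly that count; `>=k` and `any` (≥ 1) are
the relaxed modes.

Raw matches of a symmetric query are permutations of one another (a star
with three wildcard leaves matches 3! = 6 ways); the redundancy filter
keeps one hit per distinct base set, with the lexicographically smallest
assignment as representative and the collapsed multiplicity recorded.
Overlapping hits across patterns are kept, and a union report flags
connected components of the table spanned by more than one hit — that is
how interconnected clusters (octuples) surface.

## Two-structure comparison

Residues correspond when their author ids match exactly (the intended use
is pairs of very similar structures); an explicit residue map supports
renumbered pairs, and alignment-based mapping is out of scope. Bonds are
compared as (donor residue, donor atom, acceptor residue, acceptor atom)
tuples. Bonds touching residues present in only one structure are counted
in that structure's unique set *and* the residues are listed separately, so
`only_a ∪ shared = bonds(A)` holds exactly. Both tables should be built
with identical thresholds; the diff does not re-detect.

## Synthetic fragment generator

The generator emulates exactly one thing: small RNA fragments whose
base-base hydrogen-bond network is known by construction. Bases are
idealized planar templates (regular hexagon rings with 1.375 Å sides, fused
regular pentagon for purines, exocyclic O at 1.23 Å / N at 1.34 Å), all
placed in one plane. Placement walks a spanning order of the requested bond
forest; each new base is fitted by a three-parameter in-plane rigid
least-squares problem (rotation + translation) whose residuals pull
intended donor–acceptor pairs to 2.9 Å (± configurable jitter) with
approach angles steered toward ≥ 120°, and push everything else apart:
chemically legal unintended donor→acceptor combos past the detection cutoff
(4.9 Å against non-bonded partners, past 3.9 Å with margin on the bonded
interface), all other cross-base atoms past a 3.3 Å steric floor. Both
faces of the planar base are tried (template mirroring), because multi-bond
interfaces often admit only one chirality. A fit is accepted only after
re-verification: intended bonds must hold with margin (distance within the
detection window, angles ≥ 108°), and every unintended legal combo must
robustly fail the criteria. Atom usage is bookkept: ring N–H donors donate
once, exocyclic amino nitrogens (N6/N2/N4) twice, acceptors accept twice,
and no atom serves both roles — so unrealizable requests (five bonds from a
uridine, cyclic bond graphs) fail with an explicit infeasibility error
rather than producing a wrong fragment.

Three numerical concessions are documented rather than hidden: (i) on
multi-bond interfaces the rigid templates cannot hit 2.9 Å on every bond
simultaneously, so the accepted window widens to ± 0.45 Å there (still far
inside the 3.9 Å cutoff); (ii) accepted approach angles may relax to 108°
(detection requires only 90°); (iii) chemically *illegal* atom pairs (two
acceptors sharing a donor, as in any planar triple) are only held to the
steric floor, since they cannot register as bonds under any threshold. A
solver-invocation budget bounds the backtracking search; a spec that
exhausts it is reported infeasible. `random_spec` draws
inventory-feasible random specs (2–5 bases, bond counts 1–2);
`random_fixture` additionally redraws the small fraction that is
geometrically unrealizable, so property tests always consume realized
fragments.

What passing the round-trip property (detect ∘ parse ∘ generate = intended
network) shows: the detection geometry, PDB I/O, and graph construction are
mutually consistent on clean, planar, noise-free input. What it does not
show: behaviour on real structures — puckered and propeller-twisted bases,
coordinate error, crystallographic disorder, backbone context — where the
thresholds, not the bookkeeping, decide the outcome.

## Structure input

PDB parsing is delegated to gemmi. One model is kept (`MODEL` number for
multi-model files); alternate locations resolve to the highest-occupancy
conformer, ties to altloc `A` then lexicographic — a determinism policy,
not a claim about disorder. DNA residues are excluded by default behind a
flag. Inter-chain interactions are included: all retained chains enter one
graph. Parsing is deterministic; byte-identical input yields identical
structures.

## Known limitations

- Bond detection is geometric only: no energies, no water mediation, no
  bifurcation modelling beyond what the thresholds admit.
- The IRN values of any other tool's table output will differ; the author
  ids, not the IRNs, are the stable cross-reference.
- Type ordinals for tree shapes are internally consistent but not aligned
  with any external numbering; use the printed degree sequences.
- The search cost grows with table size and pattern size; refinement keeps
  typical structures (hundreds of bases) fast, but all-wildcard sextuple
  scans of ribosome-scale tables are not the design point.
- The synthetic generator produces chemically sensible but physically
  unrefined coordinates (no backbone, single plane); it is a testing
  instrument, not a modelling tool.

## Problem sizes in the shipped tests

The test suite and the acceptance script size their random batches to keep
a full run in the low minutes on one core: matcher-vs-oracle agreement on
60–200 random tables of ≤ 10 nodes, fixture round trips on 60–100 random
specs of 2–5 bases, diff identities on a handful of fragments. All are
driven by a single seed argument and scale up by changing one number.
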