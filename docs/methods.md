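# Methods

This note documents the models, rules and numerical choices behind
`silmotif`, and what the synthetic generators do and do not emulate.

## Loop extraction and topology

Transmembrane segment (TMS) boundaries are *inputs*: four 1-based
inclusive `(start, end)` pairs per sequence, supplied as a TSV sidecar and
validated for order, disjointness and bounds. The small intracellular
loop (SIL) is the slice strictly between TMS2 and TMS3; the cytosolic
N-terminal segment is everything before TMS1 plus the first five TMS1
residues, so the juxtamembrane basic residue is retained even when a
topology model places it just inside the membrane. An empty loop
(adjacent TMSs) is legal and logged, not an error.

## Anchored alignment

Short loops (6–21 residues in the human family) are too divergent for a
profile alignment to be meaningful; instead each loop is aligned on one
anchor residue found by a priority rule:

1. the most N-terminal acidic residue (Glu or Asp, no preference between
   the two) — this residue becomes **core position 2**;
2. failing that, the most N-terminal basic residue (Lys or Arg) — **core
   position 1**.

For N-terminal segments the rule is the most C-terminal Lys/Arg. Loops
matching neither class stay unanchored: they are excluded (and logged)
unless a manual offset gives the 1-based loop position to place at core
position 1 — the programmatic equivalent of aligning a divergent family
member by overall similarity. Rows are gap-padded left so the core
columns coincide and right to a rectangle; a loop ending before position 5
simply carries gaps there, and an acidic anchor on a loop's first residue
leaves a gap at position 1 (the alignment keeps a leading column so
position 1 always exists). Row order never influences gapping or
consensus (property-tested).

## Consensus statistic

Column frequencies are counts over the 20 canonical residues divided by
the number of non-gap, non-`X` observations, so each defined column's
frequencies sum to 1. A residue is consensus when *f* ≥ *f*<sub>mean</sub> + SD.
Both moments are taken over the full 20-residue frequency vector with
zeros included and population normalization (divide by 20), which makes
*f*<sub>mean</sub> exactly 0.05; this choice yields one consensus letter
for near-pure columns and 2–3 letters for mixed ones, matching how the
statistic behaves on real tetraspanin loop columns. An alternative
`observed` mode restricts both moments to residues actually present
(configurable, `consensus_denominator`). The comparison is inclusive with
a 1e−12 roundoff guard so exact ties qualify — a perfectly uniform column
(SD = 0) returns all residues present, which is the statistic's honest
answer, not a bug. Consensus sets are ordered by descending frequency,
ties alphabetical, and rendered bare (`E`) or bracketed (`[R/K]`); an
all-gap column renders a middle dot.

## Dihedrals and Ramachandran classes

Torsions follow the IUPAC sign convention (validated against Biopython's
`calc_dihedral`), reported in (−180°, 180°]. φ(i) uses C(i−1)–N(i)–CA(i)–C(i),
ψ(i) uses N(i)–CA(i)–C(i)–N(i+1); either is undefined at termini, at
incomplete residues, and across chain breaks (consecutive Cα–Cα distance
> 4.5 Å or missing backbone atoms). Undefined angles classify as OTHER
and break helix runs and motif windows.

Classification uses axis-aligned rectangles in (φ, ψ) space with half-open
upper edges (an upper edge of exactly 180° is inclusive, since angles live
in (−180, 180]):

| class | φ | ψ |
|---|---|---|
| α<sub>R</sub> | [−160, −20) | [−120, 50) |
| β | [−180, −20) | [50, 180] ∪ [−180, −150) |
| α<sub>L</sub> | [20, 160) | [−60, 90) |

Everything else is OTHER. The rectangles are pairwise disjoint and the
map is total (property-tested); they are deliberately coarse — broad
basins rather than tight favored regions — because the detector needs
robust class membership, not outlier flagging. All boundaries are
overridable via the flat key=value config file.

## M-motif detection

A hit is a 5-residue window classified
α<sub>R</sub>–α<sub>L</sub>–β–α<sub>R</sub>–α<sub>R</sub> with at least
`flank_min = 3` consecutive α<sub>R</sub> residues immediately before
position 1 and after position 5. The flank requirement plus the in-window
α<sub>R</sub> positions approximates "helical arms continuing into the
membrane helices" without demanding full TMS-length helices, which
resolved structures with disordered ends would fail. Helices elsewhere
are reported as maximal α<sub>R</sub> runs of ≥ `min_run = 4`.

Each hit carries the planarity RMS: the root-mean-square orthogonal
distance of the window's 15 backbone N/CA/C atoms to their least-squares
plane (centroid + smallest singular direction). Planarity is **reported,
not filtered**, by default — co-planarity is a qualitative feature of the
turn and no printed threshold exists; with the default turn dihedrals the
ideal hairpin measures 0.51 Å, so `max_planarity ≈ 1 Å` is a reasonable
opt-in filter for idealized geometry. An optional antiparallel filter
requires the angle between flanking helix axes (principal CA directions,
N→C oriented) to be ≥ `axis_min_angle = 120°`; it is off by default
because the class pattern plus flanks already defines the motif.

## Contact screening

Salt bridges use minimum heavy-atom distance between charged groups:
{Lys NZ; Arg NE, NH1, NH2} × {Glu OE1, OE2; Asp OD1, OD2}, inclusive
4.0 Å cutoff, hydrogens ignored. Histidine is excluded from the basic set
by default (its protonation is ambiguous at cytosolic pH and only Lys/Arg
matter for the juxtamembrane interaction). Polar mode screens side-chain
O/N atoms against backbone N/O at 3.5 Å. Distances are symmetric in the
pair order; explicitly requested pairs are always reported with their
distance, whether or not they pass the cutoff. Reports use author residue
numbering with insertion codes (`K11`, `E84`) and print distances at
0.1 Å, matching the precision such distances are conventionally quoted at.

## Synthetic generators

`build_backbone` places N/CA/C/O sequentially from internal coordinates
(bond lengths N–CA 1.458, CA–C 1.525, C–N 1.329, C=O 1.231 Å; angles
N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°; ω default 180°) in a
canonical start frame. Any self-consistent constant set would do, since
all structural tests are round trips against the package's own reader;
these are the conventional ideal-geometry averages. Carbonyl oxygens are
placed trans to the next amide nitrogen. The builder is exact: measured
dihedrals recover inputs to ≪ 1e−6° and an independent rotation-matrix
kinematics oracle agrees to 1e−6 Å.

`make_m_hairpin` joins two ideal helices (φ, ψ = −57°, −47°) by a turn
whose default per-position dihedrals — (−57, −47), (60, 45), (−120, 130),
(−57, −47), (−57, −47) — are centroids of the default Ramachandran
rectangles, so the planted window classifies correctly under any sane
region configuration. Optional Gaussian dihedral jitter (default 0°)
supports robustness testing.

`make_sil_family` samples a 5-position core from per-position frequency
tables inside uncharged random flanks (total loop length 6–21), embedded
in a full dummy four-TMS sequence so records exercise the complete
extraction → anchoring → consensus path. Flanks are drawn from the
uncharged alphabet *by design*: the planted core charges must remain the
loop's most N-terminal anchor candidates, mirroring real SILs where the
charged residues cluster in the core. Default core tables emulate the
human composition (R/K, then E with a small D minority, N/S, K/R/Q, C).

Two **synthetic stand-ins** reconstruct the published tetraspanin loop
geometry in idealized form (they are labelled synthetic and are *not* the
experimental structures): `make_synthetic_cd9` plants a QESQC turn at
author numbers 83–87 with a lone K11 whose NZ sits exactly 2.8 Å from the
nearest E84 carboxylate oxygen; `make_synthetic_cd53` plants KENKS at
76–80 (the crystallographic Cys→Ser exchange) with K7 and K10 at 5.1 and
5.2 Å from E77. Side chains are built with ideal internal coordinates and
the lysines are rigidly placed along directions that guarantee the
NZ-to-carboxylate minimum equals the planted distance. What passing tests
on these stand-ins shows: the detector, classifier and distance screen
recover planted ground truth through the full file-format path. What they
do not show: robustness to experimental coordinate error, alternate
conformations beyond the altloc policy, or real side-chain rotamer
diversity. `make_anchor_census_family` likewise plants the 33-member
anchoring composition (23 Glu / 2 Asp anchors, 8 loops without acids, 13
Arg / 11 Lys at position 1, one rule-less row aligned by manual offset) so
the census arithmetic is exercised end to end.

All generators are deterministic: one seed, byte-identical output.

## Problem sizes

The test suite and acceptance script use 100 random torsion lists,
200 + 200 structures for recall/precision, 1,000 random columns for the
consensus oracle, 100 seeds for the binomial-recovery check and 50
families for planted-core recovery — sizes at which every stochastic
check is decisively stable while the whole suite stays fast.

## Known limitations

- TMS boundaries are trusted inputs; no topology prediction is attempted,
  and anchoring tallies on real families inherit any boundary error.
- The Ramachandran rectangles are coarse by intent; borderline residues
  near region edges can flip class under small coordinate noise.
- The helix-axis antiparallel filter uses a principal-component axis,
  which is biased for very short or strongly curved arms.
- Salt-bridge screening is purely geometric: no electrostatics, no
  protonation states, no solvent.
- The synthetic stand-ins encode idealized geometry; numbers measured on
  them validate the pipeline's arithmetic, not the experimental
  structures themselves.
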