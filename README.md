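# silmotif

Sequence and structure analysis of the tetraspanin **small intracellular
loop** (SIL) — the short cytosolic linker between transmembrane segments 2
and 3 — and of the **M-shaped inter-helix turn** that its conserved
five-residue core adopts.

Tetraspanins are four-pass membrane proteins (33 members in human) whose
SIL carries a conserved core with the chemical signature
*basic – acidic – polar – basic – polar* (human consensus
`[R/K] E [N/S] [R/K/Q] C`). In crystal structures the core backbone traces
a flat letter "M" between the two flanking transmembrane helices, with a
characteristic dihedral signature — right-handed helix (α<sub>R</sub>) at
positions 1, 4, 5, a left-handed residue (α<sub>L</sub>) at position 2 and
a β-strand residue at position 3 — and the position-2 glutamate can form a
salt bridge with a juxtamembrane lysine of the N-terminus. This package
implements that whole analysis as a reusable, offline-testable pipeline:

- **Loop extraction & anchored alignment** — SILs are cut out of
  topology-annotated sequences (TMS boundaries are inputs, as a TSV
  sidecar) and aligned on a single anchor: the most N-terminal Glu/Asp
  (core position 2), falling back to the most N-terminal Lys/Arg (core
  position 1); rows matching neither rule are excluded or placed by an
  explicit manual offset.
- **Consensus calling** — per-column residue frequencies *f* over the 20
  canonical residues (gaps and `X` excluded); a residue is consensus when
  *f* ≥ *f*<sub>mean</sub> + SD (inclusive), rendered as a bracketed
  abundance-ordered string such as `[R/K] E [N/S] [R/K] C`.
- **Backbone geometry** — φ/ψ dihedrals (IUPAC sign convention, undefined
  across chain breaks), rectangle-based Ramachandran classification
  (α<sub>R</sub> / α<sub>L</sub> / β / other), helix-run assignment,
  least-squares plane fitting (RMS orthogonal distance via SVD), and
  ideal-helical-wheel angular separations.
- **M-motif detection** — every 5-residue window with the
  α<sub>R</sub>–α<sub>L</sub>–β–α<sub>R</sub>–α<sub>R</sub> class pattern
  and ≥ 3 consecutive α<sub>R</sub> residues on both flanks, reported with
  the planarity RMS of its 15 backbone N/CA/C atoms and the flanking helix
  extents; optional antiparallel-axis filter.
- **Contact screening** — minimum heavy-atom distances between charged
  side-chain groups (Lys NZ, Arg NE/NH1/NH2 vs Glu OE1/OE2, Asp OD1/OD2)
  with the inclusive 4.0 Å salt-bridge criterion, plus a polar
  side-chain-to-backbone mode (3.5 Å default).
- **Synthetic generators** — a torsion-to-Cartesian backbone builder
  (NeRF-style), helix–turn–helix hairpins with a planted turn, loop
  families with planted per-position core frequencies, exact-distance
  salt-bridge fixtures, and idealized CD9-/CD53-like stand-in structures,
  all byte-reproducible under a seed.

Structures are read and written with [gemmi](https://gemmi.readthedocs.io)
(PDB and mmCIF, first model, highest-occupancy altlocs), sequences with
Biopython.

## Worked example

```python
from silmotif import (FamilySpec, align_loops, consensus_string,
                      extract_sil, find_m_motifs, make_m_hairpin,
                      make_sil_family)

# a 33-member loop family with a planted core, as FASTA-ready records
family = make_sil_family(FamilySpec(n_sequences=33, seed=7))
loops = {r.id: extract_sil(r) for r in family.records}
print(consensus_string(align_loops(loops)))
# [R/K] E [N/S] [R/K] C

# a synthetic hairpin with the turn planted at residues 16-20
chain, planted = make_m_hairpin(n1=15, n2=15)
hit = find_m_motifs(chain)[0]
print(hit.residues[0], hit.sequence, round(hit.planarity_rms, 2))
# A16 AAAAA 0.51
```

The consensus string lists, per core position, every residue whose column
frequency reaches the mean plus one standard deviation, most abundant
first. The motif hit reports where the turn starts, its five residues and
the RMS deviation (Å) of its backbone atoms from their best-fit plane —
0.51 Å here, i.e. an essentially flat "M".

The same analyses are available from the shell:

```bash
silmotif simulate-seqs --n 33 --seed 7 --out fam/
silmotif sil-align --fasta fam/family.fasta --topology fam/topology.tsv --out aln/
silmotif simulate-structure --n1 15 --n2 15 --out hairpin.pdb
silmotif motif-scan --structure hairpin.pdb --out scan/
silmotif saltbridge --structure mystruct.pdb --pairs K11:E84
```

See `examples/` for short narrative scripts covering each capability.

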