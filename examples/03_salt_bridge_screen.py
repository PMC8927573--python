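"""Salt-bridge screening on the synthetic tetraspanin stand-ins.

The CD9-like stand-in plants a lysine (K11) 2.8 A from the turn
glutamate's carboxylate - a salt bridge under the 4 A criterion.  The
CD53-like stand-in plants its two lysines at 5.1 and 5.2 A - about one
angstrom too far.  Both are idealized reconstructions of the published
geometry, not experimental structures.
"""

from silmotif import contact_scan, find_m_motifs, make_synthetic_cd9, make_synthetic_cd53

cd9 = make_synthetic_cd9()
hit = find_m_motifs(cd9)[0]
print(f"CD9-like stand-in: turn {hit.sequence} at {hit.residues[0]}..{hit.residues[4]}")
for rec in contact_scan(cd9, pairs=[("K11", "E84")]):
    verdict = "salt bridge" if rec.is_salt_bridge else "no bridge"
    print(f"  {rec.donor}({rec.donor_atom})-{rec.acceptor}({rec.acceptor_atom}): "
          f"{rec.distance:.1f} A -> {verdict}")

cd53 = make_synthetic_cd53()
print("CD53-like stand-in:")
for rec in contact_scan(cd53, pairs=[("K7", "E77"), ("K10", "E77")]):
    verdict = "salt bridge" if rec.is_salt_bridge else "no bridge"
    print(f"  {rec.donor}-{rec.acceptor}: {rec.distance:.1f} A -> {verdict}")
# Distances are minimum heavy-atom separations between the charged groups
# (Lys NZ vs Glu OE1/OE2); the 4.0 A cutoff is inclusive.
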