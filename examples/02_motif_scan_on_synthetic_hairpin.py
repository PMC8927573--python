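"""Detecting the M-shaped inter-helix turn in a synthetic hairpin.

Builds two antiparallel alpha-helices joined by a 5-residue turn with the
alphaR-alphaL-beta-alphaR-alphaR dihedral signature, then runs the
detector and prints the hit with its backbone planarity.
"""

from silmotif import find_m_motifs, make_m_hairpin, phi_psi

chain, planted = make_m_hairpin(n1=15, n2=15)
print(f"built {len(chain)} residues; turn planted at indices {planted[0]}..{planted[1]}")

for hit in find_m_motifs(chain):
    print(f"hit at residues {hit.residues[0]}..{hit.residues[4]}: "
          f"classes {'-'.join(c.value for c in hit.classes)}")
    print(f"  planarity RMS {hit.planarity_rms:.2f} A over the 15 backbone atoms")
    print(f"  helical arms: {hit.upstream_helix} and {hit.downstream_helix}")
# The planarity RMS is the root-mean-square orthogonal distance of the
# window's N/CA/C atoms to their least-squares plane: the smaller it is,
# the more faithfully the backbone traces a flat letter M.

angles = [(d.phi, d.psi) for d in phi_psi(chain)[planted[0]:planted[1] + 1]]
print("turn (phi, psi):", [(round(p, 1), round(s, 1)) for p, s in angles])
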