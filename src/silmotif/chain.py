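"""In-memory backbone representation shared by the geometry operations.

Residues keep author numbering (with insertion codes) and a dictionary of
heavy-atom coordinates in Angstrom.  Only N/CA/C/O are required for
backbone analyses; side-chain atoms, when present, feed the contact screen.
Incomplete residues are flagged, never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class Residue:
    """One residue: author number + insertion code, 3-letter name, atoms."""

    number: int
    name: str
    atoms: dict[str, np.ndarray]
    icode: str = ""

    @property
    def complete(self) -> bool:
        """True when all four backbone atoms are present."""
        return all(a in self.atoms for a in BACKBONE_ATOMS)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    @property
    def label(self) -> str:
        """Compact author-numbered label such as ``E84`` or ``K11A``."""
        return f"{self.one_letter}{self.number}{self.icode}"

    def __getitem__(self, atom: str) -> np.ndarray:
        return self.atoms[atom]


@dataclass
class BackboneChain:
    """Ordered residues of one chain, in source order."""

    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i: int) -> Residue:
        return self.residues[i]

    def __iter__(self):
        return iter(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def find(self, label: str) -> Residue:
        """Look up a residue by author-numbered label (e.g. ``K11``).

        The one-letter code in the label is checked against the residue name.
        """
        matches = [r for r in self.residues if r.label == label.upper()]
        if not matches:
            raise InputError(
                f"chain {self.chain_id}: no residue {label!r}; "
                f"labels run {self.residues[0].label}..{self.residues[-1].label}"
                if self.residues else f"chain {self.chain_id} is empty"
            )
        return matches[0]
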