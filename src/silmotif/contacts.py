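"""Salt-bridge and polar-contact screening.

A salt bridge is operationalized as a minimum heavy-atom distance of at
most 4.0 A (inclusive) between the charged side-chain groups of a basic
residue (Lys NZ; Arg NE/NH1/NH2) and an acidic residue (Glu OE1/OE2;
Asp OD1/OD2).  Histidine is excluded from the basic set by default.  The
polar-contact mode screens side-chain O/N atoms against backbone N/O with
a 3.5 A default cutoff.  Hydrogens are never considered.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .chain import BackboneChain, Residue
from .errors import InputError

logger = logging.getLogger(__name__)

SALT_BRIDGE_CUTOFF = 4.0
POLAR_CONTACT_CUTOFF = 3.5

#: Charged side-chain atom sets, by 3-letter residue name.
BASIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}
ACIDIC_ATOMS = {"GLU": ("OE1", "OE2"), "ASP": ("OD1", "OD2")}

_BACKBONE_POLAR = ("N", "O")


@dataclass(frozen=True)
class ContactRecord:
    """Minimum-distance contact between two residues' atom groups."""

    donor: str            # residue label, e.g. K11
    donor_atom: str       # atom of the minimum-distance pair
    acceptor: str
    acceptor_atom: str
    distance: float       # A
    is_salt_bridge: bool


def _min_distance(res_a: Residue, atoms_a, res_b: Residue, atoms_b):
    best = None
    for na, nb in itertools.product(atoms_a, atoms_b):
        if na not in res_a.atoms or nb not in res_b.atoms:
            continue
        d = float(np.linalg.norm(res_a[na] - res_b[nb]))
        if best is None or d < best[0]:
            best = (d, na, nb)
    return best


def _sidechain_polar_atoms(res: Residue):
    return tuple(
        a for a in res.atoms
        if a not in ("N", "O", "C", "CA", "OXT") and a[0] in ("N", "O")
    )


def contact_scan(
    chains: BackboneChain | list[BackboneChain],
    mode: str = "saltbridge",
    pairs: list[tuple[str, str]] | None = None,
    cutoff: float | None = None,
) -> list[ContactRecord]:
    """Screen residue pairs for charged or polar contacts.

    Parameters
    ----------
    chains
        One chain or a list of chains; all residues are pooled.
    mode
        ``"saltbridge"``: basic side-chain N atoms vs acidic side-chain O
        atoms, inclusive cutoff 4.0 A; the record's ``is_salt_bridge`` flag
        reflects the cutoff, but *all* screened pairs with both groups
        present are reported when explicitly requested via `pairs`.
        ``"polar"``: side-chain O/N vs backbone N/O, default cutoff 3.5 A.
    pairs
        Optional explicit residue label pairs (e.g. ``[("K11", "E84")]``);
        when given, exactly those pairs are measured (order donor, acceptor).
        Without it, every basic x acidic (or side-chain x backbone) pair
        within the cutoff is reported.
    cutoff
        Override the mode's default cutoff (A).

    Residues missing the screened atoms are skipped with a warning.
    """
    if isinstance(chains, BackboneChain):
        chains = [chains]
    if mode not in ("saltbridge", "polar"):
        raise InputError(f"unknown contact mode {mode!r}")
    cutoff = cutoff if cutoff is not None else (
        SALT_BRIDGE_CUTOFF if mode == "saltbridge" else POLAR_CONTACT_CUTOFF
    )
    residues = [r for ch in chains for r in ch.residues]
    by_label = {}
    for r in residues:
        by_label.setdefault(r.label, r)

    def atoms_for(res: Residue, side: str):
        if mode == "saltbridge":
            table = BASIC_ATOMS if side == "donor" else ACIDIC_ATOMS
            return table.get(res.name, ())
        return _sidechain_polar_atoms(res) if side == "donor" else _BACKBONE_POLAR

    records: list[ContactRecord] = []

    def measure(res_a: Residue, res_b: Residue, always: bool) -> None:
        atoms_a = atoms_for(res_a, "donor")
        atoms_b = atoms_for(res_b, "acceptor")
        if not atoms_a or not atoms_b:
            logger.warning(
                "pair %s-%s skipped: no screened atoms (%s/%s)",
                res_a.label, res_b.label, res_a.name, res_b.name,
            )
            return
        best = _min_distance(res_a, atoms_a, res_b, atoms_b)
        if best is None:
            logger.warning(
                "pair %s-%s skipped: screened atoms missing from structure",
                res_a.label, res_b.label,
            )
            return
        d, na, nb = best
        if always or d <= cutoff:
            records.append(
                ContactRecord(
                    donor=res_a.label, donor_atom=na,
                    acceptor=res_b.label, acceptor_atom=nb,
                    distance=d,
                    is_salt_bridge=(mode == "saltbridge" and d <= cutoff),
                )
            )

    if pairs is not None:
        for lab_a, lab_b in pairs:
            for lab in (lab_a, lab_b):
                if lab.upper() not in by_label:
                    raise InputError(f"residue {lab!r} not found in the supplied chains")
            measure(by_label[lab_a.upper()], by_label[lab_b.upper()], always=True)
    else:
        if mode == "saltbridge":
            donors = [r for r in residues if r.name in BASIC_ATOMS]
            acceptors = [r for r in residues if r.name in ACIDIC_ATOMS]
        else:
            donors = [r for r in residues if _sidechain_polar_atoms(r)]
            acceptors = residues
        for res_a in donors:
            for res_b in acceptors:
                if res_a is res_b:
                    continue
                measure(res_a, res_b, always=False)
    return records
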