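"""Readers and writers for the standard formats the pipeline touches.

Sequences travel as FASTA plus a TSV topology sidecar (columns ``id``,
``tms1_start`` .. ``tms4_end``, 1-based inclusive).  Structures are PDB or
mmCIF via gemmi, first model only, with alternate conformations resolved to
the highest-occupancy altloc (ties broken alphabetically).  Reports are
diffable TSV/JSON with distances at 0.1 A and angles at 0.1 degree.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .anchoring import CoreAlignment
from .chain import BackboneChain, Residue
from .errors import InputError
from .records import SequenceRecord

logger = logging.getLogger(__name__)

TOPOLOGY_COLUMNS = ["id"] + [
    f"tms{k}_{edge}" for k in range(1, 5) for edge in ("start", "end")
]


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA into (id, uppercase sequence) pairs, preserving order.

    Lowercase letters are uppercased (logged); duplicate ids and empty
    files are hard errors.
    """
    entries: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if seq != seq.upper():
            logger.info("%s: lowercase residues uppercased", rec.id)
            seq = seq.upper()
        if rec.id in seen:
            raise InputError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        entries.append((rec.id, seq))
    if not entries:
        raise InputError(f"no FASTA records in {path}")
    return entries


def write_fasta(entries: Iterable[tuple[str, str]], path, width: int = 60) -> None:
    records = [
        BioSeqRecord(Seq(seq), id=rid, description="") for rid, seq in entries
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_topology(path) -> dict[str, tuple[tuple[int, int], ...]]:
    """Read the TMS boundary sidecar TSV into ``id -> four (start, end)``."""
    df = pd.read_csv(path, sep="\t")
    missing = set(TOPOLOGY_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"topology table {path} lacks columns {sorted(missing)}")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise InputError(f"duplicate topology ids {dupes}")
    out = {}
    for _, row in df.iterrows():
        out[str(row["id"])] = tuple(
            (int(row[f"tms{k}_start"]), int(row[f"tms{k}_end"])) for k in range(1, 5)
        )
    return out


def write_topology(records: Sequence[SequenceRecord], path) -> None:
    rows = []
    for rec in records:
        row = {"id": rec.id}
        for k, (start, end) in enumerate(rec.tms, start=1):
            row[f"tms{k}_start"] = start
            row[f"tms{k}_end"] = end
        rows.append(row)
    pd.DataFrame(rows, columns=TOPOLOGY_COLUMNS).to_csv(path, sep="\t", index=False)


def load_records(fasta_path, topology_path) -> list[SequenceRecord]:
    """Join FASTA with its topology sidecar into validated records.

    Every FASTA record must have a topology row; extra topology rows are
    ignored with a log message.
    """
    topology = read_topology(topology_path)
    records = []
    for rid, seq in read_fasta(fasta_path):
        if rid not in topology:
            raise InputError(f"record {rid!r} missing from topology table")
        records.append(SequenceRecord(id=rid, sequence=seq, tms=topology[rid]))
    unused = set(topology) - {r.id for r in records}
    if unused:
        logger.info("topology rows without FASTA records ignored: %s", sorted(unused))
    return records


def write_alignment_fasta(alignment: CoreAlignment, path) -> None:
    """Write the gap-padded alignment rows as gapped FASTA ('-' gaps)."""
    write_fasta(alignment.rows, path)


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------


def _pick_altlocs(residue: gemmi.Residue) -> dict[str, gemmi.Atom]:
    """Resolve alternate conformations: highest occupancy, ties by altloc."""
    chosen: dict[str, gemmi.Atom] = {}
    for atom in residue:
        if atom.is_hydrogen():
            continue
        prev = chosen.get(atom.name)
        if prev is None:
            chosen[atom.name] = atom
            continue
        if (atom.occ, _altloc_rank(atom)) > (prev.occ, _altloc_rank(prev)):
            chosen[atom.name] = atom
    return chosen


def _altloc_rank(atom: gemmi.Atom) -> float:
    # later in the alphabet ranks lower; blank altloc ranks highest
    return -ord(atom.altloc) if atom.altloc else 0.0


def read_structure(path, chain: str | None = None) -> BackboneChain:
    """Read one chain of a PDB/mmCIF file into a :class:`BackboneChain`.

    Format is sniffed by gemmi (extension, then content).  Only the first
    model is used.  With ``chain=None`` a single-chain file is accepted;
    otherwise the author chain ID must be given.  A missing chain raises an
    error listing what is available.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise InputError(f"{path}: no models")
    model = st[0]
    names = [ch.name for ch in model]
    if chain is None:
        if len(names) != 1:
            raise InputError(f"{path}: specify a chain; available: {names}")
        chain = names[0]
    if chain not in names:
        raise InputError(f"{path}: no chain {chain!r}; available: {names}")
    gch = model[chain]
    residues = []
    for gres in gch:
        if gres.is_water():
            continue
        atoms = {
            name: np.array([a.pos.x, a.pos.y, a.pos.z])
            for name, a in _pick_altlocs(gres).items()
        }
        if not atoms:
            continue
        icode = gres.seqid.icode.strip()
        res = Residue(number=gres.seqid.num, name=gres.name, atoms=atoms, icode=icode)
        if not res.complete:
            logger.warning(
                "chain %s residue %s%s (%s): incomplete backbone",
                chain, gres.seqid.num, icode, gres.name,
            )
        residues.append(res)
    return BackboneChain(chain_id=chain, residues=residues)


def write_pdb(chain: BackboneChain, path) -> None:
    """Write one chain as a single-model PDB file (ATOM records only)."""
    st = gemmi.Structure()
    st.name = "silmotif"
    model = gemmi.Model(1)
    gch = gemmi.Chain(chain.chain_id)
    serial = 1
    for res in chain:
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
        for name, xyz in res.atoms.items():
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(name[:1])
            atom.pos = gemmi.Position(*[round(float(v), 3) for v in xyz])
            atom.occ = 1.0
            atom.b_iso = 0.0
            atom.serial = serial
            serial += 1
            gres.add_atom(atom)
        gch.add_residue(gres)
    model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    doc_path = str(path)
    st.write_pdb(doc_path)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

#: Fixed formatting per report field: distances/planarity to 0.1 A, angles
#: to 0.1 degree, frequencies to 4 decimals.
_FORMATS = {
    "distance": "{:.1f}",
    "planarity_rms": "{:.2f}",
    "phi": "{:.1f}",
    "psi": "{:.1f}",
    "threshold": "{:.4f}",
    "frequency": "{:.4f}",
    "angle": "{:.1f}",
}


def _round_value(key: str, value):
    if isinstance(value, float):
        fmt = _FORMATS.get(key)
        return float(fmt.format(value)) if fmt else value
    return value


def write_report(rows: Sequence[Mapping], path, fmt: str = "tsv",
                 columns: Sequence[str] | None = None) -> None:
    """Write analysis rows as TSV or JSON with stable column order and fixed
    float precision.  An empty result set yields a header-only TSV (pass
    `columns` for the schema) or an empty JSON list."""
    path = Path(path)
    rows = [
        {k: _round_value(k, v) for k, v in row.items()} for row in rows
    ]
    if fmt == "tsv":
        if columns is None:
            columns = list(rows[0].keys()) if rows else []
        df = pd.DataFrame(rows, columns=columns)
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        path.write_text(json.dumps(rows, indent=2) + "\n")
    else:
        raise InputError(f"unknown report format {fmt!r}")
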