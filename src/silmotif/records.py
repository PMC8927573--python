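"""Topology-annotated protein sequences and loop extraction.

A tetraspanin carries four transmembrane segments (TMS1-TMS4).  Both the
small intracellular loop (SIL, the linker between TMS2 and TMS3) and the
cytosolic N-terminal segment are defined purely by the TMS boundary
annotations, which are *inputs* here (1-based, inclusive), typically derived
upstream with a topology predictor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import TopologyError

logger = logging.getLogger(__name__)

#: The 20 canonical one-letter residue codes, alphabetical.
CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

_ALLOWED = set(CANONICAL_RESIDUES) | {"X"}

#: Number of TMS1 residues appended to the cytosolic N-terminal segment, so
#: that the juxtamembrane basic residue is retained even when the topology
#: places it just inside the membrane.
NTERM_TMS1_OVERHANG = 5


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence with four ordered TMS intervals.

    Parameters
    ----------
    id : str
        Unique identifier (FASTA header word).
    species : str
        Free-text organism tag; empty string if unknown.
    sequence : str
        Uppercase one-letter residue codes; the 20 canonical codes plus
        ``X`` for unknown residues.
    tms : tuple of (int, int)
        Four ``(start, end)`` pairs, 1-based inclusive, ordered TMS1-TMS4,
        pairwise disjoint and strictly increasing along the sequence.
    """

    id: str
    sequence: str
    tms: tuple[tuple[int, int], ...]
    species: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence
        bad = set(seq) - _ALLOWED
        if bad:
            raise TopologyError(
                f"{self.id}: non-canonical residue codes {sorted(bad)}"
            )
        if len(self.tms) != 4:
            raise TopologyError(f"{self.id}: expected 4 TMS intervals, got {len(self.tms)}")
        prev_end = 0
        for k, (start, end) in enumerate(self.tms, start=1):
            if not (1 <= start <= end <= len(seq)):
                raise TopologyError(
                    f"{self.id}: TMS{k} ({start},{end}) outside sequence of length {len(seq)}"
                )
            if start <= prev_end:
                raise TopologyError(
                    f"{self.id}: TMS{k} ({start},{end}) overlaps or is out of order "
                    f"with the previous segment ending at {prev_end}"
                )
            prev_end = end

    def __len__(self) -> int:
        return len(self.sequence)


def extract_sil(record: SequenceRecord) -> str:
    """Return the small intracellular loop: residues between TMS2 and TMS3.

    The slice is ``end(TMS2)+1 .. start(TMS3)-1`` (1-based inclusive) and may
    be empty when the two segments are adjacent (a warning is logged).
    """
    _, (_, tms2_end), (tms3_start, _), _ = record.tms
    loop = record.sequence[tms2_end : tms3_start - 1]
    if not loop:
        logger.warning("%s: TMS2 and TMS3 are adjacent; SIL is empty", record.id)
    return loop


def extract_nterm(record: SequenceRecord, overhang: int = NTERM_TMS1_OVERHANG) -> str:
    """Return the cytosolic N-terminal segment plus the first `overhang`
    residues of TMS1."""
    (tms1_start, tms1_end), *_ = record.tms
    stop = min(tms1_start - 1 + overhang, tms1_end)
    return record.sequence[:stop]
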