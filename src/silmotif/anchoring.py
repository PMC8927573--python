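"""Anchored alignment of short loops.

Instead of a general multiple-sequence alignment, short cytosolic loops are
aligned on a single anchor residue chosen by a priority rule over residue
classes.  For the small intracellular loop the rule is: the most N-terminal
acidic residue (Glu or Asp, no preference between the two) defines core
position 2; failing that, the most N-terminal basic residue (Lys or Arg)
defines core position 1.  For the N-terminal segment the rule is the most
C-terminal basic residue.  Loops matching neither class stay unanchored and
are either excluded or placed by an explicit manual offset (the equivalent of
aligning a divergent family member by overall similarity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import InputError
from .records import SequenceRecord, extract_sil

logger = logging.getLogger(__name__)

GAP = "-"

#: Sentinel for loops where no residue class of the rule matches.
UNANCHORED = None


@dataclass(frozen=True)
class AnchorRule:
    """Priority-ordered residue classes scanned along a loop.

    ``residue_classes`` are tried in order; within a class the first hit in
    ``scan_direction`` wins.  ``core_positions`` gives, per class, the core
    position (1-based) assigned to the anchor residue.
    """

    scan_direction: str  # "N-to-C" | "C-to-N"
    residue_classes: tuple[frozenset[str], ...]
    core_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.scan_direction not in ("N-to-C", "C-to-N"):
            raise InputError(f"bad scan direction {self.scan_direction!r}")
        if len(self.residue_classes) != len(self.core_positions):
            raise InputError("one core position is required per residue class")
        for cls in self.residue_classes:
            if not cls:
                raise InputError("empty residue class in anchor rule")


#: SIL rule: most N-terminal acidic residue -> core position 2; fallback
#: most N-terminal basic residue -> core position 1.
SIL_RULE = AnchorRule(
    scan_direction="N-to-C",
    residue_classes=(frozenset("ED"), frozenset("KR")),
    core_positions=(2, 1),
)

#: N-terminus rule: most C-terminal basic residue; the anchor is core
#: position 1 of the juxtamembrane alignment frame.
NTERM_RULE = AnchorRule(
    scan_direction="C-to-N",
    residue_classes=(frozenset("KR"),),
    core_positions=(1,),
)


@dataclass(frozen=True)
class AnchorAssignment:
    """Outcome of applying an :class:`AnchorRule` to one loop."""

    record_id: str
    anchor_index: int | None  # 1-based within the loop; None == unanchored
    matched_class: frozenset[str] | None
    core_position_of_anchor: int | None

    @property
    def anchored(self) -> bool:
        return self.anchor_index is not None


def anchor_loop(loop: str, rule: AnchorRule, record_id: str = "") -> AnchorAssignment:
    """Locate the anchor residue of `loop` under `rule`.

    Returns an assignment with ``anchor_index=None`` when no residue class
    matches; that is a valid outcome, not an error.
    """
    if not loop:
        raise InputError(f"{record_id or 'loop'}: cannot anchor an empty loop")
    indices = range(len(loop)) if rule.scan_direction == "N-to-C" else range(len(loop) - 1, -1, -1)
    for cls, core_pos in zip(rule.residue_classes, rule.core_positions):
        for i in indices:
            if loop[i] in cls:
                return AnchorAssignment(record_id, i + 1, cls, core_pos)
    return AnchorAssignment(record_id, UNANCHORED, None, None)


@dataclass(frozen=True)
class CoreAlignment:
    """Gap-padded loop rows sharing a common core frame.

    ``core_columns`` are the five 0-based column indices mapped to core
    positions 1-5.  ``anchor_column`` is the column of core position 2 (the
    acidic-anchor column under the SIL rule).
    """

    rows: tuple[tuple[str, str], ...]  # (record_id, gapped residue string)
    anchor_column: int
    core_columns: tuple[int, int, int, int, int]

    @property
    def width(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    def column(self, col: int) -> list[str]:
        """Residues (including gaps) of one column, in row order."""
        if not 0 <= col < self.width:
            raise InputError(f"column {col} outside alignment of width {self.width}")
        return [row[col] for _, row in self.rows]

    def row(self, record_id: str) -> str:
        for rid, row in self.rows:
            if rid == record_id:
                return row
        raise InputError(f"no row with id {record_id!r}")


def align_loops(
    loops: Mapping[str, str] | Sequence[SequenceRecord],
    rule: AnchorRule = SIL_RULE,
    manual_offsets: Mapping[str, int] | None = None,
) -> CoreAlignment:
    """Build the anchored core alignment of a loop family.

    Parameters
    ----------
    loops
        Either a mapping ``record_id -> loop string`` or a sequence of
        :class:`SequenceRecord` (their SILs are extracted first).
    rule
        Anchor rule; default is the SIL rule.
    manual_offsets
        For unanchored rows only: ``record_id -> 1-based loop position``
        that should occupy core position 1.  Unanchored rows without a
        manual offset are excluded (and logged).

    Rows are padded with gaps on the left so that core positions line up
    across rows, and on the right to a rectangular shape.  A row whose loop
    ends before column 5 simply carries gaps there; an acidic anchor sitting
    at the very first loop residue leaves a gap at core position 1.
    """
    if not isinstance(loops, Mapping):
        loops = {rec.id: extract_sil(rec) for rec in loops}
    manual_offsets = dict(manual_offsets or {})
    if not loops:
        raise InputError("no loops to align")

    # 0-based loop index that occupies core position 1; may be -1 when the
    # acidic anchor is the loop's first residue (gap at position 1).
    core1_index: dict[str, int] = {}
    for rid, loop in loops.items():
        asg = anchor_loop(loop, rule, rid)
        if asg.anchored:
            core1_index[rid] = (asg.anchor_index - 1) - (asg.core_position_of_anchor - 1)
        elif rid in manual_offsets:
            off = manual_offsets[rid]
            if not 1 <= off <= len(loop):
                raise InputError(
                    f"{rid}: manual anchor offset {off} outside loop of length {len(loop)}"
                )
            core1_index[rid] = off - 1
        else:
            logger.warning("%s: unanchored and no manual offset; excluded from alignment", rid)
    if not core1_index:
        raise InputError("every row is unanchored; supply manual offsets")

    # clamp at 0: when every anchor sits on its loop's first residue, core
    # position 1 still gets a (all-gap) leading column
    core1_col = max(0, max(core1_index.values()))
    width = max(
        core1_col + len(loops[rid]) - core1_index[rid] for rid in core1_index
    )
    width = max(width, core1_col + 5)  # room for core positions 1-5

    rows = []
    for rid, loop in loops.items():
        if rid not in core1_index:
            continue
        left = core1_col - core1_index[rid]
        padded = GAP * left + loop
        rows.append((rid, padded + GAP * (width - len(padded))))

    core_columns = tuple(core1_col + k for k in range(5))
    return CoreAlignment(rows=tuple(rows), anchor_column=core1_col + 1, core_columns=core_columns)
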