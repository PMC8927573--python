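"""Detection of the M-shaped five-residue inter-helix turn.

The motif is a 5-residue window whose Ramachandran classes read
(alphaR, alphaL, beta, alphaR, alphaR) — right-handed helix at positions
1, 4, 5, a left-handed residue at position 2 initiating the turn, and a
beta-strand residue at position 3 bridging it — flanked on both sides by
runs of right-handed-helical residues (the helical arms).  The 15 backbone
N/CA/C atoms of the window are nearly co-planar; the RMS deviation from the
best-fit plane is reported with every hit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .chain import BackboneChain
from .geometry import (
    DihedralRecord,
    RamaClass,
    assign_helices,
    classify_chain,
    helix_axis,
    phi_psi,
    plane_fit_rms,
)

#: The dihedral-class signature of the turn, positions 1-5.
M_PATTERN = (
    RamaClass.ALPHA_R,
    RamaClass.ALPHA_L,
    RamaClass.BETA,
    RamaClass.ALPHA_R,
    RamaClass.ALPHA_R,
)


@dataclass(frozen=True)
class MotifConfig:
    """Tunable knobs of the scan.

    flank_min
        Minimum number of consecutive alphaR residues required immediately
        before position 1 and immediately after position 5.
    min_run
        Minimum alphaR run length reported as a helix.
    antiparallel_filter / axis_min_angle
        When the filter is on, the angle between the flanking helix axis
        vectors must be at least `axis_min_angle` degrees (180 = perfectly
        antiparallel).  Off by default: the class pattern plus flanks is the
        defining criterion, axis geometry is a refinement.
    max_planarity
        Optional cutoff (A) on the backbone planarity RMS; ``None`` reports
        planarity without filtering.
    """

    flank_min: int = 3
    min_run: int = 4
    antiparallel_filter: bool = False
    axis_min_angle: float = 120.0
    max_planarity: float | None = None
    rama_regions: dict | None = None
    break_distance: float = 4.5


@dataclass(frozen=True)
class MMotifHit:
    """One detected turn: window indices, classes, planarity, helical arms."""

    chain_id: str
    start: int                      # 0-based index of position 1
    residues: tuple[str, ...]       # author-numbered labels, positions 1-5
    sequence: str                   # one-letter codes of the window
    classes: tuple[RamaClass, ...]
    planarity_rms: float            # A, over the 15 window N/CA/C atoms
    upstream_helix: tuple[int, int]    # 0-based inclusive residue index range
    downstream_helix: tuple[int, int]


def _flank_run(classes: list[RamaClass], start: int, step: int) -> int:
    """Length of the alphaR run walking from `start` in direction `step`."""
    n = 0
    i = start
    while 0 <= i < len(classes) and classes[i] is RamaClass.ALPHA_R:
        n += 1
        i += step
    return n


def find_m_motifs(
    chain: BackboneChain,
    config: MotifConfig = MotifConfig(),
    dihedrals: list[DihedralRecord] | None = None,
) -> list[MMotifHit]:
    """Scan one chain for M-shaped inter-helix turns.

    Every 5-residue window matching the class signature with sufficiently
    long helical flanks yields a hit carrying the planarity RMS of its 15
    backbone atoms.  A chain too short for window plus flanks returns an
    empty list.
    """
    if dihedrals is None:
        dihedrals = phi_psi(chain, config.break_distance)
    classes = classify_chain(dihedrals, config.rama_regions)
    n = len(classes)
    hits: list[MMotifHit] = []
    for start in range(n - 4):
        window = tuple(classes[start : start + 5])
        if window != M_PATTERN:
            continue
        up = _flank_run(classes, start - 1, -1)
        down = _flank_run(classes, start + 5, +1)
        if up < config.flank_min or down < config.flank_min:
            continue
        upstream = (start - up, start - 1)
        downstream = (start + 5, start + 4 + down)
        if config.antiparallel_filter:
            a1 = helix_axis(chain, *upstream)
            a2 = helix_axis(chain, *downstream)
            angle = math.degrees(math.acos(np.clip(np.dot(a1, a2), -1.0, 1.0)))
            if angle < config.axis_min_angle:
                continue
        atoms = []
        for i in range(start, start + 5):
            res = chain[i]
            atoms.extend(res[a] for a in ("N", "CA", "C"))
        rms = plane_fit_rms(atoms)
        if config.max_planarity is not None and rms > config.max_planarity:
            continue
        hits.append(
            MMotifHit(
                chain_id=chain.chain_id,
                start=start,
                residues=tuple(chain[i].label for i in range(start, start + 5)),
                sequence="".join(chain[i].one_letter for i in range(start, start + 5)),
                classes=window,
                planarity_rms=rms,
                upstream_helix=upstream,
                downstream_helix=downstream,
            )
        )
    return hits
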