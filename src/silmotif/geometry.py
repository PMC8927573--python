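"""Backbone dihedrals, Ramachandran classification, helices, planarity.

The dihedral sign follows the IUPAC convention (right-handed positive,
looking from the second to the third atom), with angles reported in degrees
in (-180, 180].  phi(i) is defined by C(i-1)-N(i)-CA(i)-C(i) and psi(i) by
N(i)-CA(i)-C(i)-N(i+1); either is undefined at chain termini, at missing
backbone atoms, and across chain breaks (consecutive CA-CA distance above a
cutoff, default 4.5 A).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .chain import BackboneChain, Residue
from .errors import GeometryError

#: CA(i)-CA(i+1) distance (A) above which the chain is considered broken.
BREAK_DISTANCE = 4.5

_EPS = 1e-10


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle (degrees) of four points, IUPAC sign convention.

    Raises :class:`GeometryError` when a consecutive triple is collinear or
    a bond vector vanishes.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    if np.linalg.norm(b2) < _EPS:
        raise GeometryError("central bond has zero length")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _EPS or np.linalg.norm(n2) < _EPS:
        raise GeometryError("collinear points leave the torsion undefined")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    angle = -math.degrees(math.atan2(np.dot(m1, n2), np.dot(n1, n2)))
    return 180.0 if angle <= -180.0 + 1e-12 else angle


@dataclass(frozen=True)
class DihedralRecord:
    """phi/psi of one residue; ``None`` marks an undefined angle."""

    residue: Residue
    phi: float | None
    psi: float | None

    @property
    def defined(self) -> bool:
        return self.phi is not None and self.psi is not None


def _connected(a: Residue, b: Residue, break_distance: float) -> bool:
    if "CA" not in a.atoms or "CA" not in b.atoms:
        return False
    return float(np.linalg.norm(a["CA"] - b["CA"])) <= break_distance


def phi_psi(chain: BackboneChain, break_distance: float = BREAK_DISTANCE) -> list[DihedralRecord]:
    """Backbone dihedrals for every residue of `chain`.

    Termini, incomplete residues and residues adjacent to a chain break get
    ``None`` for the affected angle.
    """
    out: list[DihedralRecord] = []
    n = len(chain)
    for i, res in enumerate(chain):
        phi = psi = None
        if res.complete:
            prev = chain[i - 1] if i > 0 else None
            nxt = chain[i + 1] if i < n - 1 else None
            if prev is not None and "C" in prev.atoms and _connected(prev, res, break_distance):
                phi = dihedral(prev["C"], res["N"], res["CA"], res["C"])
            if nxt is not None and "N" in nxt.atoms and _connected(res, nxt, break_distance):
                psi = dihedral(res["N"], res["CA"], res["C"], nxt["N"])
        out.append(DihedralRecord(residue=res, phi=phi, psi=psi))
    return out


class RamaClass(enum.Enum):
    """Coarse Ramachandran region of a (phi, psi) pair."""

    ALPHA_R = "alphaR"
    ALPHA_L = "alphaL"
    BETA = "beta"
    OTHER = "other"


#: Default region rectangles as (phi_min, phi_max, psi_min, psi_max) with
#: half-open upper edges, except that an upper edge of exactly 180 is
#: inclusive (angles live in (-180, 180]).  The rectangles are pairwise
#: disjoint; everything else is OTHER.
DEFAULT_RAMA_REGIONS: dict[RamaClass, tuple[tuple[float, float, float, float], ...]] = {
    RamaClass.ALPHA_R: ((-160.0, -20.0, -120.0, 50.0),),
    RamaClass.BETA: ((-180.0, -20.0, 50.0, 180.0), (-180.0, -20.0, -180.0, -150.0)),
    RamaClass.ALPHA_L: ((20.0, 160.0, -60.0, 90.0),),
}


def _in_interval(x: float, lo: float, hi: float) -> bool:
    if hi >= 180.0:
        return lo <= x <= 180.0
    return lo <= x < hi


def classify_rama(
    phi: float | None,
    psi: float | None,
    regions: dict[RamaClass, tuple[tuple[float, float, float, float], ...]] | None = None,
) -> RamaClass:
    """Map one (phi, psi) pair to its Ramachandran class; undefined -> OTHER."""
    if phi is None or psi is None:
        return RamaClass.OTHER
    regions = regions if regions is not None else DEFAULT_RAMA_REGIONS
    for cls, rects in regions.items():
        for (phi_lo, phi_hi, psi_lo, psi_hi) in rects:
            if _in_interval(phi, phi_lo, phi_hi) and _in_interval(psi, psi_lo, psi_hi):
                return cls
    return RamaClass.OTHER


def classify_chain(
    dihedrals: list[DihedralRecord],
    regions: dict[RamaClass, tuple[tuple[float, float, float, float], ...]] | None = None,
) -> list[RamaClass]:
    return [classify_rama(d.phi, d.psi, regions) for d in dihedrals]


def assign_helices(
    classes: list[RamaClass],
    min_run: int = 4,
) -> list[tuple[int, int]]:
    """Maximal runs of >= `min_run` consecutive ALPHA_R residues.

    Returns 0-based inclusive (start, end) index pairs into the dihedral list.
    """
    runs: list[tuple[int, int]] = []
    start = None
    for i, cls in enumerate(classes + [RamaClass.OTHER]):  # sentinel flush
        if cls is RamaClass.ALPHA_R:
            if start is None:
                start = i
        elif start is not None:
            if i - start >= min_run:
                runs.append((start, i - 1))
            start = None
    return runs


def plane_fit_rms(points) -> float:
    """RMS orthogonal distance (A) of points to their least-squares plane.

    The plane passes through the centroid with normal along the smallest
    singular direction.  Requires >= 3 non-collinear points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise GeometryError("plane fit needs at least 3 points in 3D")
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-9:  # rank < 2: points are collinear or coincident
        raise GeometryError("collinear points do not define a plane")
    return float(s[2] / math.sqrt(pts.shape[0]))


def helix_axis(chain: BackboneChain, start: int, end: int) -> np.ndarray:
    """Unit axis (N->C oriented) of the helix spanning residues start..end
    (0-based inclusive), from the principal direction of the CA cloud."""
    cas = np.array([chain[i]["CA"] for i in range(start, end + 1) if "CA" in chain[i].atoms])
    if len(cas) < 2:
        raise GeometryError("helix axis needs at least two CA atoms")
    centered = cas - cas.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    axis = vt[0]
    if np.dot(axis, cas[-1] - cas[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def wheel_separation(i: int, j: int, degrees_per_residue: float = 100.0) -> float:
    """Helical-wheel angle (degrees in [0, 360)) between residues i and j of
    one ideal helix at `degrees_per_residue` per step."""
    return (abs(j - i) * degrees_per_residue) % 360.0
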