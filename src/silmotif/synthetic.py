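"""Ground-truth generators: backbones from torsions, hairpins with a planted
turn, loop families with a planted core, and contact fixtures.

Everything here is deterministic under a fixed seed and emits objects (or
standard files) that are valid inputs to the rest of the package, so every
pipeline stage can be tested without downloads.  The ``make_synthetic_cd9``
/ ``make_synthetic_cd53`` builders are *synthetic stand-ins*: idealized
reconstructions that plant the published tetraspanin loop geometry (a QESQC
or KENKS turn between two antiparallel helices, with juxtamembrane lysines
placed at specified carboxylate distances); they are not the experimental
structures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .chain import BackboneChain, ONE_TO_THREE, Residue
from .errors import GeometryError, InputError
from .records import CANONICAL_RESIDUES, SequenceRecord

# ---------------------------------------------------------------------------
# internal-coordinate backbone construction (NeRF-style)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BackboneGeometry:
    """Standard peptide bond lengths (A) and angles (degrees).

    Any self-consistent set works for round-trip testing; these are the
    conventional averages used by ideal-geometry model builders.
    """

    n_ca: float = 1.458
    ca_c: float = 1.525
    c_n: float = 1.329
    c_o: float = 1.231
    ang_n_ca_c: float = 111.2
    ang_ca_c_n: float = 116.2
    ang_c_n_ca: float = 121.7
    ang_ca_c_o: float = 120.5
    omega: float = 180.0

    def __post_init__(self) -> None:
        for L in (self.n_ca, self.ca_c, self.c_n, self.c_o):
            if L <= 0:
                raise GeometryError(f"non-physical bond length {L}")
        for a in (self.ang_n_ca_c, self.ang_ca_c_n, self.ang_c_n_ca, self.ang_ca_c_o):
            if not 0.0 < a < 180.0:
                raise GeometryError(f"non-physical bond angle {a}")


DEFAULT_GEOMETRY = BackboneGeometry()

#: Ideal right-handed alpha-helix torsions.
ALPHA_TORSION = (-57.0, -47.0, 180.0)

#: Default per-position (phi, psi) of the planted 5-residue turn: the
#: centroids of the default Ramachandran rectangles realising the
#: alphaR-alphaL-beta-alphaR-alphaR signature.
DEFAULT_TURN_DIHEDRALS = (
    (-57.0, -47.0),
    (60.0, 45.0),
    (-120.0, 130.0),
    (-57.0, -47.0),
    (-57.0, -47.0),
)


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom D bonded to C given bond length C-D, angle B-C-D and
    torsion A-B-C-D (natural extension reference frame)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    nbc = np.linalg.norm(bc)
    if nbc < 1e-10:
        raise GeometryError("coincident frame atoms")
    bc /= nbc
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise GeometryError("collinear frame atoms")
    n /= nn
    m = np.cross(n, bc)
    theta = math.radians(angle_deg)
    chi = math.radians(torsion_deg)
    d_local = bond * np.array(
        [-math.cos(theta), math.sin(theta) * math.cos(chi), math.sin(theta) * math.sin(chi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(
    torsions,
    geometry: BackboneGeometry = DEFAULT_GEOMETRY,
    sequence: str | None = None,
    chain_id: str = "A",
    start_number: int = 1,
) -> BackboneChain:
    """Construct N/CA/C/O coordinates from per-residue (phi, psi, omega).

    `torsions` is a list of ``(phi, psi, omega)`` triples, one per residue
    (degrees); phi of the first residue and psi/omega of the last do not
    influence the backbone but the last psi orients its carbonyl oxygen.
    The first residue is placed in a canonical frame (N at the origin, CA on
    +x, C in the xy plane), so equal torsion lists give identical chains.
    """
    torsions = [tuple(map(float, t)) for t in torsions]
    if len(torsions) < 2:
        raise InputError("a backbone needs at least 2 residues")
    if sequence is not None and len(sequence) != len(torsions):
        raise InputError("sequence length must match the torsion list")

    g = geometry
    theta = math.radians(g.ang_n_ca_c)
    n1 = np.zeros(3)
    ca1 = np.array([g.n_ca, 0.0, 0.0])
    c1 = ca1 + g.ca_c * np.array([-math.cos(theta), math.sin(theta), 0.0])

    coords = [{"N": n1, "CA": ca1, "C": c1}]
    for i in range(1, len(torsions)):
        _, psi_prev, omega_prev = torsions[i - 1]
        phi_i = torsions[i][0]
        prev = coords[-1]
        n_i = place_atom(prev["N"], prev["CA"], prev["C"], g.c_n, g.ang_ca_c_n, psi_prev)
        ca_i = place_atom(prev["CA"], prev["C"], n_i, g.n_ca, g.ang_c_n_ca, omega_prev)
        c_i = place_atom(prev["C"], n_i, ca_i, g.ca_c, g.ang_n_ca_c, phi_i)
        coords.append({"N": n_i, "CA": ca_i, "C": c_i})

    # Carbonyl oxygens: trans to the next amide nitrogen, i.e. torsion
    # N-CA-C-O = psi + 180 for every residue (the last one uses its own psi).
    for i, atoms in enumerate(coords):
        psi_i = torsions[i][1]
        atoms["O"] = place_atom(
            atoms["N"], atoms["CA"], atoms["C"], g.c_o, g.ang_ca_c_o, psi_i + 180.0
        )

    residues = []
    for i, atoms in enumerate(coords):
        name = ONE_TO_THREE.get(sequence[i], "ALA") if sequence else "ALA"
        residues.append(Residue(number=start_number + i, name=name, atoms=atoms))
    return BackboneChain(chain_id=chain_id, residues=residues)


# ---------------------------------------------------------------------------
# helix-turn-helix hairpin with a planted M-turn
# ---------------------------------------------------------------------------


def make_m_hairpin(
    n1: int = 15,
    n2: int = 15,
    turn_dihedrals=DEFAULT_TURN_DIHEDRALS,
    seed: int | None = None,
    jitter_deg: float = 0.0,
    sequence: str | None = None,
    geometry: BackboneGeometry = DEFAULT_GEOMETRY,
    start_number: int = 1,
    chain_id: str = "A",
) -> tuple[BackboneChain, tuple[int, int]]:
    """Two helices joined by a 5-residue turn with planted dihedrals.

    Returns the chain and the planted window as 0-based inclusive residue
    indices ``(start, end)`` of the five turn residues.  `jitter_deg` adds
    Gaussian noise (SD in degrees) to every phi/psi for robustness testing;
    the default 0 gives exact planted angles.  ``n1 = 0`` is allowed and
    yields a turn without an upstream helical arm (hence undetectable).
    """
    if len(turn_dihedrals) != 5:
        raise InputError("the turn takes exactly 5 (phi, psi) pairs")
    if n1 < 0 or n2 < 0 or n1 + n2 < 2:
        raise InputError("helix arms too short to build a chain")
    torsions = (
        [ALPHA_TORSION] * n1
        + [(phi, psi, geometry.omega) for phi, psi in turn_dihedrals]
        + [ALPHA_TORSION] * n2
    )
    if jitter_deg > 0.0:
        rng = np.random.default_rng(seed)
        torsions = [
            (phi + rng.normal(0.0, jitter_deg), psi + rng.normal(0.0, jitter_deg), omega)
            for phi, psi, omega in torsions
        ]
    chain = build_backbone(
        torsions, geometry, sequence=sequence, chain_id=chain_id, start_number=start_number
    )
    return chain, (n1, n1 + 4)


# ---------------------------------------------------------------------------
# synthetic loop families with a planted core
# ---------------------------------------------------------------------------

#: Residues used for synthetic flanks/background: uncharged, so that planted
#: core charges remain the loop's most terminal anchor candidates, mirroring
#: real SILs where the charged residues cluster in the core.
UNCHARGED_RESIDUES = tuple(aa for aa in CANONICAL_RESIDUES if aa not in "DEKRH")

#: Hydrophobic alphabet used to synthesize dummy TMS segments.
_TMS_ALPHABET = "AILMFVW"
_TMS_LEN = 21

#: Default per-position core residue frequencies, emulating the composition
#: of the human SIL core (basic - Glu - polar - basic/polar - Cys) with
#: realistic minority residues; the remainder of each distribution is spread
#: over uncharged background residues.
DEFAULT_CORE_TABLES = (
    {"R": 0.40, "K": 0.33},
    {"E": 0.70, "D": 0.06},
    {"N": 0.45, "S": 0.25},
    {"K": 0.30, "R": 0.25, "Q": 0.15},
    {"C": 0.70},
)


@dataclass(frozen=True)
class FamilySpec:
    """Recipe for a synthetic loop family.

    core
        Five per-position residue->probability tables; probabilities may sum
        to less than 1, the remainder is spread uniformly over the uncharged
        background alphabet.
    loop_length_range
        Inclusive total loop length bounds (default 6-21, the span observed
        for the human family).
    """

    n_sequences: int = 33
    core: tuple = DEFAULT_CORE_TABLES
    loop_length_range: tuple[int, int] = (6, 21)
    background: tuple = UNCHARGED_RESIDUES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise InputError("n_sequences must be >= 1")
        if len(self.core) != 5:
            raise InputError("the core takes exactly 5 position tables")
        lo, hi = self.loop_length_range
        if not 5 <= lo <= hi:
            raise InputError("loop length range must admit the 5-residue core")
        for table in self.core:
            total = sum(table.values())
            if total > 1.0 + 1e-9 or any(p < 0 for p in table.values()):
                raise InputError(f"core table probabilities invalid: {table}")


@dataclass(frozen=True)
class SilFamily:
    """A generated family: records plus the planted ground truth."""

    records: tuple[SequenceRecord, ...]
    cores: dict[str, str]          # record_id -> planted 5-residue core
    core_start: dict[str, int]     # record_id -> 1-based core start within the loop
    loops: dict[str, str]          # record_id -> full loop string


def _sample_position(rng: np.random.Generator, table: dict, background) -> str:
    residues = list(table)
    probs = [table[aa] for aa in residues]
    rest = 1.0 - sum(probs)
    if rest > 1e-12:
        residues += list(background)
        probs += [rest / len(background)] * len(background)
    return rng.choice(residues, p=np.array(probs) / sum(probs))


def _random_string(rng: np.random.Generator, alphabet, n: int) -> str:
    return "".join(rng.choice(list(alphabet)) for _ in range(n))


def make_sil_family(spec: FamilySpec) -> SilFamily:
    """Generate a family of topology-annotated sequences with a planted
    5-residue loop core.

    Each loop is random uncharged flanks around a core sampled from the
    per-position tables, embedded in a full-length dummy sequence with four
    hydrophobic TMS segments, so the records exercise the complete
    extraction -> anchoring -> consensus pipeline.  Reproducible: one seed,
    identical records.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.loop_length_range
    records, cores, core_start, loops = [], {}, {}, {}
    for k in range(spec.n_sequences):
        total = int(rng.integers(lo, hi + 1))
        left = int(rng.integers(0, total - 5 + 1))
        right = total - 5 - left
        core = "".join(_sample_position(rng, t, spec.background) for t in spec.core)
        loop = _random_string(rng, spec.background, left) + core + _random_string(
            rng, spec.background, right
        )
        rid = f"syn{k + 1:03d}"
        rec = _embed_loop(rng, rid, loop)
        records.append(rec)
        cores[rid] = core
        core_start[rid] = left + 1
        loops[rid] = loop
    return SilFamily(tuple(records), cores, core_start, loops)


def _embed_loop(rng: np.random.Generator, rid: str, loop: str) -> SequenceRecord:
    """Wrap a loop in a four-TMS dummy topology (loop sits between TMS2/3)."""
    nterm = _random_string(rng, UNCHARGED_RESIDUES, 8)
    tms = [_random_string(rng, _TMS_ALPHABET, _TMS_LEN) for _ in range(4)]
    sel = _random_string(rng, UNCHARGED_RESIDUES, 4)   # TMS1-TMS2 linker
    lel = _random_string(rng, UNCHARGED_RESIDUES, 30)  # TMS3-TMS4 linker
    cterm = _random_string(rng, UNCHARGED_RESIDUES, 6)
    seq = nterm + tms[0] + sel + tms[1] + loop + tms[2] + lel + tms[3] + cterm
    pos = len(nterm)
    bounds = []
    for segment, gap in zip(tms, (len(sel), len(loop), len(lel), 0)):
        bounds.append((pos + 1, pos + _TMS_LEN))
        pos += _TMS_LEN + gap
    return SequenceRecord(id=rid, sequence=seq, tms=tuple(bounds), species="synthetic")


def make_anchor_census_family(seed: int = 0) -> tuple[SilFamily, dict[str, int]]:
    """Synthetic stand-in for the 33-member human SIL census.

    Plants the published anchoring composition exactly: 23 loops whose most
    N-terminal acidic residue is a glutamate and 2 an aspartate; 8 loops
    without any E/D, of which 7 anchor on a basic residue and 1 (the
    Tspan31-like row) has no charged residue at all and needs a manual
    offset; 13 arginines and 11 lysines at core position 1 overall.  Flanks
    are uncharged so the planted residues are the anchors.  Returns the
    family and the manual offsets for the unanchored row.
    """
    rng = np.random.default_rng(seed)
    # (position-1 residue or None for background, position-2 anchor or None)
    rows: list[tuple[str | None, str | None]] = []
    rows += [("R", "E")] * 9 + [("K", "E")] * 8 + [(None, "E")] * 6   # 23 Glu anchors
    rows += [(None, "D")] * 2                                          # 2 Asp anchors
    rows += [("R", None)] * 4 + [("K", None)] * 3                      # 7 basic-anchored
    rows += [(None, None)]                                             # Tspan31-like
    assert len(rows) == 33

    records, cores, core_start, loops, manual = [], {}, {}, {}, {}
    for k, (pos1, pos2) in enumerate(rows):
        p1 = pos1 if pos1 else _random_string(rng, UNCHARGED_RESIDUES, 1)
        p2 = pos2 if pos2 else _random_string(rng, UNCHARGED_RESIDUES, 1)
        core = p1 + p2 + "".join(
            _sample_position(rng, t, UNCHARGED_RESIDUES) for t in DEFAULT_CORE_TABLES[2:]
        )
        # core positions 4 may be basic in the default tables; keep planted
        # anchors unambiguous by stripping charges when the row plants none.
        if pos2 is None:
            core = core[:3] + _random_string(rng, UNCHARGED_RESIDUES, 1) + core[4]
            if pos1 is None:
                core = _random_string(rng, UNCHARGED_RESIDUES, 1) + core[1:]
        total = int(rng.integers(7, 15))
        left = int(rng.integers(0, min(3, total - 5) + 1))
        right = total - 5 - left
        loop = _random_string(rng, UNCHARGED_RESIDUES, left) + core + _random_string(
            rng, UNCHARGED_RESIDUES, right
        )
        rid = f"hum{k + 1:03d}"
        records.append(_embed_loop(rng, rid, loop))
        cores[rid] = core
        core_start[rid] = left + 1
        loops[rid] = loop
        if pos1 is None and pos2 is None:
            manual[rid] = left + 1  # align the similarity-only row by hand
    family = SilFamily(tuple(records), cores, core_start, loops)
    return family, manual


# ---------------------------------------------------------------------------
# side chains and contact fixtures
# ---------------------------------------------------------------------------

# chi torsions / internal coordinates for the two side chains the contact
# fixtures need; values are conventional extended-rotamer geometry.
def _attach_cb(res: Residue) -> None:
    res.atoms["CB"] = place_atom(res["C"], res["N"], res["CA"], 1.53, 110.5, 122.5)


def attach_glu_sidechain(res: Residue, chi1: float = -65.0, chi2: float = 180.0,
                         chi3: float = -10.0) -> None:
    """Build CB-CG-CD-OE1/OE2 onto a Glu backbone with ideal geometry."""
    _attach_cb(res)
    res.atoms["CG"] = place_atom(res["N"], res["CA"], res["CB"], 1.52, 114.0, chi1)
    res.atoms["CD"] = place_atom(res["CA"], res["CB"], res["CG"], 1.52, 112.6, chi2)
    res.atoms["OE1"] = place_atom(res["CB"], res["CG"], res["CD"], 1.25, 118.3, chi3)
    res.atoms["OE2"] = place_atom(res["CB"], res["CG"], res["CD"], 1.25, 118.3, chi3 + 180.0)
    res.name = "GLU"


def attach_lys_sidechain(res: Residue, chi: float = 180.0) -> None:
    """Build CB-CG-CD-CE-NZ onto a Lys backbone, extended rotamer."""
    _attach_cb(res)
    res.atoms["CG"] = place_atom(res["N"], res["CA"], res["CB"], 1.52, 114.0, -65.0)
    res.atoms["CD"] = place_atom(res["CA"], res["CB"], res["CG"], 1.52, 111.3, chi)
    res.atoms["CE"] = place_atom(res["CB"], res["CG"], res["CD"], 1.52, 111.3, chi)
    res.atoms["NZ"] = place_atom(res["CG"], res["CD"], res["CE"], 1.49, 111.9, chi)
    res.name = "LYS"


def _lone_lysine(number: int) -> Residue:
    """A free-standing lysine residue in a canonical frame."""
    chain = build_backbone([ALPHA_TORSION, ALPHA_TORSION], sequence="KK")
    res = chain[0]
    res.number = number
    attach_lys_sidechain(res)
    return res


def _place_lysine_nz_at(res: Residue, target: np.ndarray, direction: np.ndarray) -> None:
    """Rigidly move `res` so NZ lands on `target` with the side chain
    extending along `direction` (so NZ stays the closest atom)."""
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    nz = res["NZ"]
    axis_ref = res["NZ"] - res["CE"]
    axis_ref = axis_ref / np.linalg.norm(axis_ref)
    rot = _rotation_between(axis_ref, direction)
    for name in list(res.atoms):
        res.atoms[name] = rot @ (res.atoms[name] - nz) + target
    np.testing.assert_allclose(res["NZ"], target, atol=1e-9)


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector u onto unit vector v."""
    c = float(np.dot(u, v))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # pick any perpendicular axis for the half-turn
        axis = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(u, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    axis /= s
    k = np.array([
        [0.0, -axis[2], axis[1]],
        [axis[2], 0.0, -axis[0]],
        [-axis[1], axis[0], 0.0],
    ])
    return np.eye(3) + s * k + (1.0 - c) * (k @ k)


def make_salt_bridge_toy(d: float, chain_id: str = "A") -> BackboneChain:
    """Minimal two-residue fixture: one Glu, one Lys, with the NZ-to-OE
    minimum heavy-atom distance equal to `d` (A).

    The lysine NZ is placed along the OE2->OE1 axis beyond OE1, so the
    minimum over {NZ} x {OE1, OE2} is attained at OE1 and equals `d`
    exactly.
    """
    if d <= 0:
        raise InputError("distance must be positive")
    glu_chain = build_backbone([ALPHA_TORSION, ALPHA_TORSION], sequence="EE", chain_id=chain_id)
    glu = glu_chain[0]
    attach_glu_sidechain(glu)
    away = glu["OE1"] - glu["OE2"]
    away = away / np.linalg.norm(away)
    lys = _lone_lysine(number=2)
    _place_lysine_nz_at(lys, glu["OE1"] + d * away, away)
    glu.number = 1
    return BackboneChain(chain_id=chain_id, residues=[glu, lys])


# ---------------------------------------------------------------------------
# synthetic tetraspanin stand-ins
# ---------------------------------------------------------------------------


def _placed_lysine(number: int, target_atom: np.ndarray, away: np.ndarray, d: float) -> Residue:
    lys = _lone_lysine(number)
    away = np.asarray(away, float)
    away = away / np.linalg.norm(away)
    _place_lysine_nz_at(lys, target_atom + d * away, away)
    return lys


def make_synthetic_cd9(chain_id: str = "A") -> BackboneChain:
    """Synthetic stand-in for the CD9 SIL region (not the experimental
    structure).

    An idealized TMS2-SIL-TMS3 hairpin with the QESQC turn at author numbers
    83-87 and a lone juxtamembrane lysine, numbered K11, whose NZ sits at
    2.8 A from the nearest carboxylate oxygen of the turn glutamate E84 —
    the salt-bridge geometry reported for the crystal structure.
    """
    seq = "L" * 20 + "QESQC" + "L" * 20
    chain, (w0, _) = make_m_hairpin(20, 20, sequence=seq, start_number=63, chain_id=chain_id)
    glu = chain[w0 + 1]
    assert glu.one_letter == "E" and glu.number == 84
    attach_glu_sidechain(glu)
    away = glu["OE1"] - glu["OE2"]
    lys = _placed_lysine(11, glu["OE1"], away, 2.8)
    return BackboneChain(chain_id=chain_id, residues=[lys] + chain.residues)


def make_synthetic_cd53(chain_id: str = "A") -> BackboneChain:
    """Synthetic stand-in for the CD53 SIL region (not the experimental
    structure).

    The KENKS turn sits at author numbers 76-80 (the crystallographic
    construct carries the Cys->Ser exchange), with two juxtamembrane
    lysines K7 and K10 whose NZ atoms are 5.1 A and 5.2 A from the nearest
    carboxylate oxygen of E77 — about one angstrom beyond the 4 A
    salt-bridge criterion, as reported.
    """
    seq = "L" * 20 + "KENKS" + "L" * 20
    chain, (w0, _) = make_m_hairpin(20, 20, sequence=seq, start_number=56, chain_id=chain_id)
    glu = chain[w0 + 1]
    assert glu.one_letter == "E" and glu.number == 77
    attach_glu_sidechain(glu)
    base = glu["OE1"] - glu["OE2"]
    tilt = np.cross(base, glu["OE1"] - glu["CD"])
    k7 = _placed_lysine(7, glu["OE1"], base, 5.1)
    k10 = _placed_lysine(10, glu["OE1"], base + 0.6 * tilt / np.linalg.norm(tilt)
                         * np.linalg.norm(base), 5.2)
    return BackboneChain(chain_id=chain_id, residues=[k7, k10] + chain.residues)
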