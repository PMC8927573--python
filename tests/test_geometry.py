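import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from silmotif import (
    GeometryError,
    RamaClass,
    assign_helices,
    build_backbone,
    classify_chain,
    classify_rama,
    dihedral,
    make_m_hairpin,
    phi_psi,
    plane_fit_rms,
    wheel_separation,
)
from silmotif.geometry import DEFAULT_RAMA_REGIONS


def oracle_dihedral(p1, p2, p3, p4):
    """Independent torsion formula: acos of normal angle, sign from the
    triple product (different route than the implementation's atan2)."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
    if np.dot(np.cross(n1, n2), b2) < 0:
        ang = -ang
    return ang


class TestDihedral:
    def test_planar_cis_is_zero(self):
        pts = [np.array(p, float) for p in
               [(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)]]
        assert dihedral(*pts) == pytest.approx(0.0, abs=1e-12)

    def test_planar_trans_is_180(self):
        pts = [np.array(p, float) for p in
               [(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)]]
        assert dihedral(*pts) == pytest.approx(180.0)

    def test_matches_independent_oracle(self, rng):
        for _ in range(1000):
            pts = rng.normal(size=(4, 3)) * 3
            try:
                ours = dihedral(*pts)
            except GeometryError:
                continue
            assert ours == pytest.approx(oracle_dihedral(*pts), abs=1e-9)

    def test_rigid_transform_invariance(self, rng):
        for _ in range(100):
            pts = rng.normal(size=(4, 3)) * 3
            rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
            shift = rng.normal(size=3) * 10
            moved = [rot @ p + shift for p in pts]
            try:
                ref = dihedral(*pts)
            except GeometryError:
                continue
            assert dihedral(*moved) == pytest.approx(ref, abs=1e-9)

    def test_collinear_rejected(self):
        pts = [np.array([float(i), 0, 0]) for i in range(4)]
        with pytest.raises(GeometryError):
            dihedral(*pts)


class TestPhiPsi:
    def test_two_residue_chain_boundary_contract(self):
        chain = build_backbone([(-57, -47, 180)] * 2)
        recs = phi_psi(chain)
        assert recs[0].phi is None and recs[0].psi is not None
        assert recs[1].phi is not None and recs[1].psi is None

    def test_break_undefines_angles(self):
        chain = build_backbone([(-57, -47, 180)] * 6)
        for res in chain.residues[3:]:
            for name in res.atoms:
                res.atoms[name] = res.atoms[name] + np.array([50.0, 0, 0])
        recs = phi_psi(chain)
        assert recs[3].phi is None and recs[2].psi is None
        assert recs[4].phi is not None  # the shifted block is internally intact

    def test_incomplete_residue_undefined(self):
        chain = build_backbone([(-57, -47, 180)] * 5)
        del chain[2].atoms["C"]
        recs = phi_psi(chain)
        assert recs[2].phi is None and recs[2].psi is None


class TestClassifyRama:
    @pytest.mark.parametrize(
        "phi,psi,expected",
        [
            (-57, -47, RamaClass.ALPHA_R),
            (60, 45, RamaClass.ALPHA_L),
            (-120, 130, RamaClass.BETA),
            (-120, 180, RamaClass.BETA),   # psi upper edge inclusive at 180
            (-120, -160, RamaClass.BETA),  # wrapped beta strip
            (0, 0, RamaClass.OTHER),
            (None, -47, RamaClass.OTHER),
        ],
    )
    def test_examples(self, phi, psi, expected):
        assert classify_rama(phi, psi) is expected

    def test_totality_and_disjointness(self, rng):
        """Every defined angle pair maps to exactly one class."""
        for _ in range(2000):
            phi = float(rng.uniform(-180, 180))
            psi = float(rng.uniform(-180, 180))
            memberships = [
                cls
                for cls, rects in DEFAULT_RAMA_REGIONS.items()
                for (plo, phi_hi, slo, shi) in rects
                if (plo <= phi < phi_hi or (phi_hi >= 180 and phi == 180))
                and (slo <= psi < shi or (shi >= 180 and psi == 180))
            ]
            assert len(memberships) <= 1
            expected = memberships[0] if memberships else RamaClass.OTHER
            assert classify_rama(phi, psi) is expected


class TestAssignHelices:
    def test_ideal_helix_single_segment(self):
        chain = build_backbone([(-57, -47, 180)] * 20)
        classes = classify_chain(phi_psi(chain))
        assert assign_helices(classes) == [(1, 18)]  # termini undefined

    def test_hairpin_two_segments(self):
        chain, (w0, w1) = make_m_hairpin(10, 10)
        classes = classify_chain(phi_psi(chain))
        runs = assign_helices(classes)
        # upstream arm, then downstream arm; positions 1/4/5 of the turn are
        # alphaR and merge into the adjacent runs
        assert len(runs) == 2
        assert runs[0][1] == w0 and runs[1][0] == w1 - 1

    def test_no_helix_in_beta_chain(self):
        chain = build_backbone([(-120, 130, 180)] * 10)
        classes = classify_chain(phi_psi(chain))
        assert assign_helices(classes) == []

    def test_min_run_threshold(self):
        classes = [RamaClass.ALPHA_R] * 3 + [RamaClass.OTHER] + [RamaClass.ALPHA_R] * 4
        assert assign_helices(classes, min_run=4) == [(4, 7)]


class TestPlaneFitRms:
    def test_coplanar_sets_are_zero(self, rng):
        for _ in range(20):
            pts2d = rng.normal(size=(8, 2)) * 5
            pts = np.column_stack([pts2d, np.zeros(8)])
            rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
            pts = pts @ rot.T + rng.normal(size=3)
            assert plane_fit_rms(pts) == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_offsets_give_h(self):
        # square corners alternating +h/-h around the ring: no tilted plane
        # can absorb the offsets, so the best fit is z=0 with RMS exactly h
        h = 0.37
        pts = np.array([
            [1, 0, h], [0, 1, -h], [-1, 0, h], [0, -1, -h],
        ], float)
        assert plane_fit_rms(pts) == pytest.approx(h, abs=1e-12)

    def test_matches_numeric_minimization_oracle(self, rng):
        """Independent oracle: directly minimize RMS plane distance over
        (normal angles, offset) with scipy."""
        for _ in range(40):
            pts = rng.normal(size=(int(rng.integers(4, 12)), 3)) * 4

            def rms(params):
                theta, phi_ang, d = params
                n = np.array([
                    math.sin(theta) * math.cos(phi_ang),
                    math.sin(theta) * math.sin(phi_ang),
                    math.cos(theta),
                ])
                return math.sqrt(np.mean((pts @ n - d) ** 2))

            best = min(
                (minimize(rms, x0, method="Nelder-Mead",
                          options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000})
                 for x0 in ([0.5, 0.5, 0.0], [1.5, -1.0, 1.0], [0.1, 2.5, -1.0])),
                key=lambda r: r.fun,
            )
            assert plane_fit_rms(pts) == pytest.approx(best.fun, abs=1e-6)

    def test_rigid_transform_invariance(self, rng):
        pts = rng.normal(size=(10, 3)) * 3
        ref = plane_fit_rms(pts)
        rot = Rotation.random(random_state=7).as_matrix()
        assert plane_fit_rms(pts @ rot.T + 5.0) == pytest.approx(ref, abs=1e-9)

    def test_collinear_rejected(self):
        pts = np.array([[i, 0.0, 0.0] for i in range(5)])
        with pytest.raises(GeometryError):
            plane_fit_rms(pts)


class TestWheelSeparation:
    @pytest.mark.parametrize("delta,expected", [(0, 0.0), (18, 0.0), (5, 140.0)])
    def test_modular_arithmetic(self, delta, expected):
        assert wheel_separation(10, 10 + delta) == pytest.approx(expected)

    def test_symmetry(self):
        assert wheel_separation(3, 10) == wheel_separation(10, 3)
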