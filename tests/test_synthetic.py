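import math

import numpy as np
import pytest

from silmotif import (
    FamilySpec,
    InputError,
    SIL_RULE,
    align_loops,
    anchor_loop,
    build_backbone,
    consensus_string,
    extract_sil,
    make_anchor_census_family,
    make_m_hairpin,
    make_salt_bridge_toy,
    make_sil_family,
    phi_psi,
)
from silmotif.synthetic import BackboneGeometry, DEFAULT_GEOMETRY, place_atom


def oracle_build(torsions, g=DEFAULT_GEOMETRY):
    """Independent kinematics: accumulate explicit rotation matrices
    bond-by-bond in a running local frame (no NeRF frame reuse)."""

    def rot_x(a):
        c, s = math.cos(a), math.sin(a)
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])

    def rot_z(a):
        c, s = math.cos(a), math.sin(a)
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])

    # Bond chain: N1-CA1-C1-N2-CA2-C2-... with per-step (length, bond angle,
    # preceding torsion).  Walk a frame whose x-axis is the current bond.
    lengths, angles, torsion_seq = [], [], []
    n = len(torsions)
    for i in range(n):
        phi, psi, omega = torsions[i]
        if i > 0:
            lengths += [g.c_n, g.n_ca, g.ca_c]
            angles += [g.ang_ca_c_n, g.ang_c_n_ca, g.ang_n_ca_c]
            torsion_seq += [torsions[i - 1][1], torsions[i - 1][2], phi]
    pos = [np.zeros(3), np.array([g.n_ca, 0.0, 0.0])]
    theta0 = math.radians(g.ang_n_ca_c)
    pos.append(pos[1] + g.ca_c * np.array([-math.cos(theta0), math.sin(theta0), 0.0]))
    for L, ang, tor in zip(lengths, angles, torsion_seq):
        a, b, c = pos[-3], pos[-2], pos[-1]
        # build an explicit frame at c: x along b->c, z normal to (a,b,c)
        x = c - b
        x /= np.linalg.norm(x)
        z = np.cross(b - a, x)
        z /= np.linalg.norm(z)
        y = np.cross(z, x)
        frame = np.column_stack([x, y, z])
        direction = rot_x(math.radians(tor)) @ rot_z(math.radians(180.0 - ang)) @ np.array([1.0, 0, 0])
        pos.append(c + L * (frame @ direction))
    return pos  # flat list: N1, CA1, C1, N2, CA2, C2, ...


class TestBuildBackbone:
    def test_round_trip_of_ideal_helix(self):
        chain = build_backbone([(-57.0, -47.0, 180.0)] * 8)
        for rec in phi_psi(chain):
            if rec.phi is not None:
                assert rec.phi == pytest.approx(-57.0, abs=1e-6)
            if rec.psi is not None:
                assert rec.psi == pytest.approx(-47.0, abs=1e-6)

    def test_round_trip_of_random_torsions(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 12))
            torsions = [
                (float(rng.uniform(-179, 179)), float(rng.uniform(-179, 179)), 180.0)
                for _ in range(n)
            ]
            chain = build_backbone(torsions)
            for i, rec in enumerate(phi_psi(chain)):
                if rec.phi is not None:
                    assert rec.phi == pytest.approx(torsions[i][0], abs=1e-6)
                if rec.psi is not None:
                    assert rec.psi == pytest.approx(torsions[i][1], abs=1e-6)

    def test_bond_lengths_match_geometry_constants(self):
        g = DEFAULT_GEOMETRY
        chain = build_backbone([(-57, -47, 180)] * 6)
        for i, res in enumerate(chain):
            assert np.linalg.norm(res["CA"] - res["N"]) == pytest.approx(g.n_ca, abs=1e-9)
            assert np.linalg.norm(res["C"] - res["CA"]) == pytest.approx(g.ca_c, abs=1e-9)
            assert np.linalg.norm(res["O"] - res["C"]) == pytest.approx(g.c_o, abs=1e-9)
            if i:
                prev = chain[i - 1]
                assert np.linalg.norm(res["N"] - prev["C"]) == pytest.approx(g.c_n, abs=1e-9)

    def test_matches_rotation_matrix_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 8))
            torsions = [
                (float(rng.uniform(-179, 179)), float(rng.uniform(-179, 179)),
                 float(rng.uniform(-179, 179)))
                for _ in range(n)
            ]
            chain = build_backbone(torsions)
            expected = oracle_build(torsions)
            got = []
            for res in chain:
                got += [res["N"], res["CA"], res["C"]]
            for g_atom, e_atom in zip(got, expected):
                np.testing.assert_allclose(g_atom, e_atom, atol=1e-6)

    def test_non_physical_geometry_rejected(self):
        with pytest.raises(Exception):
            BackboneGeometry(ang_n_ca_c=180.0)
        with pytest.raises(Exception):
            BackboneGeometry(n_ca=-1.0)

    def test_too_short_rejected(self):
        with pytest.raises(InputError):
            build_backbone([(-57, -47, 180)])


class TestMakeMHairpin:
    def test_same_seed_identical_coordinates(self):
        a, _ = make_m_hairpin(8, 8, seed=5, jitter_deg=2.0)
        b, _ = make_m_hairpin(8, 8, seed=5, jitter_deg=2.0)
        for ra, rb in zip(a, b):
            for name in ra.atoms:
                assert np.array_equal(ra[name], rb[name])

    def test_different_seed_differs_under_jitter(self):
        a, _ = make_m_hairpin(8, 8, seed=1, jitter_deg=2.0)
        b, _ = make_m_hairpin(8, 8, seed=2, jitter_deg=2.0)
        assert not np.allclose(a[4]["CA"], b[4]["CA"])


class TestMakeSilFamily:
    def test_noise_free_core_recovered_exactly(self):
        spec = FamilySpec(n_sequences=20, core=tuple({aa: 1.0} for aa in "KENKC"), seed=9)
        fam = make_sil_family(spec)
        loops = {r.id: extract_sil(r) for r in fam.records}
        assert loops == fam.loops
        assert consensus_string(align_loops(loops)) == "K E N K C"

    def test_same_seed_identical_records(self):
        a = make_sil_family(FamilySpec(n_sequences=10, seed=3))
        b = make_sil_family(FamilySpec(n_sequences=10, seed=3))
        assert [r.sequence for r in a.records] == [r.sequence for r in b.records]
        assert a.cores == b.cores

    def test_loop_lengths_in_range(self):
        fam = make_sil_family(FamilySpec(n_sequences=40, seed=11))
        assert all(6 <= len(loop) <= 21 for loop in fam.loops.values())

    def test_planted_frequency_recovered_within_binomial_bounds(self):
        """Plant Glu at position 2 with probability 23/33; over many seeds the
        pipeline-recovered frequency stays within 3 binomial SE."""
        p = 23 / 33
        n = 33
        se = math.sqrt(p * (1 - p) / n)
        core = ({"R": 1.0}, {"E": p}, {"N": 1.0}, {"K": 1.0}, {"C": 1.0})
        within = 0
        for seed in range(100):
            fam = make_sil_family(FamilySpec(n_sequences=n, core=core, seed=seed))
            aln = align_loops(fam.loops)
            from silmotif import column_frequencies

            prof = column_frequencies(aln, aln.core_columns[1])
            f_e = prof.counts.get("E", 0) / n
            if abs(f_e - p) <= 3 * se:
                within += 1
        assert within >= 95

    def test_records_have_valid_topology(self):
        fam = make_sil_family(FamilySpec(n_sequences=10, seed=2))
        for rec in fam.records:  # SequenceRecord validates on construction
            assert len(rec.tms) == 4


class TestCensusStandin:
    def test_planted_anchor_composition_recovered(self):
        fam, manual = make_anchor_census_family(seed=0)
        loops = {r.id: extract_sil(r) for r in fam.records}
        tallies = {"E": 0, "D": 0, "basic": 0, "unanchored": 0}
        for rid, loop in loops.items():
            asg = anchor_loop(loop, SIL_RULE, rid)
            if not asg.anchored:
                tallies["unanchored"] += 1
            elif loop[asg.anchor_index - 1] in "ED":
                tallies[loop[asg.anchor_index - 1]] += 1
            else:
                tallies["basic"] += 1
        assert tallies == {"E": 23, "D": 2, "basic": 7, "unanchored": 1}
        aln = align_loops(loops, manual_offsets=manual)
        assert len(aln.rows) == 33
        from silmotif import column_frequencies

        counts = column_frequencies(aln, aln.core_columns[0]).counts
        assert counts["R"] == 13 and counts["K"] == 11


class TestSaltBridgeToy:
    @pytest.mark.parametrize("d", [2.8, 4.0, 4.5])
    def test_exact_minimum_distance(self, d):
        from silmotif import contact_scan

        toy = make_salt_bridge_toy(d)
        rec = contact_scan(toy, pairs=[("K2", "E1")])[0]
        assert rec.distance == pytest.approx(d, abs=1e-9)
        assert rec.is_salt_bridge is (d <= 4.0)

    def test_positive_distance_required(self):
        with pytest.raises(InputError):
            make_salt_bridge_toy(0.0)
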