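"""Geometry: superposition, Rg, dyad frame, breathing angles, distances."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import nucbreathe as nb
from nucbreathe.geometry import (
    DyadFrame,
    _project_angles,
    build_dyad_frame,
    linker_vector,
    min_group_distance,
    radius_of_gyration,
    superpose_to_reference,
)
from nucbreathe.selections import dna_mask
from conftest import make_point_frame


def random_rigid(rng):
    rot = Rotation.random(rng=rng)
    shift = rng.uniform(-50, 50, size=3)
    return lambda xyz: rot.apply(xyz) + shift


class TestSuperposition:
    def test_identical_frames_have_zero_rmsd(self):
        rng = np.random.default_rng(0)
        frame = make_point_frame(rng.normal(size=(40, 3)))
        sel = np.ones(40, dtype=bool)
        _, rmsd = superpose_to_reference(frame, frame, selection=sel)
        assert rmsd == pytest.approx(0.0, abs=1e-7)

    def test_rigid_motion_is_fully_removed(self):
        rng = np.random.default_rng(1)
        ref = make_point_frame(rng.normal(scale=5, size=(60, 3)))
        moved = ref.with_coords(
            Rotation.from_euler("z", 90, degrees=True).apply(ref.coords)
            + [10.0, -4.0, 7.0])
        sel = np.ones(60, dtype=bool)
        fitted, rmsd = superpose_to_reference(moved, ref, selection=sel)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(fitted.coords, ref.coords, atol=1e-9)

    def test_matches_rotation_search_oracle(self):
        # independent oracle: random rotation search with shrinking local
        # refinement around the incumbent (no gradient information shared
        # with the Kabsch implementation)
        rng = np.random.default_rng(7)
        a = rng.normal(scale=3, size=(50, 3))
        b = rng.normal(scale=3, size=(50, 3))
        ref = make_point_frame(a)
        frame = make_point_frame(b)
        sel = np.ones(50, dtype=bool)
        _, rmsd = superpose_to_reference(frame, ref, selection=sel)

        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)

        def cost(rot):
            return float(np.sqrt(((rot.apply(bc) - ac) ** 2).sum(1).mean()))

        best = Rotation.identity()
        best_cost = cost(best)
        for cand in Rotation.random(4000, rng=rng):
            c = cost(cand)
            if c < best_cost:
                best, best_cost = cand, c
        for scale in (0.3, 0.1, 0.03, 0.01, 0.003):
            for _ in range(400):
                cand = Rotation.from_rotvec(
                    rng.normal(scale=scale, size=3)) * best
                c = cost(cand)
                if c < best_cost:
                    best, best_cost = cand, c
        assert rmsd <= best_cost + 1e-12   # Kabsch is the true optimum
        assert best_cost - rmsd < 1e-2     # and the search gets this close

    def test_selection_mismatch_raises(self):
        f1 = make_point_frame(np.zeros((5, 3)))
        f2 = make_point_frame(np.zeros((6, 3)))
        with pytest.raises(ValueError):
            superpose_to_reference(f2, f1,
                                   selection=np.ones(5, dtype=bool))


class TestRadiusOfGyration:
    def test_two_unit_masses(self):
        frame = make_point_frame([[3.0, 0, 0], [-3.0, 0, 0]])
        sel = np.ones(2, dtype=bool)
        assert radius_of_gyration(frame, sel) == pytest.approx(3.0)

    def test_cube_corners(self):
        a = 2.5
        corners = [[sx * a, sy * a, sz * a]
                   for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
        frame = make_point_frame(corners)
        assert radius_of_gyration(frame, np.ones(8, dtype=bool)) == \
            pytest.approx(a * math.sqrt(3))

    def test_weighted_random_points_match_direct_sum(self):
        rng = np.random.default_rng(3)
        xyz = rng.normal(scale=10, size=(500, 3))
        masses = rng.uniform(1, 30, size=500)
        frame = make_point_frame(xyz)
        frame.masses[:] = masses
        sel = np.ones(500, dtype=bool)
        # naive summation oracle
        com = sum(m * x for m, x in zip(masses, xyz)) / masses.sum()
        sq = sum(m * ((x - com) ** 2).sum()
                 for m, x in zip(masses, xyz)) / masses.sum()
        assert radius_of_gyration(frame, sel) == \
            pytest.approx(math.sqrt(sq), rel=1e-10)

    def test_empty_selection_raises(self):
        frame = make_point_frame(np.zeros((4, 3)))
        with pytest.raises(ValueError):
            radius_of_gyration(frame, np.zeros(4, dtype=bool))


class TestDyadFrame:
    def test_axes_orthonormal_and_right_handed(self, closed_nucleosome):
        frame, topo, _ = closed_nucleosome
        d = build_dyad_frame(frame, topo)
        for v in (d.X, d.Y, d.Z):
            assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-10)
        assert abs(d.X @ d.Y) < 1e-8
        assert abs(d.X @ d.Z) < 1e-8
        assert abs(d.Y @ d.Z) < 1e-8
        np.testing.assert_allclose(np.cross(d.X, d.Y), d.Z, atol=1e-8)

    def test_z_tracks_superhelical_axis(self, closed_nucleosome):
        frame, topo, gt = closed_nucleosome
        d = build_dyad_frame(frame, topo)
        angle = math.degrees(math.acos(abs(float(d.Z @ gt.axis))))
        assert angle < 5.0

    def test_equivariant_under_rigid_motion(self, closed_nucleosome):
        frame, topo, _ = closed_nucleosome
        d0 = build_dyad_frame(frame, topo)
        rng = np.random.default_rng(11)
        rot = Rotation.random(rng=rng)
        shift = np.array([12.0, -8.0, 30.0])
        moved = frame.with_coords(rot.apply(frame.coords) + shift)
        d1 = build_dyad_frame(moved, topo)
        np.testing.assert_allclose(d1.origin, rot.apply(d0.origin) + shift,
                                   atol=1e-8)
        for a0, a1 in ((d0.X, d1.X), (d0.Y, d1.Y), (d0.Z, d1.Z)):
            np.testing.assert_allclose(a1, rot.apply(a0), atol=1e-8)

    def test_plane_fit_variant_also_orthonormal(self, closed_nucleosome):
        frame, topo, _ = closed_nucleosome
        d = build_dyad_frame(frame, topo, normal_method="plane_fit")
        assert abs(d.X @ d.Z) < 1e-8


class TestLinkerVector:
    def _line_system(self, direction, reverse=False):
        """11 collinear pseudo-phosphate bp on each linker of a tiny
        nucleosome-like topology."""
        from nucbreathe.topology import build_topology
        n_bp = 30
        cfg = {
            "chains": {"I": "DNA_I", "J": "DNA_J", "E": "H3-A"},
            "species": "custom", "tails": {}, "n_bp": n_bp,
            "dna_residues": {"I": list(range(1, n_bp + 1)),
                             "J": list(range(n_bp, 0, -1))},
            "regions": {"core_size": 8, "outer_gyre_size": 10},
        }
        topo = build_topology(cfg)
        u = np.asarray(direction, float)
        u = u / np.linalg.norm(u)
        coords, chains, resids, names = [], [], [], []
        rng = np.random.default_rng(5)
        core_center = np.zeros(3)
        order = range(n_bp)
        for bp in (reversed(order) if reverse else order):
            # place bp positions: core bps clustered, linkers along ±u
            if 11 <= bp <= 18:
                pos = core_center + rng.normal(scale=1.0, size=3)
            elif bp < 11:
                pos = core_center - (11 - bp) * 3.4 * u
            else:
                pos = core_center + (bp - 18) * 3.4 * u
            for chain in ("I", "J"):
                resid = bp + 1 if chain == "I" else n_bp - bp
                coords.append(pos)
                chains.append(chain)
                resids.append(resid)
                names.append("P")
        frame = make_point_frame(np.array(coords), chains=chains,
                                 resids=resids, names=names,
                                 elements=["P"] * len(coords))
        frame.roles[:] = np.where(np.array(chains) == "I", "DNA_I", "DNA_J")
        return frame, topo, u

    def test_collinear_linker_returns_outward_direction(self):
        frame, topo, u = self._line_system([1.0, 2.0, -0.5])
        v3 = linker_vector(frame, topo, "3p")
        assert float(v3 @ u) == pytest.approx(1.0, abs=1e-9)
        v5 = linker_vector(frame, topo, "5p")
        assert float(v5 @ (-u)) == pytest.approx(1.0, abs=1e-9)

    def test_orientation_independent_of_file_order(self):
        frame, topo, u = self._line_system([0.3, -1.0, 0.7], reverse=True)
        v3 = linker_vector(frame, topo, "3p")
        assert float(v3 @ u) == pytest.approx(1.0, abs=1e-9)

    def test_helical_linker_within_10deg_of_generated_arm_axis(
            self, closed_nucleosome):
        frame, topo, gt = closed_nucleosome
        for side in ("5p", "3p"):
            v = linker_vector(frame, topo, side)
            angle = math.degrees(math.acos(
                np.clip(float(v @ gt.arm_axes[side]), -1, 1)))
            assert angle < 10.0

    def test_too_short_linker_raises(self, closed_nucleosome):
        frame, topo, _ = closed_nucleosome
        with pytest.raises(ValueError, match="short"):
            linker_vector(frame, nb.build_topology({
                "chains": dict(topo.chain_map), "species": "human",
                "n_bp": 168, "dna_residues": {
                    "I": list(range(1, 169)),
                    "J": list(range(168, 0, -1))},
                "regions": {"core_size": 166, "outer_gyre_size": 40},
            }), "3p")


class TestBreathingAngles:
    def _identity_dyad(self):
        return DyadFrame(origin=np.zeros(3), X=np.array([1.0, 0, 0]),
                         Y=np.array([0, 1.0, 0]), Z=np.array([0, 0, 1.0]))

    def test_v_along_z_gives_zero_gamma1(self):
        g1, _ = _project_angles(np.array([0, 0, 1.0]), self._identity_dyad())
        assert g1 == pytest.approx(0.0)

    def test_v_rotated_30deg_toward_x_gives_gamma1_30(self):
        v = Rotation.from_euler("y", 30, degrees=True).apply([0, 0, 1.0])
        g1, _ = _project_angles(v, self._identity_dyad())
        assert g1 == pytest.approx(30.0)

    def test_v_along_y_gives_zero_gamma2(self):
        _, g2 = _project_angles(np.array([0, 1.0, 0]), self._identity_dyad())
        assert g2 == pytest.approx(0.0)

    def test_gamma2_positive_sense_about_z(self):
        v = Rotation.from_euler("z", 25, degrees=True).apply([0, 1.0, 0])
        _, g2 = _project_angles(v, self._identity_dyad())
        assert g2 == pytest.approx(25.0)

    def test_projection_perpendicular_to_plane_is_undefined(self):
        g1, g2 = _project_angles(np.array([0, 1.0, 0]),
                                 self._identity_dyad())
        assert math.isnan(g1)  # v ⟂ XZ plane
        assert g2 == pytest.approx(0.0)


class TestMinGroupDistance:
    def test_singletons(self):
        frame = make_point_frame([[0, 0, 0], [7.0, 0, 0]])
        a = np.array([True, False])
        assert min_group_distance(frame, a, ~a) == pytest.approx(7.0)

    def test_overlapping_groups_give_zero(self):
        frame = make_point_frame([[1.0, 2, 3], [1.0, 2, 3], [9, 9, 9]])
        a = np.array([True, False, True])
        b = np.array([False, True, False])
        assert min_group_distance(frame, a, b) == pytest.approx(0.0)

    def test_matches_brute_force_exactly(self):
        rng = np.random.default_rng(17)
        xyz = rng.uniform(-40, 40, size=(400, 3))
        frame = make_point_frame(xyz)
        a = np.zeros(400, dtype=bool)
        a[:200] = True
        d = min_group_distance(frame, a, ~a)
        brute = min(
            np.linalg.norm(xyz[i] - xyz[j])
            for i in range(200) for j in range(200, 400))
        assert d == brute  # exact, not approximate

    def test_empty_group_raises(self):
        frame = make_point_frame(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            min_group_distance(frame, np.zeros(3, dtype=bool),
                               np.ones(3, dtype=bool))


class TestRigidInvariance:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rg_and_angles_invariant_under_joint_rigid_motion(
            self, closed_nucleosome, seed):
        frame, topo, _ = closed_nucleosome
        dna = dna_mask(frame, topo)
        dyad = build_dyad_frame(frame, topo)
        rg0 = radius_of_gyration(frame, dna)
        ang0 = nb.breathing_angles(frame, dyad, topo)

        rng = np.random.default_rng(seed)
        transform = random_rigid(rng)
        moved = frame.with_coords(transform(frame.coords))
        dyad_m = build_dyad_frame(moved, topo)
        rg1 = radius_of_gyration(moved, dna)
        ang1 = nb.breathing_angles(moved, dyad_m, topo)

        assert rg1 == pytest.approx(rg0, abs=1e-6)
        for attr in ("gamma1_5p", "gamma2_5p", "gamma1_3p", "gamma2_3p"):
            assert getattr(ang1, attr) == pytest.approx(
                getattr(ang0, attr), abs=1e-6)
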