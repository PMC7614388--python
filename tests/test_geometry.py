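"""Chair construction, face rule, pose building and Kabsch superposition."""

import numpy as np
import pytest

from insptools.algebra import ENANTIOMER_MAP, PhosphoInositol, parse_name
from insptools.geometry import (
    CC_BOND,
    RigidTransform,
    build_ideal_chair,
    construct_pose,
    kabsch_superpose,
    read_ring_pdb,
    required_face,
    required_face_geometric,
    ring_normal,
    rotation_about_axis,
    write_ring_pdb,
)


def random_rigid(rng):
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return RigidTransform(rot, rng.standard_normal(3) * 5)


class TestIdealChair:
    def test_ring_closes_with_equal_bonds(self, ideal_chair):
        assert ideal_chair.ring_closure_deviation() < 1e-6
        d = np.linalg.norm(
            np.roll(ideal_chair.carbons, -1, axis=0) - ideal_chair.carbons, axis=1
        )
        assert np.allclose(d, CC_BOND, atol=1e-9)

    def test_bond_angles_tetrahedral(self, ideal_chair):
        c = ideal_chair.carbons
        for i in range(6):
            u = c[(i + 1) % 6] - c[i]
            w = c[(i - 1) % 6] - c[i]
            cosang = u @ w / (np.linalg.norm(u) * np.linalg.norm(w))
            assert cosang == pytest.approx(-1.0 / 3.0, abs=1e-9)

    def test_only_c2_substituent_axial(self, ideal_chair):
        assert [ideal_chair.is_axial(k) for k in range(1, 7)] == [
            False,
            True,
            False,
            False,
            False,
            False,
        ]

    def test_equatorial_tilt_pattern(self, ideal_chair):
        """Equatorial substituents at C1/C3/C5 tilt toward the obverse face
        (the C2-axial side); those at C4/C6 tilt toward the reverse face."""
        n = ideal_chair.obverse_normal
        for k in (1, 3, 5):
            assert ideal_chair.substituent(k) @ n > 0
        for k in (4, 6):
            assert ideal_chair.substituent(k) @ n < 0

    def test_alternating_pucker(self, ideal_chair):
        # consecutive carbons pucker to opposite faces
        z = ideal_chair.carbons[:, 2]
        assert np.all(np.sign(z[::2]) == -np.sign(z[1::2]))


class TestFaceRule:
    @pytest.mark.parametrize(
        "target, face",
        [(1, "reverse"), (3, "reverse"), (5, "reverse"), (4, "obverse"), (6, "obverse")],
    )
    def test_rule(self, target, face):
        assert required_face(target) == face

    def test_axial_target_rejected(self):
        with pytest.raises(ValueError):
            required_face(2)
        with pytest.raises(ValueError):
            required_face_geometric(2)

    def test_rule_emerges_from_coordinates(self, ideal_chair):
        for target in (1, 3, 4, 5, 6):
            assert required_face_geometric(target, ideal_chair) == required_face(
                target
            )


class TestC2C5Rotation:
    def test_realizes_the_enantiomer_position_map(self, ideal_chair):
        """A 180-degree turn about the C2-C5 axis exchanges carbons 1<->3 and
        4<->6 in the projected ring ordering (the sigma map), and flips the
        presented face."""
        axis = ideal_chair.carbon(5) - ideal_chair.carbon(2)
        rot = RigidTransform(rotation_about_axis(axis, 180.0), np.zeros(3))
        flipped = ideal_chair.transformed(rot)
        for k in range(1, 7):
            img = flipped.carbon(k)
            nearest = min(
                range(1, 7),
                key=lambda j: np.linalg.norm(img - ideal_chair.carbon(j)),
            )
            assert nearest == ENANTIOMER_MAP[k]
        assert flipped.obverse_normal @ ideal_chair.obverse_normal < 0

    def test_reflection_through_mirror_plane_gives_same_position_map(
        self, ideal_chair
    ):
        """Brute-force 3D oracle: reflecting the chair through the C2/C5
        mirror plane maps carbon k onto sigma(k)."""
        # mirror plane contains C2, C5 and the ring normal
        c2, c5 = ideal_chair.carbon(2), ideal_chair.carbon(5)
        centroid = ideal_chair.carbons.mean(axis=0)
        in_plane1 = c5 - c2
        in_plane2 = ring_normal(ideal_chair.carbons)
        normal = np.cross(in_plane1, in_plane2)
        normal /= np.linalg.norm(normal)
        for k in range(1, 7):
            v = ideal_chair.carbon(k) - centroid
            reflected = v - 2 * normal * (normal @ v) + centroid
            nearest = min(
                range(1, 7),
                key=lambda j: np.linalg.norm(reflected - ideal_chair.carbon(j)),
            )
            assert nearest == ENANTIOMER_MAP[k]


class TestConstructPose:
    @pytest.mark.parametrize(
        "isomer, target, face",
        [
            ("Ins(1,4,6)P3", 3, "reverse"),
            ("Ins(3,4,6)P3", 1, "reverse"),
            ("Ins(3,4,5)P3", 6, "obverse"),
            ("Ins(1,3,4)P3", 5, "reverse"),
        ],
    )
    def test_face_and_target_placement(self, isomer, target, face):
        pose = construct_pose(parse_name(isomer), target)
        assert pose.face == face
        tpos = pose.chair.carbon(target)
        assert np.arctan2(tpos[1], tpos[0]) == pytest.approx(0.0, abs=1e-9)
        # the required face is presented toward the +z observer
        presented = pose.chair.obverse_normal[2]
        assert (presented < 0) == (face == "reverse")

    def test_phosphorylated_target_rejected(self):
        with pytest.raises(ValueError):
            construct_pose(parse_name("Ins(1,4,6)P3"), 4)

    def test_axial_target_rejected(self):
        with pytest.raises(ValueError):
            construct_pose(parse_name("Ins(1,4,6)P3"), 2)

    def test_transform_reproduces_pose_coordinates(self, ideal_chair):
        pose = construct_pose(parse_name("Ins(1,4,6)P3"), 3)
        rebuilt = pose.transform.apply(ideal_chair.carbons)
        assert np.allclose(rebuilt, pose.chair.carbons, atol=1e-9)


class TestKabsch:
    def test_identity(self, ideal_chair):
        _, rmsd = kabsch_superpose(ideal_chair.carbons, ideal_chair.carbons)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_recovers_random_rigid_motion(self, ideal_chair):
        rng = np.random.default_rng(11)
        for _ in range(10):
            t = random_rigid(rng)
            moved = t.apply(ideal_chair.carbons)
            fit, rmsd = kabsch_superpose(ideal_chair.carbons, moved)
            assert rmsd < 1e-9
            assert np.allclose(fit.rotation, t.rotation, atol=1e-8)
            assert np.linalg.det(fit.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_rmsd_invariant_to_prerotation_of_both_sets(self, ideal_chair):
        rng = np.random.default_rng(3)
        a = ideal_chair.carbons
        b = a + 0.1 * rng.standard_normal(a.shape)
        _, rmsd0 = kabsch_superpose(a, b)
        pre = random_rigid(rng)
        _, rmsd1 = kabsch_superpose(pre.apply(a), pre.apply(b))
        assert rmsd1 == pytest.approx(rmsd0, abs=1e-9)

    def test_no_reflection_even_for_mirrored_target(self, ideal_chair):
        mirrored = ideal_chair.carbons * np.array([1.0, 1.0, -1.0])
        fit, _ = kabsch_superpose(ideal_chair.carbons, mirrored)
        assert np.linalg.det(fit.rotation) == pytest.approx(1.0, abs=1e-9)
        fit2, rmsd2 = kabsch_superpose(
            ideal_chair.carbons, mirrored, allow_reflection=True
        )
        assert np.linalg.det(fit2.rotation) == pytest.approx(-1.0, abs=1e-9)
        assert rmsd2 < 1e-12

    def test_jitter_rmsd_matches_monte_carlo_expectation(self, ideal_chair):
        """After fitting, the mean squared residual of N jittered points
        approaches sigma^2 * (3N - 6)/N: 3N noisy coordinates minus the 6
        rigid-body degrees of freedom absorbed by the fit."""
        rng = np.random.default_rng(42)
        sigma = 0.05
        n = 6
        rmsds = []
        for _ in range(400):
            jittered = ideal_chair.carbons + sigma * rng.standard_normal((n, 3))
            _, rmsd = kabsch_superpose(ideal_chair.carbons, jittered)
            rmsds.append(rmsd ** 2)
        observed = np.sqrt(np.mean(rmsds))
        expected = sigma * np.sqrt((3 * n - 6.0) / n)
        assert observed == pytest.approx(expected, rel=0.05)

    def test_degenerate_input_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(ValueError):
            kabsch_superpose(line, line)
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestPdbIO:
    def test_roundtrip(self, ideal_chair, tmp_path):
        path = tmp_path / "ring.pdb"
        write_ring_pdb(ideal_chair, path)
        coords = read_ring_pdb(path)
        assert coords.shape == (6, 3)
        # PDB format stores 3 decimal places
        assert np.allclose(coords, ideal_chair.carbons, atol=5e-4)
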