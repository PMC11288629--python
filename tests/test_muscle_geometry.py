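"""Path geometry: frame transforms, length additivity, the finite
difference moment-arm oracle, polynomial derivatives, and the
force-to-torque sign convention."""

import json
from importlib import resources

import numpy as np
import pytest

from diffeffector import muscle_geometry as mg
from diffeffector.core_kinematics import PointMassParams, TwoLinkParams


@pytest.fixture(scope="module")
def arm_paths():
    spec = json.loads(
        (resources.files("diffeffector") / "data" / "arm26_paths.json").read_text())
    return mg.load_muscle_paths(spec["muscles"])


@pytest.fixture(scope="module")
def poly_params():
    spec = json.loads(
        (resources.files("diffeffector") / "data" /
         "arm26_moment_arm_poly.json").read_text())
    return [mg.PolynomialPathParams(a0=r["a0"], a1s=r["a1s"], a1e=r["a1e"],
                                    a2e=r["a2e"], name=r["name"])
            for r in spec["muscles"]]


def x_path(anchor):
    return mg.MusclePath("pm", [mg.FixationPoint(0, np.asarray(anchor, float)),
                                mg.FixationPoint(1, np.zeros(2))])


class TestResolvePathPoints:
    def test_world_point_invariant(self, arm_params):
        path = mg.MusclePath("sf", [mg.FixationPoint(0, [-0.15, 0.03]),
                                    mg.FixationPoint(1, [0.094, 0.017])])
        for q in ([0.3, 0.4], [1.2, 2.0]):
            pts = mg.resolve_path_points(path, np.atleast_2d(q), arm_params)
            np.testing.assert_allclose(np.asarray(pts[0]), [[-0.15, 0.03]])

    def test_identity_rotation(self, arm_params):
        path = mg.MusclePath("m", [mg.FixationPoint(0, [0, 0]),
                                   mg.FixationPoint(1, [0.094, 0.017])])
        pts = mg.resolve_path_points(path, np.array([[0.0, 0.0]]), arm_params)
        np.testing.assert_allclose(np.asarray(pts[1]), [[0.094, 0.017]], atol=1e-15)

    def test_quarter_turn(self, arm_params):
        path = mg.MusclePath("m", [mg.FixationPoint(0, [0, 0]),
                                   mg.FixationPoint(1, [0.094, 0.017])])
        pts = mg.resolve_path_points(path, np.array([[np.pi / 2, 0.0]]), arm_params)
        np.testing.assert_allclose(np.asarray(pts[1]), [[-0.017, 0.094]], atol=1e-12)

    def test_unknown_body(self, arm_params):
        path = mg.MusclePath("m", [mg.FixationPoint(0, [0, 0]),
                                   mg.FixationPoint(5, [0.1, 0.0])])
        with pytest.raises(ValueError):
            mg.resolve_path_points(path, np.zeros((1, 2)), arm_params)


class TestMusculotendonLength:
    def test_345_triangle(self):
        assert np.asarray(mg.musculotendon_length(
            [np.array([[0.0, 0.0]]), np.array([[3.0, 4.0]])])) == 5.0

    def test_additivity(self):
        pts = [np.array([[0.0, 0.0]]), np.array([[1.0, 0.0]]), np.array([[1.0, 1.0]])]
        assert np.asarray(mg.musculotendon_length(pts)) == 2.0

    def test_collinear_midpoint_no_change(self):
        direct = np.asarray(mg.musculotendon_length(
            [np.array([[0.0, 0.0]]), np.array([[2.0, 2.0]])]))
        via = np.asarray(mg.musculotendon_length(
            [np.array([[0.0, 0.0]]), np.array([[1.0, 1.0]]), np.array([[2.0, 2.0]])]))
        np.testing.assert_allclose(via, direct, rtol=1e-12)

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            mg.musculotendon_length([np.zeros((1, 2))])


class TestGeometricMomentArms:
    def test_finite_difference_oracle_256_states(self, arm_paths, arm_params, rng):
        """Analytic moment arms equal central differences of path length."""
        h = 1e-4
        worst = 0.0
        for _ in range(256):
            q = rng.uniform([0.05, 0.05], [2.3, 2.65], (1, 2))
            _, mas = mg.geometric_moment_arms(arm_paths, q, arm_params)
            for j in range(2):
                dq = np.zeros((1, 2))
                dq[0, j] = h
                lp, _ = mg.geometric_moment_arms(arm_paths, q + dq, arm_params)
                lm, _ = mg.geometric_moment_arms(arm_paths, q - dq, arm_params)
                fd = (np.asarray(lp) - np.asarray(lm)) / (2 * h)
                worst = max(worst, np.abs(fd - np.asarray(mas[j])).max())
        assert worst < 1e-6

    def test_monoarticular_elbow_muscle_zero_shoulder_ma(self, arm_paths,
                                                         arm_params, rng):
        names = [p.name for p in arm_paths]
        ee = names.index("elbow_extensor")
        ef = names.index("elbow_flexor")
        q = rng.uniform(0.1, 2.2, (16, 2))
        _, mas = mg.geometric_moment_arms(arm_paths, q, arm_params)
        np.testing.assert_allclose(np.asarray(mas[0])[:, ee], 0.0, atol=1e-12)
        np.testing.assert_allclose(np.asarray(mas[0])[:, ef], 0.0, atol=1e-12)

    def test_pointmass_centre_moment_arm(self):
        """Upper-right anchor at (2,2), point at origin: shortening the
        muscle raises x and y, so both moment arms are -sqrt(2)/2."""
        _, mas = mg.path_length_and_moment_arms(x_path([2, 2]), np.zeros((1, 2)),
                                                PointMassParams())
        for j in range(2):
            np.testing.assert_allclose(np.asarray(mas[j]), -np.sqrt(2) / 2,
                                       rtol=1e-12)

    def test_pointmass_diagonal_invariance(self):
        path = x_path([2, 2])
        for j in range(2):
            vals = []
            for q in ([[1.0, 1.0]], [[-1.0, -1.0]], [[0.5, 0.5]]):
                _, mas = mg.path_length_and_moment_arms(path, np.array(q),
                                                        PointMassParams())
                vals.append(np.asarray(mas[j]).item())
            np.testing.assert_allclose(vals, vals[0], rtol=1e-12)

    def test_lower_right_muscle_sign_structure(self):
        """At the workspace centre the lower-right muscle's moment arm is
        negative w.r.t. x (shortening increases x) and positive w.r.t. y."""
        _, mas = mg.path_length_and_moment_arms(x_path([2, -2]), np.zeros((1, 2)),
                                                PointMassParams())
        assert np.asarray(mas[0]).item() < 0
        assert np.asarray(mas[1]).item() > 0

    def test_degenerate_path_raises(self):
        path = x_path([0, 0])
        with pytest.raises(ArithmeticError):
            mg.path_length_and_moment_arms(path, np.zeros((1, 2)), PointMassParams())


class TestPolynomialMomentArms:
    def test_shoulder_flexor_zero_elbow_ma(self, poly_params, rng):
        sf = next(p for p in poly_params if p.name == "shoulder_flexor")
        for _ in range(10):
            q = rng.uniform(0, 2.3, (1, 2))
            _, mas = mg.polynomial_length_and_moment_arms(sf, q)
            assert np.asarray(mas[1]).item() == 0.0

    def test_elbow_flexor_affine_elbow_ma(self, poly_params):
        ef = next(p for p in poly_params if p.name == "elbow_flexor")
        for qe in (0.0, 0.7, 1.9):
            q = np.array([[0.4, qe]])
            _, mas = mg.polynomial_length_and_moment_arms(ef, q)
            np.testing.assert_allclose(np.asarray(mas[1]),
                                       ef.a1e + 2 * ef.a2e * qe, rtol=1e-12)
            # independent of the shoulder angle
            _, mas2 = mg.polynomial_length_and_moment_arms(
                ef, np.array([[1.8, qe]]))
            np.testing.assert_allclose(np.asarray(mas[1]), np.asarray(mas2[1]))

    def test_constant_coefficients_only(self):
        p = mg.PolynomialPathParams(a0=0.25)
        length, mas = mg.polynomial_length_and_moment_arms(p, np.array([[0.9, 1.4]]))
        np.testing.assert_allclose(np.asarray(length), 0.25)
        np.testing.assert_allclose(np.asarray(mas[0]), 0.0)
        np.testing.assert_allclose(np.asarray(mas[1]), 0.0)

    def test_derivative_matches_finite_difference(self, poly_params, rng):
        h = 1e-6
        q = rng.uniform(0.1, 2.2, (1, 2))
        lengths, mas = mg.polynomial_length_and_moment_arms(poly_params, q)
        for j in range(2):
            dq = np.zeros((1, 2))
            dq[0, j] = h
            lp, _ = mg.polynomial_length_and_moment_arms(poly_params, q + dq)
            lm, _ = mg.polynomial_length_and_moment_arms(poly_params, q - dq)
            np.testing.assert_allclose((np.asarray(lp) - np.asarray(lm)) / (2 * h),
                                       np.asarray(mas[j]), atol=1e-8)

    def test_biarticular_flexor_both_negative_over_limit_box(self, poly_params):
        bf = next(p for p in poly_params if p.name == "biarticular_flexor")
        qs = np.linspace(0, np.deg2rad(135), 12)
        qe = np.linspace(0, np.deg2rad(155), 12)
        grid = np.stack(np.meshgrid(qs, qe, indexing="ij"), -1).reshape(-1, 2)
        _, mas = mg.polynomial_length_and_moment_arms(bf, grid)
        assert np.all(np.asarray(mas[0]) < 0)
        assert np.all(np.asarray(mas[1]) < 0)

    def test_flexor_extensor_sign_convention(self, poly_params):
        """Flexors have negative, extensors positive moment arms at the
        reference posture."""
        q = np.deg2rad([[45.0, 90.0]])
        by_name = {p.name: p for p in poly_params}
        for name, joint, sign in [
            ("shoulder_flexor", 0, -1), ("shoulder_extensor", 0, +1),
            ("elbow_flexor", 1, -1), ("elbow_extensor", 1, +1),
            ("biarticular_flexor", 0, -1), ("biarticular_flexor", 1, -1),
            ("biarticular_extensor", 0, +1), ("biarticular_extensor", 1, +1),
        ]:
            _, mas = mg.polynomial_length_and_moment_arms(by_name[name], q)
            assert np.sign(np.asarray(mas[joint]).item()) == sign, name

    def test_invalid_a0(self):
        with pytest.raises(ValueError):
            mg.PolynomialPathParams(a0=0.0)


class TestMuscleTorque:
    def test_zero_forces(self):
        tau = mg.muscle_torque([np.zeros((1, 3)), np.zeros((1, 3))],
                               np.zeros((1, 3)))
        np.testing.assert_array_equal(np.asarray(tau), [[0.0, 0.0]])

    def test_single_muscle_sign(self):
        ma = [np.array([[0.03]]), np.array([[0.0]])]
        tau = mg.muscle_torque(ma, np.array([[100.0]]))
        np.testing.assert_allclose(np.asarray(tau), [[-3.0, 0.0]])

    def test_symmetric_x_cancellation(self):
        """Equal pulls on all four point-mass muscles at the centre sum
        to zero generalized force (brute-force sum)."""
        anchors = [(2, 2), (2, -2), (-2, -2), (-2, 2)]
        mas = [[], []]
        for a in anchors:
            _, ma = mg.path_length_and_moment_arms(x_path(a), np.zeros((1, 2)),
                                                   PointMassParams())
            mas[0].append(np.asarray(ma[0]).item())
            mas[1].append(np.asarray(ma[1]).item())
        forces = np.full((1, 4), 250.0)
        tau = mg.muscle_torque([np.array([mas[0]]), np.array([mas[1]])], forces)
        np.testing.assert_allclose(np.asarray(tau), [[0.0, 0.0]], atol=1e-12)
        brute = -np.sum(np.array(mas) * 250.0, axis=1)
        np.testing.assert_allclose(np.asarray(tau)[0], brute, atol=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            mg.muscle_torque([np.zeros((1, 3))], np.zeros((1, 2)))
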