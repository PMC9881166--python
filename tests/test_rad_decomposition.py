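"""Angle decomposition: exactness, conventions and pairwise metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from radkit.rad_decomposition import (
    RADAngles,
    decompose,
    delta_theta,
    er_angle,
    nearest_neighbors,
    reconstruct,
)
from radkit.reference_frames import ReferenceFrame
from radkit.rigid_geometry import RigidTransform, rotation_about_axis


@pytest.fixture(scope="module")
def frame():
    axis = np.array([0.0, 0.0, 1.0])
    return ReferenceFrame(
        domain="body",
        axis_direction=axis,
        axis_point=np.array([10.0, -5.0, 2.0]),
        zero_tilt_direction=np.array([1.0, 0.0, 0.0]),
        frame_of="LSU_core",
        reference_angle_deg=8.0,
    )


def build(frame, phi, theta, psi, delta_x=(0.0, 0.0, 0.0)):
    """Construct the transform for given angles about the frame's axis point
    (independent of the reconstruct() under test)."""
    rot = rotation_about_axis(frame.axis_direction, phi)
    if theta:
        nodes = rotation_about_axis(frame.axis_direction, psi) @ frame.zero_tilt_direction
        rot = rotation_about_axis(nodes, theta) @ rot
    c = frame.axis_point
    return RigidTransform(rot, c - rot @ c + np.asarray(delta_x, float))


class TestDecompose:
    def test_identity(self, frame):
        out = decompose(RigidTransform.identity(), frame)
        assert out.phi_deg == pytest.approx(0.0, abs=1e-9)
        assert out.theta_deg == pytest.approx(0.0, abs=1e-9)
        assert out.psi_deg is None
        assert out.delta_x_norm == pytest.approx(0.0, abs=1e-12)

    def test_known_angles_recovered(self, frame):
        t = build(frame, 7.0, 3.0, 40.0)
        out = decompose(t, frame)
        assert out.phi_deg == pytest.approx(7.0, abs=1e-6)
        assert out.theta_deg == pytest.approx(3.0, abs=1e-6)
        assert out.psi_deg == pytest.approx(40.0, abs=1e-6)
        assert out.delta_x_norm == pytest.approx(0.0, abs=1e-9)
        # brute-force check: rebuild the matrix elementwise
        rebuilt = reconstruct(out, frame)
        assert np.allclose(rebuilt.rotation, t.rotation, atol=1e-9)
        assert np.allclose(rebuilt.translation, t.translation, atol=1e-9)

    def test_negative_phi_and_negative_psi(self, frame):
        out = decompose(build(frame, -12.5, 5.0, -110.0), frame)
        assert out.phi_deg == pytest.approx(-12.5, abs=1e-6)
        assert out.psi_deg == pytest.approx(-110.0, abs=1e-6)

    def test_pure_translation(self, frame):
        t = RigidTransform(np.eye(3), np.array([1.0, -2.0, 0.5]))
        out = decompose(t, frame)
        assert out.phi_deg == pytest.approx(0.0, abs=1e-9)
        assert out.theta_deg == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(out.delta_x, [1.0, -2.0, 0.5], atol=1e-12)

    def test_small_theta_flags_psi_undefined(self, frame):
        out = decompose(build(frame, 9.0, 0.1, 50.0), frame)
        assert out.psi_deg is None
        assert out.phi_deg == pytest.approx(9.0, abs=0.05)

    def test_delta_x_recovered_when_minimal(self, frame):
        """A residual translation orthogonal to the axis-displacement
        direction is returned verbatim."""
        phi, theta, psi = 6.0, 4.0, 25.0
        t0 = build(frame, phi, theta, psi)
        # displacement direction of axis points under the rotation
        a_axis = (t0.rotation - np.eye(3)) @ frame.axis_direction
        dx = np.cross(a_axis, frame.axis_direction)
        dx *= 2.0 / np.linalg.norm(dx)
        out = decompose(build(frame, phi, theta, psi, delta_x=dx), frame)
        assert out.delta_x_norm == pytest.approx(2.0, abs=1e-9)

    @given(st.integers(0, 100_000))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_reconstruction_is_exact_for_any_transform(self, frame, seed):
        """decompose → reconstruct is the identity on rigid transforms
        (rotation and translation to 1e-9) whenever θ is resolvable."""
        rng = np.random.default_rng(seed)
        t = RigidTransform(
            Rotation.random(rng=rng).as_matrix(), rng.normal(0, 20, 3)
        )
        out = decompose(t, frame, theta_tolerance_deg=1e-12)
        rebuilt = reconstruct(out, frame)
        assert np.allclose(rebuilt.rotation, t.rotation, atol=1e-9)
        assert np.allclose(rebuilt.translation, t.translation, atol=1e-8)

    def test_delta_x_invariant_to_axis_anchor_shift(self, frame):
        """Sliding the frame's anchor point along the axis line changes
        neither x_c nor the minimized |Δx|."""
        t = build(frame, 10.0, 6.0, 70.0, delta_x=(0.3, 1.1, -0.4))
        out0 = decompose(t, frame)
        shifted = ReferenceFrame(
            domain=frame.domain,
            axis_direction=frame.axis_direction,
            axis_point=frame.axis_point + 37.5 * frame.axis_direction,
            zero_tilt_direction=frame.zero_tilt_direction,
            frame_of=frame.frame_of,
            reference_angle_deg=frame.reference_angle_deg,
        )
        out1 = decompose(t, shifted)
        assert out1.delta_x_norm == pytest.approx(out0.delta_x_norm, abs=1e-9)
        assert np.allclose(out1.x_c, out0.x_c, atol=1e-6)

    def test_zero_tilt_consistency_with_er_angle(self, frame):
        """With no tilt the Euler–Rodrigues angle to the reference equals
        the magnitude of the primary rotation."""
        for phi in (-15.0, -2.0, 3.0, 20.0):
            t = build(frame, phi, 0.0, 0.0)
            out = decompose(t, frame)
            assert out.theta_deg == pytest.approx(0.0, abs=1e-9)
            assert er_angle(t, RigidTransform.identity()) == pytest.approx(
                abs(phi), abs=1e-9
            )
            assert out.phi_deg == pytest.approx(phi, abs=1e-9)


class TestPairwiseMetrics:
    def test_er_angle_zero_iff_equal(self, frame):
        t = build(frame, 5.0, 2.0, 30.0)
        assert er_angle(t, t) == pytest.approx(0.0, abs=1e-9)

    def test_er_angle_same_axis_additivity(self, frame):
        a = build(frame, 5.0, 0.0, 0.0)
        b = build(frame, 8.0, 0.0, 0.0)
        assert er_angle(a, b) == pytest.approx(3.0, abs=1e-9)
        assert er_angle(b, a) == pytest.approx(3.0, abs=1e-9)

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_er_angle_matches_quaternion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ra, rb = (Rotation.random(rng=rng) for _ in range(2))
        expected = np.degrees((ra * rb.inv()).magnitude())  # quaternion distance
        got = er_angle(
            RigidTransform(ra.as_matrix()), RigidTransform(rb.as_matrix())
        )
        assert got == pytest.approx(expected, abs=1e-9)

    def test_delta_theta_ignores_primary_rotation(self, frame):
        a = build(frame, -3.0, 0.0, 0.0)
        b = build(frame, 12.0, 0.0, 0.0)
        assert delta_theta(a, b, frame) == pytest.approx(0.0, abs=1e-9)

    def test_delta_theta_same_direction_is_difference_of_tilts(self, frame):
        a = build(frame, 4.0, 2.0, 55.0)
        b = build(frame, -6.0, 5.0, 55.0)
        assert delta_theta(a, b, frame) == pytest.approx(3.0, abs=1e-9)

    def test_delta_theta_opposite_directions_add(self, frame):
        a = build(frame, 0.0, 3.0, 20.0)
        b = build(frame, 0.0, 3.0, -160.0)
        assert delta_theta(a, b, frame) == pytest.approx(6.0, abs=1e-9)

    @given(st.integers(0, 1000), st.floats(-170, 170))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_delta_theta_invariant_to_own_axis_rotation(self, frame, seed, gamma):
        rng = np.random.default_rng(seed)
        a = build(frame, rng.uniform(-20, 20), rng.uniform(0, 10), rng.uniform(-180, 180))
        b = build(frame, rng.uniform(-20, 20), rng.uniform(0, 10), rng.uniform(-180, 180))
        base = delta_theta(a, b, frame)
        # extra rotation about a's own current axis
        current_axis = a.rotation @ frame.axis_direction
        a_extra = RigidTransform(rotation_about_axis(current_axis, gamma)) @ a
        assert delta_theta(a_extra, b, frame) == pytest.approx(base, abs=1e-8)


class TestNearestNeighbors:
    def test_phi_gap_ordering(self, frame):
        ensemble = [("s0", 0.0), ("s1", 1.0), ("s5", 5.0)]
        out = {r["accession"]: r for r in nearest_neighbors(ensemble, metric="phi-gap")}
        assert out["s0"]["distance_deg"] == pytest.approx(1.0)
        assert out["s5"]["distance_deg"] == pytest.approx(4.0)
        assert out["s5"]["neighbor"] == "s1"

    def test_er_nearest(self, frame):
        ensemble = [
            ("s0", build(frame, 0.0, 0.0, 0.0)),
            ("s1", build(frame, 1.0, 0.0, 0.0)),
            ("s5", build(frame, 5.0, 0.0, 0.0)),
        ]
        out = {r["accession"]: r for r in nearest_neighbors(ensemble)}
        assert out["s5"]["neighbor"] == "s1"
        assert out["s5"]["distance_deg"] == pytest.approx(4.0, abs=1e-9)

    def test_duplicates_have_zero_distance(self, frame):
        t = build(frame, 3.0, 1.0, 10.0)
        out = nearest_neighbors([("a", t), ("b", t), ("c", build(frame, 9, 0, 0))])
        by = {r["accession"]: r for r in out}
        assert by["a"]["distance_deg"] == pytest.approx(0.0, abs=1e-9)
        assert by["a"]["neighbor"] == "b"

    def test_matches_brute_force_oracle(self, frame):
        rng = np.random.default_rng(77)
        rots = Rotation.random(40, rng=rng)
        ensemble = [(f"s{i}", RigidTransform(r.as_matrix())) for i, r in enumerate(rots)]
        got = nearest_neighbors(ensemble)
        # independent all-pairs oracle via quaternion distances
        mats = np.array([np.degrees((a * b.inv()).magnitude()) for a in rots for b in rots]).reshape(40, 40)
        np.fill_diagonal(mats, np.inf)
        for i, rec in enumerate(got):
            assert rec["neighbor"] == f"s{int(np.argmin(mats[i]))}"
            assert rec["distance_deg"] == pytest.approx(mats[i].min(), abs=1e-9)
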