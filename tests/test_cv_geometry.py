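"""Parabolic-solid CV mapping: round trips, gradients, walls."""

import numpy as np
import pytest

from lvmetad.cv_geometry import (
    CVTriple,
    THETA_REG_LENGTH,
    VolumeSpec,
    axial_wall_energy,
    compute_cvs,
    cv_gradients,
    cvs_and_gradients,
    invert_cvs,
    restraint_potential,
    wall_energy,
    wall_gradient_cvs,
    wrap_angle,
)
from lvmetad.errors import GeometryError, ParameterError


def _random_interior_points(vol, rng, n=40):
    """Cartesian points strictly inside the paraboloid volume."""
    pts = []
    e1, e2 = vol.transverse_basis()
    while len(pts) < n:
        a = rng.uniform(vol.a0 + 0.8, vol.a0 + 5.0)
        tau = rng.uniform(0.05, 0.95 * vol.tau_max)
        theta = rng.uniform(-np.pi, np.pi)
        rp = tau * np.sqrt(vol.steepness * (a - vol.a0))
        p = vol.origin + a * vol.axis + rp * (np.cos(theta) * e1 + np.sin(theta) * e2)
        pts.append(p)
    return np.asarray(pts)


class TestComputeCvs:
    def test_on_axis_point(self, generic_volume):
        vol = generic_volume
        host = vol.origin
        guest = vol.origin + 3.0 * vol.axis
        cvs = compute_cvs(guest, host, vol)
        assert cvs.rho == pytest.approx(3.0, abs=1e-12)
        assert cvs.tau == pytest.approx(0.0, abs=1e-12)
        assert cvs.theta == 0.0  # tie-break convention

    def test_paraboloid_surface_is_tau_one(self, generic_volume):
        vol = generic_volume
        e1, _ = vol.transverse_basis()
        a = vol.a0 + 2.0
        rp = np.sqrt(vol.steepness * (a - vol.a0))
        guest = vol.origin + a * vol.axis + rp * e1
        cvs = compute_cvs(guest, vol.origin, vol)
        assert cvs.tau == pytest.approx(1.0, rel=1e-12)

    def test_behind_apex_is_degenerate(self, generic_volume):
        vol = generic_volume
        guest = vol.origin + (vol.a0 - 0.1) * vol.axis
        with pytest.raises(GeometryError):
            compute_cvs(guest, vol.origin, vol)

    def test_theta_equivariant_under_axial_rotation(self, generic_volume, rng):
        """Rotating the guest about the axis by alpha shifts theta by alpha."""
        vol = generic_volume
        host = vol.origin
        for p in _random_interior_points(vol, rng, n=10):
            alpha = rng.uniform(-3, 3)
            base = compute_cvs(p, host, vol)
            r = p - vol.origin
            a = float(r @ vol.axis)
            r_perp = r - a * vol.axis
            e1, e2 = vol.transverse_basis()
            c, s = np.cos(alpha), np.sin(alpha)
            v1, v2 = float(r_perp @ e1), float(r_perp @ e2)
            rotated = vol.origin + a * vol.axis + (c * v1 - s * v2) * e1 + (s * v1 + c * v2) * e2
            rot = compute_cvs(rotated, host, vol)
            assert wrap_angle(rot.theta - base.theta - alpha) == pytest.approx(0.0, abs=1e-9)
            assert rot.tau == pytest.approx(base.tau, rel=1e-9)

    def test_tau_scales_with_transverse_coordinates(self, generic_volume, rng):
        vol = generic_volume
        for p in _random_interior_points(vol, rng, n=5):
            r = p - vol.origin
            a = float(r @ vol.axis)
            r_perp = r - a * vol.axis
            c = 0.5
            shrunk = vol.origin + a * vol.axis + c * r_perp
            t1 = compute_cvs(p, vol.origin, vol).tau
            t2 = compute_cvs(shrunk, vol.origin, vol).tau
            assert t2 == pytest.approx(c * t1, rel=1e-10)


class TestRoundTrip:
    def test_cartesian_to_cv_and_back(self, generic_volume, rng):
        vol = generic_volume
        host = vol.origin + np.array([0.2, -0.1, 0.0])
        for p in _random_interior_points(vol, rng, n=25):
            cvs = compute_cvs(p, host, vol)
            if cvs.rho > vol.rho_max or cvs.tau > vol.tau_max:
                continue
            back = invert_cvs(cvs, host, vol)
            assert np.linalg.norm(back - p) < 1e-10

    def test_cv_to_cartesian_and_back(self, generic_volume):
        vol = generic_volume
        host = vol.origin
        cvs = CVTriple(rho=4.0, tau=0.6, theta=1.1)
        p = invert_cvs(cvs, host, vol)
        again = compute_cvs(p, host, vol)
        assert again.rho == pytest.approx(cvs.rho, abs=1e-10)
        assert again.tau == pytest.approx(cvs.tau, abs=1e-10)
        assert again.theta == pytest.approx(cvs.theta, abs=1e-10)

    def test_tau_zero_recovers_axis_point(self, generic_volume):
        vol = generic_volume
        p = invert_cvs(CVTriple(rho=5.0, tau=0.0, theta=2.0), vol.origin, vol)
        assert np.linalg.norm(p - vol.origin) == pytest.approx(5.0, abs=1e-10)
        r_perp = (p - vol.origin) - ((p - vol.origin) @ vol.axis) * vol.axis
        assert np.linalg.norm(r_perp) < 1e-10

    def test_out_of_volume_cvs_rejected(self, generic_volume):
        with pytest.raises(GeometryError):
            invert_cvs(CVTriple(rho=3.0, tau=2.0 * generic_volume.tau_max, theta=0.0),
                       generic_volume.origin, generic_volume)


class TestGradients:
    def test_rho_gradient_is_unit_vector(self, generic_volume):
        vol = generic_volume
        host = vol.origin
        guest = vol.origin + 2.0 * vol.axis + np.array([0.0, 0.4, 0.2])
        g_rho, _, _ = cv_gradients(guest, host, vol)
        expect = (guest - host) / np.linalg.norm(guest - host)
        np.testing.assert_allclose(g_rho, expect, atol=1e-12)

    def test_all_gradients_match_finite_differences(self, generic_volume, rng):
        vol = generic_volume
        host = vol.origin + np.array([0.1, 0.05, -0.2])
        h = 1e-5
        for p in _random_interior_points(vol, rng, n=15):
            grads = cv_gradients(p, host, vol)
            for q, grad in zip(range(3), grads):
                for d in range(3):
                    dp = np.zeros(3)
                    dp[d] = h
                    hi = compute_cvs(p + dp, host, vol)
                    lo = compute_cvs(p - dp, host, vol)
                    vals_hi = (hi.rho, hi.tau, hi.theta)
                    vals_lo = (lo.rho, lo.tau, lo.theta)
                    diff = vals_hi[q] - vals_lo[q]
                    if q == 2:
                        diff = wrap_angle(diff)
                    fd = diff / (2 * h)
                    assert grad[d] == pytest.approx(fd, rel=1e-6, abs=1e-7)

    def test_on_axis_theta_gradient_is_capped(self, generic_volume):
        vol = generic_volume
        guest = vol.origin + 2.5 * vol.axis
        _, _, g_theta = cv_gradients(guest, vol.origin, vol)
        assert np.all(np.isfinite(g_theta))
        assert np.linalg.norm(g_theta) <= 1.0 / THETA_REG_LENGTH + 1e-12

    def test_fused_path_agrees_with_separate_calls(self, generic_volume, rng):
        vol = generic_volume
        host = vol.origin + np.array([0.3, 0.0, 0.1])
        for p in _random_interior_points(vol, rng, n=5):
            cvs = compute_cvs(p, host, vol)
            grads = cv_gradients(p, host, vol)
            fused_cvs, g_r, g_t, g_th, _ = cvs_and_gradients(p, host, vol)
            assert fused_cvs.rho == pytest.approx(cvs.rho, abs=1e-14)
            assert fused_cvs.tau == pytest.approx(cvs.tau, abs=1e-14)
            assert fused_cvs.theta == pytest.approx(cvs.theta, abs=1e-14)
            for a, b in zip(grads, (g_r, g_t, g_th)):
                np.testing.assert_allclose(a, b, atol=1e-14)


class TestWalls:
    def test_zero_inside_volume(self, generic_volume):
        assert wall_energy(CVTriple(1.0, 0.5, 0.3), generic_volume) == 0.0

    def test_rho_wall_quadratic(self):
        vol = VolumeSpec(origin=np.zeros(3), axis=[1, 0, 0], steepness=1.0, a0=0.0,
                         rho_max=5.0, tau_max=1.0, wall_k=10.0)
        assert wall_energy(CVTriple(6.0, 0.5, 0.0), vol) == pytest.approx(10.0)

    def test_wall_gradients_match_energy(self, generic_volume):
        vol = generic_volume
        cvs = CVTriple(vol.rho_max + 0.7, vol.tau_max + 0.2, 0.1)
        d_rho, d_tau, d_theta = wall_gradient_cvs(cvs, vol)
        h = 1e-6
        fd_rho = (wall_energy(CVTriple(cvs.rho + h, cvs.tau, cvs.theta), vol)
                  - wall_energy(CVTriple(cvs.rho - h, cvs.tau, cvs.theta), vol)) / (2 * h)
        fd_tau = (wall_energy(CVTriple(cvs.rho, cvs.tau + h, cvs.theta), vol)
                  - wall_energy(CVTriple(cvs.rho, cvs.tau - h, cvs.theta), vol)) / (2 * h)
        assert d_rho == pytest.approx(fd_rho, rel=1e-6)
        assert d_tau == pytest.approx(fd_tau, rel=1e-6)
        assert d_theta == 0.0

    def test_axial_wall_engages_below_a_min(self, generic_volume):
        vol = generic_volume
        e, g = axial_wall_energy(vol.a_min - 0.5, vol)
        assert e == pytest.approx(vol.wall_k * 0.25)
        assert g < 0
        assert axial_wall_energy(vol.a_min + 0.1, vol) == (0.0, 0.0)

    def test_cartesian_restraint_gradient_matches_fd(self, generic_volume, rng):
        vol = generic_volume
        host = vol.origin
        pot = restraint_potential(vol, host)
        pts = _random_interior_points(vol, rng, n=12)
        pts = pts + rng.normal(scale=2.0, size=pts.shape)  # push some outside the walls
        keep = (pts - vol.origin) @ vol.axis > vol.a0 + 0.6
        pts = pts[keep]
        h = 1e-6
        for d in range(3):
            dx = np.zeros(3)
            dx[d] = h
            fd = (pot.energy(pts + dx) - pot.energy(pts - dx)) / (2 * h)
            np.testing.assert_allclose(pot.gradient(pts)[:, d], fd, rtol=1e-4, atol=1e-6)


class TestVolumeSpec:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            VolumeSpec(origin=np.zeros(3), axis=[1, 0, 0], steepness=-1.0, a0=0.0,
                       rho_max=5.0, tau_max=1.0, wall_k=10.0)
        with pytest.raises(ParameterError):
            VolumeSpec(origin=np.zeros(3), axis=[1, 0, 0], steepness=1.0, a0=0.0,
                       rho_max=5.0, tau_max=1.0, wall_k=10.0, a_min=-1.0)

    def test_axis_normalized_and_basis_orthonormal(self):
        vol = VolumeSpec(origin=np.zeros(3), axis=[3, 4, 0], steepness=1.0, a0=0.0,
                         rho_max=5.0, tau_max=1.0, wall_k=1.0)
        assert np.linalg.norm(vol.axis) == pytest.approx(1.0, abs=1e-14)
        e1, e2 = vol.transverse_basis()
        for v in (e1, e2):
            assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-12)
            assert abs(v @ vol.axis) < 1e-12
        assert abs(e1 @ e2) < 1e-12

    def test_wrap_angle_range(self):
        assert wrap_angle(np.pi) == pytest.approx(np.pi)
        assert wrap_angle(-np.pi) == pytest.approx(np.pi)
        assert wrap_angle(3 * np.pi / 2) == pytest.approx(-np.pi / 2)
        arr = wrap_angle(np.array([0.0, 2 * np.pi, -3 * np.pi]))
        np.testing.assert_allclose(arr, [0.0, 0.0, np.pi])
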