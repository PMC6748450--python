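"""Curvature-wave evaluation, midline reconstruction, and the
momentum-conserving body frame."""

import numpy as np
import pytest

import swimtorque as st
from swimtorque._spectral import time_derivative
from swimtorque.kinematics import (
    KinematicsSpec,
    MidlineState,
    curvature_field,
    default_grids,
    kinematic_derivatives,
    make_midline,
    midline_from_curvature,
    momentum_conserving_frame,
)


class TestCurvatureField:
    def test_published_eel_parameters_at_tail(self):
        # kappa(1, 0) = 11.41 * e^0 * sin(2*pi/0.59)
        spec = KinematicsSpec.eel()
        kappa, _ = curvature_field(spec, np.array([0.0, 1.0]), np.array([0.0]))
        assert kappa[1, 0] == pytest.approx(11.41 * np.sin(2 * np.pi / 0.59), abs=1e-12)
        assert kappa[1, 0] == pytest.approx(-10.7334, abs=5e-4)

    def test_zero_envelope_gives_zero_field(self):
        spec = KinematicsSpec(envelope_kind="carangiform", a0=0.0, k=2 * np.pi)
        kappa, kdot = curvature_field(spec, *default_grids(11, 8, 1))
        assert not kappa.any() and not kdot.any()

    def test_mackerel_head_at_t0_is_zero(self):
        kappa, _ = curvature_field(
            KinematicsSpec.mackerel(), np.array([0.0]), np.array([0.0]))
        assert kappa[0, 0] == 0.0

    def test_kappadot_is_analytic_derivative(self):
        spec = KinematicsSpec.eel()
        s, t = default_grids(31, 64, 1)
        kappa, kdot = curvature_field(spec, s, t)
        assert np.allclose(kdot, time_derivative(kappa, t[1] - t[0]), atol=1e-8)

    def test_unknown_envelope_rejected(self):
        with pytest.raises(st.ConfigurationError):
            KinematicsSpec(envelope_kind="thunniform")


class TestMidlineFromCurvature:
    def test_zero_curvature_is_straight_unit_segment(self):
        s = np.linspace(0, 1, 101)
        x, y, theta = midline_from_curvature(np.zeros_like(s), s)
        assert np.hypot(x[-1] - x[0], y[-1] - y[0]) == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(theta, 0.0)

    def test_constant_full_turn_closes_circle(self):
        s = np.linspace(0, 1, 401)
        x, y, _ = midline_from_curvature(np.full_like(s, 2 * np.pi), s)
        assert np.hypot(x[-1] - x[0], y[-1] - y[0]) < 1e-6

    def test_path_length_constancy_and_convergence(self):
        # the parametrization is unit-speed; the chord-sum estimate of the
        # path length is 1 to discretization accuracy, improving as O(h^2)
        spec = KinematicsSpec.eel()
        errs = []
        for ns in (201, 401):
            s, t = default_grids(ns, 16, 1)
            kappa, _ = curvature_field(spec, s, t)
            x, y, _ = midline_from_curvature(kappa, s)
            L = np.sum(np.hypot(np.diff(x, axis=0), np.diff(y, axis=0)), axis=0)
            errs.append(np.max(np.abs(L - 1.0)))
        assert errs[0] < 2e-4
        assert errs[1] < 0.3 * errs[0]

    def test_theta_derivative_recovers_curvature(self):
        spec = KinematicsSpec.mackerel()
        s, t = default_grids(401, 4, 1)
        kappa, _ = curvature_field(spec, s, t)
        _, _, theta = midline_from_curvature(kappa, s)
        kappa_fd = np.gradient(theta, s, axis=0)
        interior = slice(2, -2)
        assert np.max(np.abs(kappa_fd[interior] - kappa[interior])) < 1e-3


class TestMomentumConservingFrame:
    def test_rigid_drifting_body_is_brought_to_rest(self):
        s, t = default_grids(51, 32, 1)
        x = s[:, None] + 0.3 * t[None, :] * 0  # straight rod
        # add a rigid-body periodic drift
        shift = 0.1 * np.sin(2 * np.pi * t)
        mid = MidlineState(
            s=s, t=t, x=np.broadcast_to(s[:, None], (51, 32)).copy(),
            y=np.broadcast_to(shift, (51, 32)).copy(),
            theta=np.zeros((51, 32)), kappa=np.zeros((51, 32)),
            kappadot=np.zeros((51, 32)))
        out = momentum_conserving_frame(mid, np.ones_like(s))
        assert np.max(np.abs(out.vx)) < 1e-10
        assert np.max(np.abs(out.vy)) < 1e-10

    def test_residuals_below_tolerance(self, suite):
        for fx in suite.values():
            assert fx.midline.residuals["linear"] < 1e-8
            assert fx.midline.residuals["angular"] < 1e-8

    def test_curvature_unchanged_by_frame_transform(self):
        spec = KinematicsSpec.eel()
        raw = make_midline(spec, ns=81, nt=64, n_periods=1, frame="raw")
        out = momentum_conserving_frame(raw, np.ones_like(raw.s))
        assert np.max(np.abs(out.kappa - raw.kappa)) < 1e-12
        # and the tangent-angle derivative still matches the curvature
        dtheta = np.gradient(out.theta, out.s, axis=0)
        # finite-difference recovery limited by kappa'' h^2 at this grid
        assert np.max(np.abs(dtheta[2:-2] - out.kappa[2:-2])) < 5e-2

    def test_residual_decreases_with_tighter_tolerance(self):
        spec = KinematicsSpec.mackerel()
        res = []
        for tol in (1e-4, 1e-8):
            mid = make_midline(spec, ns=81, nt=64, n_periods=1, tol=tol)
            res.append(mid.residuals["angular"])
        assert res[1] <= res[0]


class TestKinematicDerivatives:
    def test_stationary_midline_has_zero_rates(self, small_midline):
        s, t = small_midline.s, small_midline.t
        mid = MidlineState(
            s=s, t=t, x=np.broadcast_to(s[:, None], (len(s), len(t))).copy(),
            y=np.zeros((len(s), len(t))), theta=np.zeros((len(s), len(t))),
            kappa=np.zeros((len(s), len(t))), kappadot=np.zeros((len(s), len(t))))
        out = kinematic_derivatives(mid)
        assert np.max(np.abs(out.vx)) < 1e-12 and np.max(np.abs(out.ay)) < 1e-12

    def test_harmonic_acceleration_identity(self):
        s = np.linspace(0, 1, 11)
        t = np.arange(64) / 64.0
        y = 1e-3 * np.sin(2 * np.pi * t)[None, :] * np.ones((11, 1))
        mid = MidlineState(s=s, t=t, x=np.zeros_like(y), y=y.copy(),
                           theta=np.zeros_like(y), kappa=np.zeros_like(y),
                           kappadot=np.zeros_like(y))
        out = kinematic_derivatives(mid)
        assert np.allclose(out.ay, -(2 * np.pi) ** 2 * y, atol=1e-12)

    def test_nonuniform_time_grid_rejected(self, small_midline):
        bad = small_midline.copy()
        bad.t = bad.t.copy()
        bad.t[3] += 1e-3
        with pytest.raises(st.ConfigurationError):
            kinematic_derivatives(bad)


def test_small_amplitude_matches_linear_theory():
    """At infinitesimal amplitude the momentum-conserving lateral motion
    converges to the linearized solution (double integration of kappa
    plus the zero-momentum rigid modes)."""
    eps = 1e-3
    spec = KinematicsSpec(envelope_kind="carangiform", a0=eps, k=2 * np.pi)
    mid = make_midline(spec, ns=201, nt=128, n_periods=1)
    s, t = mid.s, mid.t
    kappa0 = eps
    c1 = -3.0 * kappa0 / (2.0 * np.pi**3)
    c0 = -0.5 * c1
    Yhat = (1j * kappa0 * np.exp(2j * np.pi * s) / (4 * np.pi**2) + c0 + c1 * s)
    y_lin = np.real(Yhat[:, None] * np.exp(-2j * np.pi * t)[None, :])
    err = np.max(np.abs(mid.y - y_lin)) / np.max(np.abs(y_lin))
    assert err < 1e-3


def test_midline_table_roundtrip(tmp_path, small_midline):
    from swimtorque.io import read_midline, write_midline

    path = tmp_path / "mid.csv"
    write_midline(path, small_midline)
    back = read_midline(path)
    for name in ("x", "y", "theta", "kappa", "kappadot", "vx", "vy", "ax", "ay"):
        assert np.max(np.abs(getattr(back, name) - getattr(small_midline, name))) < 1e-12
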