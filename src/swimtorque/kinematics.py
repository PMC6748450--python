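"""Midline kinematics from a prescribed traveling curvature wave.

The deformation of an undulatory swimmer is prescribed as a curvature wave

    kappa(s, t) = A(s) * sin(k*s - omega_u*t),

with arc length s in [0, 1] (head at 0, tail at 1, body length = 1) and
the undulation period as the unit of time (omega_u = 2*pi).  Two standard
amplitude envelopes are supported:

* anguilliform (eel-like):   A(s) = a_max * exp(s - 1)
* carangiform (mackerel-like): A(s) = a0 + a1*s + a2*s**2

The midline is reconstructed by integrating the tangent angle, and the
whole-body rotation/translation left free by the curvature prescription is
fixed by requiring that the motion, in the absence of external forces,
conserves linear and angular momentum ("recoil" correction).  All time
derivatives are spectral over the periodic time axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_simpson, cumulative_trapezoid, simpson

from ._spectral import check_uniform, time_antiderivative, time_derivative
from .errors import ConfigurationError, ConvergenceError

OMEGA_U = 2.0 * np.pi


@dataclass(frozen=True)
class KinematicsSpec:
    """Parametric traveling curvature wave.

    Parameters
    ----------
    envelope_kind : {"anguilliform", "carangiform"}
        Shape of the curvature amplitude envelope A(s).
    a_max : float
        Tail curvature amplitude (anguilliform envelope only), 1/body length.
    a0, a1, a2 : float
        Polynomial envelope coefficients (carangiform envelope only).
    k : float
        Wavenumber of the body undulation, rad/body length.
    """

    envelope_kind: str
    a_max: float = 0.0
    a0: float = 0.0
    a1: float = 0.0
    a2: float = 0.0
    k: float = 2.0 * np.pi
    omega_u: float = OMEGA_U
    period: float = 1.0

    def __post_init__(self) -> None:
        if self.envelope_kind not in ("anguilliform", "carangiform"):
            raise ConfigurationError(
                f"unknown envelope_kind {self.envelope_kind!r}; "
                "expected 'anguilliform' or 'carangiform'"
            )
        if self.k <= 0:
            raise ConfigurationError("wavenumber k must be positive")

    @property
    def wavelength(self) -> float:
        return 2.0 * np.pi / self.k

    def amplitude(self, s: np.ndarray) -> np.ndarray:
        """Curvature amplitude envelope A(s)."""
        s = np.asarray(s, dtype=float)
        if self.envelope_kind == "anguilliform":
            return self.a_max * np.exp(s - 1.0)
        return self.a0 + self.a1 * s + self.a2 * s**2

    @classmethod
    def eel(cls) -> "KinematicsSpec":
        """Anguilliform kinematics: a_max = 11.41, lambda = 0.59."""
        return cls(envelope_kind="anguilliform", a_max=11.41, k=2.0 * np.pi / 0.59)

    @classmethod
    def mackerel(cls) -> "KinematicsSpec":
        """Carangiform kinematics: A(s) = 1 - 3.2 s + 5.6 s^2, lambda = 1.0."""
        return cls(
            envelope_kind="carangiform", a0=1.0, a1=-3.2, a2=5.6, k=2.0 * np.pi / 1.0
        )


@dataclass
class MidlineState:
    """Space-time midline fields on a rectangular (s, t) grid.

    Arrays are shaped (Ns, Nt).  ``frame`` is one of "raw",
    "momentum-conserving", or "lab".
    """

    s: np.ndarray
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    theta: np.ndarray
    kappa: np.ndarray
    kappadot: np.ndarray
    vx: np.ndarray | None = None
    vy: np.ndarray | None = None
    ax: np.ndarray | None = None
    ay: np.ndarray | None = None
    frame: str = "raw"
    period: float = 1.0
    residuals: dict = field(default_factory=dict)

    @property
    def tangent(self) -> tuple[np.ndarray, np.ndarray]:
        return np.cos(self.theta), np.sin(self.theta)

    @property
    def normal(self) -> tuple[np.ndarray, np.ndarray]:
        # left normal: 90 deg counterclockwise from the tangent
        return -np.sin(self.theta), np.cos(self.theta)

    def copy(self) -> "MidlineState":
        kw = {
            name: (getattr(self, name).copy() if getattr(self, name) is not None else None)
            for name in ("s", "t", "x", "y", "theta", "kappa", "kappadot",
                         "vx", "vy", "ax", "ay")
        }
        return MidlineState(frame=self.frame, period=self.period,
                            residuals=dict(self.residuals), **kw)


def default_grids(
    ns: int = 201, nt: int = 256, n_periods: int = 2, period: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Default s and t grids: s in [0, 1] inclusive; t endpoint-exclusive."""
    s = np.linspace(0.0, 1.0, ns)
    t = np.arange(nt * n_periods) * (period / nt)
    return s, t


def curvature_field(
    spec: KinematicsSpec, s_grid: np.ndarray, t_grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate kappa(s,t) and its analytic time derivative on the grid.

    kappa    =  A(s) sin(k s - omega_u t)
    kappadot = -A(s) omega_u cos(k s - omega_u t)
    """
    s = np.asarray(s_grid, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    if s.ndim != 1 or np.any(np.diff(s) <= 0):
        raise ConfigurationError("s_grid must be 1-D strictly increasing")
    if s[0] < -1e-12 or s[-1] > 1.0 + 1e-12:
        raise ConfigurationError("s_grid must lie in [0, 1]")
    if t.ndim != 1 or np.any(np.diff(t) <= 0):
        raise ConfigurationError("t_grid must be 1-D strictly increasing")
    amp = spec.amplitude(s)[:, None]
    phase = spec.k * s[:, None] - spec.omega_u * t[None, :]
    kappa = amp * np.sin(phase)
    kappadot = -amp * spec.omega_u * np.cos(phase)
    return kappa, kappadot


def midline_from_curvature(
    kappa: np.ndarray, s_grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate curvature to a unit-speed midline.

    theta(s) = theta_ref + int_0^s kappa ds';  r(s) = int_0^s (cos, sin) theta.
    theta_ref is chosen so the arc-length mean of theta vanishes (mean
    tangent along +x) and the head sits at the origin.

    Returns (x, y, theta), each shaped like kappa (Ns, Nt) or (Ns,).
    """
    s = np.asarray(s_grid, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    squeeze = kappa.ndim == 1
    if squeeze:
        kappa = kappa[:, None]
    if s.size >= 3:
        cumint = lambda f: cumulative_simpson(f, x=s, axis=0, initial=0.0)
        mean = lambda f: simpson(f, x=s, axis=0) / (s[-1] - s[0])
    else:
        cumint = lambda f: cumulative_trapezoid(f, s, axis=0, initial=0.0)
        mean = lambda f: np.trapezoid(f, s, axis=0) / (s[-1] - s[0])
    theta = cumint(kappa)
    theta -= mean(theta)
    x = cumint(np.cos(theta))
    y = cumint(np.sin(theta))
    if squeeze:
        return x[:, 0], y[:, 0], theta[:, 0]
    return x, y, theta


def kinematic_derivatives(midline: MidlineState) -> MidlineState:
    """Fill v and a by spectral differentiation over the periodic time axis."""
    dt = check_uniform(midline.t)
    out = midline.copy()
    out.vx = time_derivative(out.x, dt)
    out.vy = time_derivative(out.y, dt)
    out.ax = time_derivative(out.vx, dt)
    out.ay = time_derivative(out.vy, dt)
    return out


def _trapz_weights(s: np.ndarray) -> np.ndarray:
    w = np.zeros_like(s)
    w[1:] += 0.5 * np.diff(s)
    w[:-1] += 0.5 * np.diff(s)
    return w


def momentum_conserving_frame(
    midline: MidlineState,
    m_b: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 25,
) -> MidlineState:
    """Rotate/translate the body frame so the free motion conserves momentum.

    At every time sample the transformed motion satisfies (with mass per
    unit length m_b and trapezoidal quadrature)

        int m_b v ds           = 0   (both components; com pinned at origin)
        int m_b (r - r_c) x v ds = 0   (z-component)

    The linear condition is enforced exactly by pinning the center of mass
    at the origin.  The angular condition is enforced by a per-time yaw
    rate phidot = -L(t)/I(t) integrated spectrally; because spectral
    differentiation of the rotated fields does not commute exactly with
    the rotation, the correction is iterated to the residual tolerance.

    The curvature field (the shape) is unchanged by the transform.
    """
    m_b = np.asarray(m_b, dtype=float)
    if np.any(m_b < 0):
        raise ConfigurationError("m_b must be nonnegative")
    s = midline.s
    w = _trapz_weights(s) * m_b
    M = float(np.sum(w))
    if M <= 0:
        raise ConfigurationError("total mass must be positive")
    dt = check_uniform(midline.t)
    period = midline.period

    out = midline.copy()
    x, y, theta = out.x.copy(), out.y.copy(), out.theta.copy()

    # momentum scale used to normalize residuals: M * L^2 / period
    scale = M * 1.0 / period

    lin_res = ang_res = np.inf
    for _ in range(max_iter):
        # pin the center of mass at the origin (exact linear-momentum fix)
        x = x - (w @ x) / M
        y = y - (w @ y) / M
        vx = time_derivative(x, dt)
        vy = time_derivative(y, dt)
        L = w @ (x * vy - y * vx)
        inertia = w @ (x**2 + y**2)
        ang_res = float(np.max(np.abs(L)) / scale)
        px = w @ vx
        py = w @ vy
        lin_res = float(max(np.max(np.abs(px)), np.max(np.abs(py))) / M)
        if ang_res < tol and lin_res < tol:
            break
        phidot = -L / inertia
        phi, _ = time_antiderivative(phidot, dt)
        c, sn = np.cos(phi), np.sin(phi)
        x, y = c * x - sn * y, sn * x + c * y
        theta = theta + phi
    else:
        raise ConvergenceError(
            "momentum-conserving frame did not converge: "
            f"angular residual {ang_res:.3e}, linear residual {lin_res:.3e} "
            f"(tolerance {tol:.1e})"
        )

    out.x, out.y, out.theta = x, y, theta
    out.frame = "momentum-conserving"
    out.residuals = {"linear": lin_res, "angular": ang_res}
    return kinematic_derivatives(out)


def make_midline(
    spec: KinematicsSpec,
    m_b: np.ndarray | None = None,
    ns: int = 201,
    nt: int = 256,
    n_periods: int = 2,
    frame: str = "momentum-conserving",
    tol: float = 1e-8,
) -> MidlineState:
    """Build a midline on default grids, optionally momentum-conserving.

    If ``m_b`` is None a uniform unit mass density is used for the frame
    correction (the frame conditions depend only on the normalized mass
    distribution).
    """
    s, t = default_grids(ns, nt, n_periods, spec.period)
    kappa, kappadot = curvature_field(spec, s, t)
    x, y, theta = midline_from_curvature(kappa, s)
    mid = MidlineState(
        s=s, t=t, x=x, y=y, theta=theta, kappa=kappa, kappadot=kappadot,
        frame="raw", period=spec.period,
    )
    if frame == "raw":
        return kinematic_derivatives(mid)
    if frame != "momentum-conserving":
        raise ConfigurationError(f"unknown frame {frame!r}")
    if m_b is None:
        m_b = np.ones_like(s)
    return momentum_conserving_frame(mid, m_b, tol=tol)
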