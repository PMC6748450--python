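"""Internal torque and power fields along an undulating body.

The internal bending moment T(s, t) that muscles and passive tissue must
supply is obtained from the force balance of either body portion around
the point of interest, treating inertia as the d'Alembert load -m_b a so
the effective external load is G = F - m_b a:

    T_posterior(s, t) = -e_z . int_s^1 (r' - r(s)) x G dl
    T_anterior(s, t)  = +e_z . int_0^s (r' - r(s)) x G dl

The two agree when G carries zero net force and torque; their relative
error grows at the free ends where T -> 0, so the reported torque is the
weighted average T = s*T_posterior + (1 - s)*T_anterior.

Power bookkeeping: internal power per unit length P_T = T * kappadot and
power transferred to the fluid P_F = -F . v; over whole cycles the two
integrate to the same total (energy closure).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_simpson, simpson

from ._spectral import (
    check_uniform,
    fundamental_coefficient,
    n_cycles,
    wrap_phase,
)
from .bodies import BodyModel
from .errors import ConfigurationError, ConsistencyError
from .forces import ForceField, project_rigid_modes, _body_weights
from .kinematics import MidlineState


@dataclass
class TorqueField:
    """Internal torque (z-component) on the (s, t) grid."""

    s: np.ndarray
    t: np.ndarray
    T: np.ndarray
    T_posterior: np.ndarray
    T_anterior: np.ndarray
    balance_residual: dict | None = None


@dataclass
class PowerFields:
    """Internal/external power distributions and per-cycle work budget."""

    s: np.ndarray
    t: np.ndarray
    P_T: np.ndarray
    P_F: np.ndarray | None = None
    W: np.ndarray | None = None        # cycle work of P_T at each s
    W_plus: np.ndarray | None = None   # positive-part cycle work
    P_tot: float | None = None
    P_tot_plus: float | None = None


@dataclass
class WaveSpeedEstimate:
    """Traveling-wave speed of a field's fundamental temporal harmonic."""

    phase: np.ndarray              # unwrapped phase over the full s grid
    s: np.ndarray
    window: tuple[float, float]
    slope: float                   # d(phase)/ds over the window
    speed: float                   # omega_u / |slope|; inf when standing
    direction: str                 # "posterior" | "anterior" | "standing"
    r_squared: float
    fundamental_fraction: np.ndarray
    standing: bool = False


def torque_from_forces(
    force: ForceField,
    midline: MidlineState,
    body: BodyModel,
    balance: str = "project",
    tol: float = 1e-6,
) -> TorqueField:
    """Internal torque from a force field by two-sided integration.

    ``balance`` controls how an unbalanced effective load G = F - m_b a is
    handled: "project" (default) removes the rigid recoil modes — the free
    body's inertial reaction to the unbalanced load — before integrating;
    "strict" raises ConsistencyError if the normalized net force or torque
    residual exceeds ``tol``.
    """
    s = midline.s
    if force.s.shape != s.shape or np.max(np.abs(force.s - s)) > 1e-12:
        raise ConfigurationError("force and midline grids do not match")
    if midline.ax is None:
        from .kinematics import kinematic_derivatives

        midline = kinematic_derivatives(midline)
    mb = body.m_b[:, None]
    Gx = force.Fx - mb * midline.ax
    Gy = force.Fy - mb * midline.ay
    weights = _body_weights(body, s)
    Gx_p, Gy_p, diag = project_rigid_modes(Gx, Gy, midline, weights)
    if balance == "strict":
        if diag["net_force"] > tol or diag["net_torque"] > tol:
            raise ConsistencyError(
                "effective load F - m_b a is not momentum-consistent: "
                f"normalized net force {diag['net_force']:.3e}, "
                f"net torque {diag['net_torque']:.3e} exceed tol {tol:.1e}"
            )
    elif balance != "project":
        raise ConfigurationError(f"unknown balance mode {balance!r}")
    Gx, Gy = Gx_p, Gy_p

    # cumulative integrals from the head; cross terms expanded so the
    # moment arm about r(s) needs only running integrals
    x, y = midline.x, midline.y
    iGx = cumulative_simpson(Gx, x=s, axis=0, initial=0.0)
    iGy = cumulative_simpson(Gy, x=s, axis=0, initial=0.0)
    ixGy_yGx = cumulative_simpson(x * Gy - y * Gx, x=s, axis=0, initial=0.0)
    T_ant = ixGy_yGx - x * iGy + y * iGx
    # posterior integral = total - anterior piece, about the same point
    tot_xGy_yGx = ixGy_yGx[-1:, :]
    tot_Gx = iGx[-1:, :]
    tot_Gy = iGy[-1:, :]
    T_post = -((tot_xGy_yGx - ixGy_yGx) - x * (tot_Gy - iGy) + y * (tot_Gx - iGx))
    sw = s[:, None]
    T = sw * T_post + (1.0 - sw) * T_ant
    return TorqueField(s=s, t=midline.t, T=T, T_posterior=T_post,
                       T_anterior=T_ant, balance_residual=diag)


def internal_power(torque: TorqueField, kappadot: np.ndarray) -> np.ndarray:
    """P_T(s, t) = T * kappadot."""
    if torque.T.shape != np.shape(kappadot):
        raise ConfigurationError("torque and kappadot grids do not match")
    return torque.T * np.asarray(kappadot)


def external_power(force: ForceField, midline: MidlineState) -> np.ndarray:
    """P_F(s, t) = -F . v (power the body feeds into the fluid)."""
    if midline.vx is None:
        from .kinematics import kinematic_derivatives

        midline = kinematic_derivatives(midline)
    return -(force.Fx * midline.vx + force.Fy * midline.vy)


def work_budget(
    P_T: np.ndarray,
    s: np.ndarray,
    t: np.ndarray,
    period: float = 1.0,
    P_F: np.ndarray | None = None,
) -> PowerFields:
    """Per-cycle work profiles W(s), W+(s) and cycle-mean power totals.

    W(s) integrates P_T over one cycle (averaged over the whole cycles
    sampled); W+(s) integrates only the positive part — the muscle work
    when no storage or transfer of negative-power energy is possible.
    """
    ncyc = n_cycles(t, period)
    dt = check_uniform(t)
    W = np.sum(P_T, axis=1) * dt / ncyc
    W_plus = np.sum(np.maximum(P_T, 0.0), axis=1) * dt / ncyc
    P_tot = float(simpson(W, x=s) / period)
    P_tot_plus = float(simpson(W_plus, x=s) / period)
    return PowerFields(s=s, t=t, P_T=P_T, P_F=P_F, W=W, W_plus=W_plus,
                       P_tot=P_tot, P_tot_plus=P_tot_plus)


def wave_speed(
    field: np.ndarray,
    s: np.ndarray,
    t: np.ndarray,
    s_window: tuple[float, float] = (0.2, 0.9),
    period: float = 1.0,
    omega_u: float = 2.0 * np.pi,
    min_fundamental_fraction: float = 0.5,
    max_speed: float = 50.0,
) -> WaveSpeedEstimate:
    """Traveling-wave speed from the fundamental-harmonic phase profile.

    The per-s phase of the temporal fundamental is unwrapped along s
    (2*pi continuity) and fitted linearly over ``s_window``; the speed is
    omega_u / |slope| in body lengths per period.  A near-zero slope is
    reported as a standing wave (speed above the resolvable bound) rather
    than a number.
    """
    c = fundamental_coefficient(field, t, period)
    var = np.var(field, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(var > 0, 0.5 * np.abs(c) ** 2 / np.maximum(var, 1e-300), 0.0)
    phase = np.unwrap(np.angle(c))
    mask = (s >= s_window[0]) & (s <= s_window[1])
    if not np.any(mask):
        raise ConfigurationError("empty s_window")
    if np.any(frac[mask] < min_fundamental_fraction):
        warnings.warn(
            "fundamental harmonic carries < 50% of the temporal power at "
            "some s in the fit window; the wave-speed fit is ill-conditioned",
            stacklevel=2,
        )
    sw = s[mask]
    pw = phase[mask]
    slope, intercept = np.polyfit(sw, pw, 1)
    fit = slope * sw + intercept
    ss_res = float(np.sum((pw - fit) ** 2))
    ss_tot = float(np.sum((pw - pw.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    # a standing wave has a (anti)phase-locked complex profile: after
    # rotating by half the phase of sum(c^2), c is real up to noise —
    # this also catches the pi phase steps at amplitude nodes that a
    # slope threshold alone would misread as travel
    cw = c[mask]
    psi = 0.5 * np.angle(np.sum(cw**2))
    locked = float(np.max(np.abs(np.imag(cw * np.exp(-1j * psi))))
                   / max(np.max(np.abs(cw)), 1e-300))
    standing = locked < 0.05 or abs(slope) < omega_u / max_speed
    if standing:
        speed = np.inf
        direction = "standing"
    else:
        speed = omega_u / abs(slope)
        direction = "posterior" if slope > 0 else "anterior"
    return WaveSpeedEstimate(
        phase=phase, s=s, window=s_window, slope=float(slope),
        speed=float(speed), direction=direction, r_squared=r2,
        fundamental_fraction=frac, standing=standing,
    )


def phase_compare(
    force: ForceField,
    midline: MidlineState,
    period: float = 1.0,
    class_tol: float = np.pi / 12.0,
) -> dict:
    """Per-s phase of the lateral force against -v_y and -a_y.

    Classifies each s as resistive-like (force in phase with the negated
    velocity), reactive-like (in phase with the negated acceleration), or
    mixed.  Phase differences are wrapped to (-pi, pi].
    """
    if midline.ax is None:
        from .kinematics import kinematic_derivatives

        midline = kinematic_derivatives(midline)
    t = midline.t
    cF = fundamental_coefficient(force.Fy, t, period)
    cv = fundamental_coefficient(-midline.vy, t, period)
    ca = fundamental_coefficient(-midline.ay, t, period)
    dv = wrap_phase(np.angle(cF) - np.angle(cv))
    da = wrap_phase(np.angle(cF) - np.angle(ca))
    labels = np.where(
        np.abs(dv) <= class_tol, "resistive-like",
        np.where(np.abs(da) <= class_tol, "reactive-like", "mixed"),
    )
    return {
        "s": midline.s,
        "phase_force": np.unwrap(np.angle(cF)),
        "phase_neg_v": np.unwrap(np.angle(cv)),
        "phase_neg_a": np.unwrap(np.angle(ca)),
        "dphi_v": dv,
        "dphi_a": da,
        "classification": labels,
    }
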