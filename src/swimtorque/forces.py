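"""Hydrodynamic force-per-unit-length closures and reduced-order recoil.

Two theoretical closures are provided on the midline:

* resistive (drag-type):  F = -c_n v_n n - c_t v_t t
* reactive (added-mass):  F = -d/dt (m_a v_n n)

with v_n, v_t the normal/tangential velocity components, n the left
normal, and m_a the added mass per unit length.  Externally computed
force fields can be imported from delimited tables.  A 3-DOF rigid
recoil integrator (forward, lateral, yaw) turns a body-frame deformation
plus a closure into reduced-order free swimming, reporting the mean
speed U and Strouhal number St = f * A_pp / U.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._spectral import check_uniform, time_derivative
from .bodies import BodyModel, mass_properties
from .errors import ConfigurationError, ConvergenceError
from .io import read_field, write_field
from .kinematics import MidlineState, kinematic_derivatives


@dataclass
class ForceField:
    """Force per unit length exerted by the fluid on the body."""

    s: np.ndarray
    t: np.ndarray
    Fx: np.ndarray
    Fy: np.ndarray
    closure: str = "external"

    def save(self, path) -> None:
        write_field(path, self.s, self.t, Fx=self.Fx, Fy=self.Fy)


@dataclass
class SwimState:
    """Summary of a reduced-order free-swimming run."""

    U: float
    A_pp: float
    St: float
    heading: np.ndarray          # unit swimming direction (lab frame)
    yaw: np.ndarray              # yaw angle over the last cycle
    omega: np.ndarray            # yaw rate over the last cycle
    T_tot: np.ndarray            # net hydrodynamic torque over the last cycle
    cycle_speeds: list = field(default_factory=list)
    converged: bool = False

    def summary(self) -> dict:
        return {
            "U": self.U, "A_pp": self.A_pp, "St": self.St,
            "converged": self.converged,
            "cycle_speeds": list(self.cycle_speeds),
        }


def _normal_components(midline: MidlineState):
    nx, ny = midline.normal
    tx, ty = midline.tangent
    v_n = midline.vx * nx + midline.vy * ny
    v_t = midline.vx * tx + midline.vy * ty
    return nx, ny, tx, ty, v_n, v_t


def resistive_force(
    midline: MidlineState, body: BodyModel, quadratic: bool = False
) -> ForceField:
    """Drag-type closure, linear in the local velocity by default.

    The quadratic variant uses |v_n| v_n for the normal component.
    """
    if midline.vx is None:
        midline = kinematic_derivatives(midline)
    nx, ny, tx, ty, v_n, v_t = _normal_components(midline)
    cn = body.c_n[:, None]
    ct = body.c_t[:, None]
    fn = -cn * (np.abs(v_n) * v_n if quadratic else v_n)
    ft = -ct * v_t
    return ForceField(
        s=midline.s, t=midline.t,
        Fx=fn * nx + ft * tx, Fy=fn * ny + ft * ty,
        closure="resistive",
    )


def reactive_force(midline: MidlineState, body: BodyModel) -> ForceField:
    """Added-mass closure: F = -d/dt (m_a v_n n), evaluated spectrally."""
    if midline.vx is None:
        midline = kinematic_derivatives(midline)
    nx, ny, _, _, v_n, _ = _normal_components(midline)
    ma = body.m_a[:, None]
    wx = ma * v_n * nx
    wy = ma * v_n * ny
    dt = check_uniform(midline.t)
    return ForceField(
        s=midline.s, t=midline.t,
        Fx=-time_derivative(wx, dt), Fy=-time_derivative(wy, dt),
        closure="reactive",
    )


def mixed_force(
    midline: MidlineState, body: BodyModel, resistive_weight: float = 0.5
) -> ForceField:
    """Convex combination of the resistive and reactive closures."""
    fr = resistive_force(midline, body)
    fa = reactive_force(midline, body)
    w = resistive_weight
    return ForceField(
        s=midline.s, t=midline.t,
        Fx=w * fr.Fx + (1 - w) * fa.Fx, Fy=w * fr.Fy + (1 - w) * fa.Fy,
        closure="mixed",
    )


def load_force_field(path) -> ForceField:
    """Read an externally computed force field from a delimited table."""
    s, t, f = read_field(path, ("Fx", "Fy"))
    return ForceField(s=s, t=t, Fx=f["Fx"], Fy=f["Fy"], closure="external")


def _body_weights(body: BodyModel | None, s: np.ndarray) -> np.ndarray:
    """Mass weights for the rigid-mode projection; uniform for massless bodies."""
    if body is None or body.mass <= 0:
        return np.ones_like(s)
    return body.m_b


def project_rigid_modes(
    Gx: np.ndarray, Gy: np.ndarray, midline: MidlineState, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Remove the net force and net torque of a load field at every time.

    Subtracts a mass-weighted rigid-mode force distribution

        d = w(s) [ F_net / W + alpha * J (r - r_c) ],  alpha = tau_net / I_w,

    which is the inertial reaction of the free body recoiling under the
    unbalanced part of the load.  Returns the projected components and
    the residual diagnostics (pre-projection net force / torque scales).
    The quadrature matches the torque integration (Simpson), so the
    projected load has exactly zero net force and torque under it.
    """
    from scipy.integrate import simpson

    s = midline.s
    integ = lambda f: simpson(f, x=s, axis=0)
    w = np.asarray(weights, dtype=float)
    W = float(integ(w))
    xc = integ(w[:, None] * midline.x) / W
    yc = integ(w[:, None] * midline.y) / W
    rx = midline.x - xc
    ry = midline.y - yc
    fnx = integ(Gx)
    fny = integ(Gy)
    tau = integ(rx * Gy - ry * Gx)
    inertia = integ(w[:, None] * (rx**2 + ry**2))
    alpha = tau / inertia
    Gx2 = Gx - w[:, None] * (fnx / W - alpha * ry)
    Gy2 = Gy - w[:, None] * (fny / W + alpha * rx)
    scale = max(np.max(np.abs(Gx)), np.max(np.abs(Gy)), 1e-300)
    diag = {
        "net_force": float(max(np.max(np.abs(fnx)), np.max(np.abs(fny))) / scale),
        "net_torque": float(np.max(np.abs(tau)) / scale),
    }
    return Gx2, Gy2, diag


# ---------------------------------------------------------------------------
# 3-DOF rigid recoil (reduced-order free swimming)
# ---------------------------------------------------------------------------


def _rot(phi: float) -> np.ndarray:
    c, s = np.cos(phi), np.sin(phi)
    return np.array([[c, -s], [s, c]])


class _RecoilRHS:
    """Force assembly for the 3-DOF Newton-Euler recoil equations.

    The reactive closure is linear in the unknown rigid accelerations
    (added mass), so each evaluation solves a 3x3 system
    (M_rb + A_added) qddot = rhs instead of treating the added-mass force
    explicitly (which would be unstable whenever m_a is comparable to m_b).
    """

    def __init__(self, midline: MidlineState, body: BodyModel, closure: str):
        if closure not in ("resistive", "reactive", "mixed", "none"):
            raise ConfigurationError(f"unknown closure {closure!r}")
        self.closure = closure
        self.body = body
        self.s = midline.s
        dt = check_uniform(midline.t)
        self.mid = midline
        self.thetadot_b = time_derivative(midline.theta, dt)
        props = mass_properties(body, midline)
        self.M = props["M"]
        self.inertia = props["I"]
        self.idot = props["Idot"]
        # com of the body-frame midline (should be ~0 in the momentum frame)
        self.xc = props["com"][0]
        self.yc = props["com"][1]

    def __call__(self, j: int, q: np.ndarray) -> np.ndarray:
        """Time derivative of q = (X, Y, Phi, Ux, Uy, Om) at grid index j."""
        X, Y, Phi, Ux, Uy, Om = q
        m = self.mid
        s = self.s
        R = _rot(Phi)
        xb = m.x[:, j] - self.xc[j]
        yb = m.y[:, j] - self.yc[j]
        vxb, vyb = m.vx[:, j], m.vy[:, j]
        axb, ayb = m.ax[:, j], m.ay[:, j]
        # lab-frame relative position, velocity, known part of acceleration
        rx = R[0, 0] * xb + R[0, 1] * yb
        ry = R[1, 0] * xb + R[1, 1] * yb
        vdx = R[0, 0] * vxb + R[0, 1] * vyb - Om * ry
        vdy = R[1, 0] * vxb + R[1, 1] * vyb + Om * rx
        vx = Ux + vdx
        vy = Uy + vdy
        akx = (R[0, 0] * axb + R[0, 1] * ayb
               - 2.0 * Om * (R[1, 0] * vxb + R[1, 1] * vyb) - Om**2 * rx)
        aky = (R[1, 0] * axb + R[1, 1] * ayb
               + 2.0 * Om * (R[0, 0] * vxb + R[0, 1] * vyb) - Om**2 * ry)
        theta = m.theta[:, j] + Phi
        nx, ny = -np.sin(theta), np.cos(theta)
        tx, ty = np.cos(theta), np.sin(theta)
        thetadot = self.thetadot_b[:, j] + Om

        F0x = np.zeros_like(s)
        F0y = np.zeros_like(s)
        use_res = self.closure in ("resistive", "mixed")
        use_rea = self.closure in ("reactive", "mixed")
        wmix = 0.5 if self.closure == "mixed" else 1.0
        if use_res:
            v_n = vx * nx + vy * ny
            v_t = vx * tx + vy * ty
            fn = -self.body.c_n * v_n
            ft = -self.body.c_t * v_t
            F0x += wmix * (fn * nx + ft * tx)
            F0y += wmix * (fn * ny + ft * ty)
        A = np.zeros((3, 3))
        if use_rea:
            ma = wmix * self.body.m_a
            v_n = vx * nx + vy * ny
            # d n/dt = -thetadot * t
            ndotx, ndoty = -thetadot * tx, -thetadot * ty
            vdotn = vx * ndotx + vy * ndoty
            acc_n = akx * nx + aky * ny
            F0x += -(ma * (acc_n + vdotn) * nx + ma * v_n * ndotx)
            F0y += -(ma * (acc_n + vdotn) * ny + ma * v_n * ndoty)
            jr_n = rx * ny - ry * nx  # cross(r, n) = (J r) . n
            A[0, 0] = np.trapezoid(ma * nx * nx, s)
            A[0, 1] = A[1, 0] = np.trapezoid(ma * nx * ny, s)
            A[1, 1] = np.trapezoid(ma * ny * ny, s)
            A[0, 2] = A[2, 0] = np.trapezoid(ma * jr_n * nx, s)
            A[1, 2] = A[2, 1] = np.trapezoid(ma * jr_n * ny, s)
            A[2, 2] = np.trapezoid(ma * jr_n * jr_n, s)

        fnet = np.array([np.trapezoid(F0x, s), np.trapezoid(F0y, s)])
        tau = np.trapezoid(rx * F0y - ry * F0x, s)
        lhs = A + np.diag([self.M, self.M, self.inertia[j]])
        rhs = np.array([fnet[0], fnet[1], tau - self.idot[j] * Om])
        acc = np.linalg.solve(lhs, rhs)
        self.last_tau = tau
        return np.array([Ux, Uy, Om, acc[0], acc[1], acc[2]])


def integrate_rigid_recoil(
    midline: MidlineState,
    body: BodyModel,
    closure: str = "resistive",
    U0: float = 0.3,
    max_cycles: int = 40,
    speed_tol: float = 0.02,
    substeps: int = 4,
) -> tuple[SwimState, MidlineState]:
    """Integrate forward/lateral/yaw free swimming driven by a closure.

    The body-frame deformation (momentum-conserving midline) is replayed
    periodically while Newton-Euler equations d(M U)/dt = F_net and
    d(I omega)/dt = T_tot are advanced with an RK4 scheme.  Fish-like
    bodies are nearly massless relative to their hydrodynamic damping
    (M ~ 1e-3 in these units), which makes the recoil dynamics stiff;
    the deformation is Fourier-resampled so each stored sample is covered
    by ``substeps`` RK4 steps.  Integration stops when the cycle-mean
    speed changes by less than ``speed_tol`` relative between
    consecutive cycles.

    Returns the swim summary and the lab-frame midline over the last cycle.
    """
    if midline.frame != "momentum-conserving":
        raise ConfigurationError("recoil integration requires a momentum-conserving midline")
    if substeps < 1:
        raise ConfigurationError("substeps must be >= 1")
    dt = check_uniform(midline.t)
    per_cycle = int(round(midline.period / dt))
    # refine so RK4 midpoints of every substep land on stored samples
    fine = _resample_time(midline, 2 * substeps)
    rhs = _RecoilRHS(fine, body, closure)
    h = dt / substeps

    q = np.array([0.0, 0.0, 0.0, -U0, 0.0, 0.0])
    n_fine = fine.t.shape[0]
    hist_q = []
    hist_tau = []
    cycle_speeds: list[float] = []
    converged = False
    cyc = 0
    j = 0
    while cyc < max_cycles:
        start = np.array([q[0], q[1]])
        cycle_q = []
        cycle_tau = []
        for step in range(per_cycle * substeps):
            if step % substeps == 0:
                cycle_q.append(q.copy())
            k1 = rhs(j % n_fine, q)
            tau0 = rhs.last_tau
            k2 = rhs((j + 1) % n_fine, q + 0.5 * h * k1)
            k3 = rhs((j + 1) % n_fine, q + 0.5 * h * k2)
            k4 = rhs((j + 2) % n_fine, q + h * k3)
            q = q + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            if step % substeps == 0:
                cycle_tau.append(tau0)
            j += 2
        disp = np.hypot(q[0] - start[0], q[1] - start[1])
        U = disp / midline.period
        cycle_speeds.append(float(U))
        hist_q = cycle_q
        hist_tau = cycle_tau
        cyc += 1
        if closure == "none":
            converged = True
            break
        if cyc >= 3 and abs(cycle_speeds[-1] - cycle_speeds[-2]) <= (
            speed_tol * max(abs(cycle_speeds[-1]), 1e-12)
        ):
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            "recoil integration did not reach a steady cycle-mean speed; "
            f"cycle speeds: {[round(u, 5) for u in cycle_speeds]}"
        )

    qs = np.array(hist_q)  # (per_cycle, 6)
    # lab-frame midline over the last cycle
    lab = _lab_midline(midline, qs, per_cycle)
    heading_vec = np.array([q[0] - qs[0, 0], q[1] - qs[0, 1]])
    norm = np.hypot(*heading_vec)
    heading = heading_vec / norm if norm > 0 else np.array([-1.0, 0.0])
    lateral = np.array([-heading[1], heading[0]])
    tail = np.stack([lab.x[-1, :], lab.y[-1, :]])
    lat = lateral @ tail
    A_pp = float(np.max(lat) - np.min(lat))
    U = cycle_speeds[-1]
    St = (1.0 / midline.period) * A_pp / U if U > 0 else np.inf
    state = SwimState(
        U=float(U), A_pp=A_pp, St=float(St), heading=heading,
        yaw=qs[:, 2], omega=qs[:, 5], T_tot=np.array(hist_tau),
        cycle_speeds=cycle_speeds, converged=converged,
    )
    return state, lab


def _resample_time(midline: MidlineState, factor: int) -> MidlineState:
    """Fourier-resample all time-dependent fields onto a finer grid."""
    if midline.vx is None:
        midline = kinematic_derivatives(midline)
    n = midline.t.shape[0]
    dt = check_uniform(midline.t)
    m = n * factor
    out = midline.copy()
    out.t = midline.t[0] + np.arange(m) * (dt / factor)

    def up(f):
        fh = np.fft.rfft(f, axis=-1)
        pad = np.zeros((f.shape[0], m // 2 + 1), dtype=complex)
        pad[:, : fh.shape[1]] = fh
        return np.fft.irfft(pad, n=m, axis=-1) * factor

    for name in ("x", "y", "theta", "kappa", "kappadot", "vx", "vy", "ax", "ay"):
        setattr(out, name, up(getattr(midline, name)))
    return out


def _lab_midline(midline: MidlineState, qs: np.ndarray, per_cycle: int) -> MidlineState:
    lab = midline.copy()
    ncols = midline.t.shape[0]
    reps = ncols // per_cycle
    qfull = np.tile(qs, (reps, 1))[:ncols]
    X, Y, Phi = qfull[:, 0], qfull[:, 1], qfull[:, 2]
    c, sn = np.cos(Phi), np.sin(Phi)
    lab.x = c * midline.x - sn * midline.y + X
    lab.y = sn * midline.x + c * midline.y + Y
    lab.theta = midline.theta + Phi
    Ux, Uy, Om = qfull[:, 3], qfull[:, 4], qfull[:, 5]
    rx = lab.x - X
    ry = lab.y - Y
    vbx = c * midline.vx - sn * midline.vy
    vby = sn * midline.vx + c * midline.vy
    lab.vx = Ux + vbx - Om * ry
    lab.vy = Uy + vby + Om * rx
    lab.ax = None
    lab.ay = None
    lab.frame = "lab"
    return lab
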