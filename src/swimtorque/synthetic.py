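"""Synthetic fixtures: CFD-emulating force fields and joint series.

Everything the analysis pipeline consumes can be generated here with
controlled structure: lateral force fields whose per-station phase
interpolates between the negated velocity (resistive-like) and the
negated acceleration (reactive-like), harmonic joint torque/curvature
series with prescribed phase orderings, and ready-to-run eel/mackerel
parameter bundles.  All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._spectral import fundamental_coefficient
from .bodies import BodyModel, eel_profile, mackerel_profile
from .errors import ConfigurationError
from .forces import ForceField, project_rigid_modes, _body_weights
from .kinematics import KinematicsSpec, MidlineState, kinematic_derivatives, make_midline


@dataclass(frozen=True)
class SyntheticForceSpec:
    """Lateral force field with controllable phase structure.

    ``alpha`` in [0, pi/2] sets the per-station phase relative to the
    negated lateral velocity: 0 is resistive-like, pi/2 reactive-like
    (the negated acceleration leads the negated velocity by pi/2).
    ``alpha`` may be a scalar or a callable of s.
    """

    alpha: object = 0.0
    amplitude: object = 1.0     # scalar or callable of s
    noise: float = 0.0
    seed: int = 0

    def alpha_of(self, s: np.ndarray) -> np.ndarray:
        a = self.alpha(s) if callable(self.alpha) else np.full_like(s, self.alpha)
        if np.any(a < -1e-12) or np.any(a > np.pi / 2 + 1e-12):
            raise ConfigurationError("alpha must lie in [0, pi/2]")
        return a

    def amplitude_of(self, s: np.ndarray) -> np.ndarray:
        return (self.amplitude(s) if callable(self.amplitude)
                else np.full_like(s, self.amplitude))


def make_force_field(
    spec: SyntheticForceSpec,
    midline: MidlineState,
    body: BodyModel | None = None,
    project: bool = True,
) -> ForceField:
    """Generate a lateral force field with the requested phase structure.

    With ``project=True`` (default) the field is afterwards projected to
    zero net force and net torque at every time — required for a
    well-posed torque integration, but the projection shifts the per-s
    phases slightly; generate with ``project=False`` to verify phase
    recovery exactly.
    """
    if midline.vx is None:
        midline = kinematic_derivatives(midline)
    s, t = midline.s, midline.t
    omega = 2.0 * np.pi / midline.period
    cv = fundamental_coefficient(-midline.vy, t, midline.period)
    unit = np.where(np.abs(cv) > 0, cv / np.maximum(np.abs(cv), 1e-300), 1.0)
    alpha = spec.alpha_of(s)
    amp = spec.amplitude_of(s)
    # -a leads -v by pi/2 under the Re[c exp(-i omega t)] convention
    Fhat = amp * unit * np.exp(-1j * alpha)
    Fy = np.real(Fhat[:, None] * np.exp(-1j * omega * t)[None, :])
    if spec.noise > 0:
        rng = np.random.default_rng(spec.seed)
        Fy = Fy + spec.noise * rng.standard_normal(Fy.shape)
    Fx = np.zeros_like(Fy)
    if project:
        Fx, Fy, _ = project_rigid_modes(Fx, Fy, midline, _body_weights(body, s))
    return ForceField(s=s, t=t, Fx=Fx, Fy=Fy, closure="external")


@dataclass(frozen=True)
class JointSeriesSpec:
    """Harmonic torque/curvature-rate series at two joints.

    Each series is amp * sin(omega t + phase) (+ optional harmonics and
    noise).  Phases are radians.
    """

    amp_T1: float = 1.0
    amp_T2: float = 0.6
    amp_kd1: float = 1.0
    amp_kd2: float = 1.3
    phi_T1: float = 0.3
    phi_T2: float = -0.8
    phi_kd1: float = 0.3
    phi_kd2: float = -1.9
    harmonics: tuple = ()       # (order, relative amp) pairs added to all series
    noise: float = 0.0
    seed: int = 0

    @classmethod
    def carangiform_ordering(cls) -> "JointSeriesSpec":
        """Preset with the worked phase ordering phi_kd1 ~ phi_T1 > phi_T2 > phi_kd2.

        Because phi_kd1 is not behind phi_T1, only stages I-III occur.
        """
        return cls()


def make_joint_series(
    spec: JointSeriesSpec, nt: int = 256, n_periods: int = 1, period: float = 1.0
):
    """Return (t, T_1, T_2, kd_1, kd_2) harmonic series."""
    t = np.arange(nt * n_periods) * (period / nt)
    omega = 2.0 * np.pi / period
    rng = np.random.default_rng(spec.seed)

    def series(amp, phi):
        x = amp * np.sin(omega * t + phi)
        for order, rel in spec.harmonics:
            x = x + amp * rel * np.sin(order * omega * t + phi)
        if spec.noise > 0:
            x = x + spec.noise * rng.standard_normal(t.shape)
        return x

    return (
        t,
        series(spec.amp_T1, spec.phi_T1),
        series(spec.amp_T2, spec.phi_T2),
        series(spec.amp_kd1, spec.phi_kd1),
        series(spec.amp_kd2, spec.phi_kd2),
    )


@dataclass
class Fixture:
    """One swimmer's ready-to-run configuration."""

    name: str
    spec: KinematicsSpec
    body: BodyModel
    midline: MidlineState
    manifest: dict = field(default_factory=dict)


def fixture_suite(ns: int = 201, nt: int = 256, n_periods: int = 2) -> dict:
    """Eel and mackerel kinematics + bodies + momentum-conserving midlines."""
    out = {}
    for name, spec, maker in (
        ("eel", KinematicsSpec.eel(), eel_profile),
        ("mackerel", KinematicsSpec.mackerel(), mackerel_profile),
    ):
        body = maker(ns)
        mid = make_midline(spec, m_b=body.m_b, ns=ns, nt=nt, n_periods=n_periods)
        manifest = {
            "name": name,
            "envelope_kind": spec.envelope_kind,
            "a_max": spec.a_max, "a0": spec.a0, "a1": spec.a1, "a2": spec.a2,
            "wavelength": spec.wavelength,
            "mass": body.mass,
            "ns": ns, "nt": nt, "n_periods": n_periods,
            "frame_residuals": mid.residuals,
        }
        out[name] = Fixture(name=name, spec=spec, body=body, midline=mid,
                            manifest=manifest)
    return out
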