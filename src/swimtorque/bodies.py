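"""Parametric body property profiles.

The mass distribution, geometry envelopes, and hydrodynamic coefficient
profiles used by the recoil, force, and torque computations.  Profiles are
smooth parametric stand-ins for scanned fish geometries, scaled to the
target total masses (fluid density = 1, body length = 1): M = 0.0019 for
the eel-like body and M = 0.0101 for the mackerel-like body.

The mass per unit length assumes an elliptical cross-section,
m_b(s) = (pi/4) * w(s) * h(s), with density equal to the fluid.  The
added-mass profile defaults to that of a section of height h,
m_a(s) = pi * h(s)^2 / 4.  The resistive coefficients default to
c_n = 1 and c_t = 0.1 * c_n; the source measurements provide no closure
coefficients, so these are configurable package choices.
"""

from __future__ import annotations

from dataclasses import dataclass, replace  # noqa: F401  (replace used below)

import numpy as np
from scipy.interpolate import PchipInterpolator

from ._spectral import check_uniform, time_derivative
from .errors import ConfigurationError

SECTION_FACTOR = np.pi / 4.0  # elliptical cross-section area factor

EEL_MASS = 0.0019
MACKEREL_MASS = 0.0101


@dataclass(frozen=True)
class BodyModel:
    """Body property profiles on an arc-length grid."""

    s: np.ndarray
    m_b: np.ndarray  # mass per unit length
    h: np.ndarray    # section height (out-of-plane)
    w: np.ndarray    # section width (in-plane)
    m_a: np.ndarray  # added mass per unit length
    c_n: np.ndarray  # normal resistive coefficient
    c_t: np.ndarray  # tangential resistive coefficient

    def __post_init__(self) -> None:
        if np.any(self.m_b < -1e-15):
            raise ConfigurationError("m_b must be nonnegative")

    @property
    def mass(self) -> float:
        """Total mass M = int m_b ds."""
        return float(np.trapezoid(self.m_b, self.s))

    def scaled_to_mass(self, mass: float) -> "BodyModel":
        """Rescale w and h jointly (preserving aspect) to a target mass."""
        f = np.sqrt(mass / self.mass)
        return replace(
            self,
            m_b=self.m_b * f**2,
            h=self.h * f,
            w=self.w * f,
            m_a=self.m_a * f**2,
        )


def _finish(s: np.ndarray, w: np.ndarray, h: np.ndarray, mass: float,
            c_n: float, c_t: float) -> BodyModel:
    m_b = SECTION_FACTOR * w * h
    body = BodyModel(
        s=s, m_b=m_b, h=h, w=w,
        m_a=np.pi * h**2 / 4.0,
        c_n=np.full_like(s, c_n),
        c_t=np.full_like(s, c_t),
    )
    return body.scaled_to_mass(mass)


def _envelope(s: np.ndarray, stations, values) -> np.ndarray:
    """Monotone-cubic envelope through morphological anchor stations."""
    return np.clip(PchipInterpolator(stations, values)(s), 0.0, None)


def eel_profile(
    ns: int = 201, mass: float = EEL_MASS, c_n: float = 1.0, c_t: float = 0.1
) -> BodyModel:
    """Elongated lamprey/eel-like body.

    Anchored at morphological stations of an anguilliform body: a blunt
    head (full girth within the first tenth), a near-cylindrical trunk to
    s ~ 0.6, and a gradual tail taper.  The section height carries the
    documented increase near s ~ 0.7 where the dorsal/anal fin fold
    raises the body profile.  Scaled to the target total mass.
    """
    if ns < 3:
        raise ConfigurationError("ns must be >= 3")
    s = np.linspace(0.0, 1.0, ns)
    girth = _envelope(
        s,
        [0.0, 0.02, 0.05, 0.10, 0.20, 0.50, 0.60, 0.70, 0.80, 0.90, 0.97, 1.0],
        [0.0, 0.50, 0.85, 0.95, 1.00, 1.00, 0.97, 0.85, 0.60, 0.35, 0.12, 0.0],
    )
    w = 0.048 * girth
    bump = 1.0 + 0.30 * np.exp(-(((s - 0.7) / 0.09) ** 2))
    h = 0.048 * girth * bump
    return _finish(s, w, h, mass, c_n, c_t)


def mackerel_profile(
    ns: int = 201, mass: float = MACKEREL_MASS, c_n: float = 1.0, c_t: float = 0.1
) -> BodyModel:
    """Fusiform mackerel-like body.

    Depth and width envelopes anchored at morphological stations of a
    scombrid: maximal section anterior of mid-body (s ~ 0.35-0.4), a
    sustained taper over the posterior trunk, a narrow caudal peduncle
    (s ~ 0.85-0.92, under 10% of the maximal section), and a thin caudal
    membrane of near-zero width — it carries height (for added mass) but
    almost no body mass.  Scaled to the target total mass.
    """
    if ns < 3:
        raise ConfigurationError("ns must be >= 3")
    s = np.linspace(0.0, 1.0, ns)
    h = 0.19 * _envelope(
        s,
        [0.0, 0.03, 0.10, 0.20, 0.35, 0.50, 0.65, 0.75, 0.85, 0.92, 1.0],
        [0.0, 0.35, 0.70, 0.90, 1.00, 0.95, 0.75, 0.55, 0.25, 0.12, 0.05],
    )
    w = 0.11 * _envelope(
        s,
        [0.0, 0.05, 0.15, 0.35, 0.55, 0.70, 0.85, 0.92, 1.0],
        [0.0, 0.50, 0.85, 1.00, 0.85, 0.55, 0.15, 0.05, 0.0],
    )
    # caudal-fin lobe: height (added mass) without body mass
    h = h + 0.10 * np.exp(-(((s - 1.0) / 0.06) ** 2))
    return _finish(s, w, h, mass, c_n, c_t)


def mass_properties(body: BodyModel, midline) -> dict:
    """Total mass, center of mass, and moment of inertia time series.

    I(t) = int m_b |r - r_com|^2 ds about the instantaneous center of
    mass; Idot by spectral time differentiation.
    """
    s = midline.s
    if body.s.shape != s.shape or np.max(np.abs(body.s - s)) > 1e-12:
        raise ConfigurationError("body and midline s-grids do not match")
    m = body.m_b
    M = body.mass
    xc = np.trapezoid(m[:, None] * midline.x, s, axis=0) / M
    yc = np.trapezoid(m[:, None] * midline.y, s, axis=0) / M
    r2 = (midline.x - xc) ** 2 + (midline.y - yc) ** 2
    inertia = np.trapezoid(m[:, None] * r2, s, axis=0)
    dt = check_uniform(midline.t)
    idot = time_derivative(inertia, dt)
    return {"M": M, "com": np.stack([xc, yc]), "I": inertia, "Idot": idot}
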