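"""Spectral helpers for periodic-in-time fields.

All kinematic fields produced by the package are exactly periodic in time,
so time derivatives and antiderivatives are taken in Fourier space along
the last axis.  Grids are uniform with the endpoint excluded (t covers
[t0, t0 + span) with span a whole number of periods).
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError


def check_uniform(t: np.ndarray, name: str = "t_grid", rtol: float = 1e-9) -> float:
    """Return the grid step, raising ConfigurationError if non-uniform."""
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ConfigurationError(f"{name} must be 1-D with at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0) or np.max(np.abs(dt - dt[0])) > rtol * abs(dt[0]):
        raise ConfigurationError(f"{name} must be strictly increasing and uniform")
    return float(dt[0])


def _angular_freqs(n: int, dt: float) -> np.ndarray:
    return 2.0j * np.pi * np.fft.rfftfreq(n, d=dt)


def time_derivative(f: np.ndarray, dt: float) -> np.ndarray:
    """Spectral d/dt along the last axis of a periodic field."""
    f = np.asarray(f, dtype=float)
    n = f.shape[-1]
    iw = _angular_freqs(n, dt)
    fh = np.fft.rfft(f, axis=-1) * iw
    if n % 2 == 0:
        # the Nyquist mode has no well-defined derivative; drop it
        fh[..., -1] = 0.0
    return np.fft.irfft(fh, n=n, axis=-1)


def time_antiderivative(f: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Zero-mean spectral antiderivative along the last axis.

    Returns (F, mean) where F is periodic with zero temporal mean and
    ``mean`` is the temporal mean of f (the secular rate that a periodic
    antiderivative cannot absorb).
    """
    f = np.asarray(f, dtype=float)
    n = f.shape[-1]
    iw = _angular_freqs(n, dt)
    fh = np.fft.rfft(f, axis=-1)
    mean = fh[..., 0].real / n
    out = np.zeros_like(fh)
    out[..., 1:] = fh[..., 1:] / iw[1:]
    if n % 2 == 0:
        out[..., -1] = 0.0
    return np.fft.irfft(out, n=n, axis=-1), mean


def fundamental_coefficient(
    f: np.ndarray, t: np.ndarray, period: float = 1.0
) -> np.ndarray:
    """Complex amplitude of the fundamental temporal harmonic.

    With convention f(t) ~ Re[c * exp(-i*omega*t)], omega = 2*pi/period.
    The time grid must cover a whole number of periods.
    """
    dt = check_uniform(t)
    n = t.shape[0]
    span = n * dt
    ncyc = span / period
    if abs(ncyc - round(ncyc)) > 1e-8:
        raise ConfigurationError("time grid must span a whole number of periods")
    omega = 2.0 * np.pi / period
    phase = np.exp(1j * omega * np.asarray(t))
    return 2.0 / n * np.tensordot(np.asarray(f, dtype=float), phase, axes=([-1], [0]))


def n_cycles(t: np.ndarray, period: float = 1.0) -> int:
    """Number of whole periods spanned by the (endpoint-exclusive) grid."""
    dt = check_uniform(t)
    span = t.shape[0] * dt
    ncyc = span / period
    if abs(ncyc - round(ncyc)) > 1e-8 or round(ncyc) < 1:
        raise ConfigurationError(
            f"time grid spans {ncyc:g} periods; a whole number >= 1 is required"
        )
    return int(round(ncyc))


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(phi)))
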