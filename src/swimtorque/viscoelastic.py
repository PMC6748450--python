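"""Elastic and viscous body-torque corrections.

Passive tissue contributes a torque proportional to the local curvature
(elastic) or its rate (viscous).  Scaled so its temporal standard
deviation is a fraction beta (default 0.4) of that of the hydrodynamic +
inertial torque at each station:

    T_e = beta * <T>(s) * kappa(s, t)    / <kappa>(s)
    T_v = beta * <T>(s) * kappadot(s, t) / <kappadot>(s)

where <.> is the standard deviation over whole cycles (temporal mean
removed).  The torque the muscles must generate is then T + T_e or
T + T_v.  Over a cycle the elastic correction stores and releases energy
(int T_e * kappadot dt = 0) while the viscous one only dissipates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._spectral import check_uniform, n_cycles
from .errors import ConfigurationError
from .mechanics import wave_speed, work_budget


def _cycle_std(field: np.ndarray) -> np.ndarray:
    """Temporal standard deviation per s, mean removed (whole cycles)."""
    return np.std(field, axis=1)


def _scaled_correction(
    T: np.ndarray, shape: np.ndarray, beta: float, what: str
) -> np.ndarray:
    if beta < 0:
        raise ConfigurationError("beta must be nonnegative")
    Tstd = _cycle_std(T)
    sstd = _cycle_std(shape)
    out = np.zeros_like(T)
    ok = sstd > 0
    if not np.all(ok):
        warnings.warn(
            f"<{what}> vanishes at {np.count_nonzero(~ok)} station(s); "
            "correction set to 0 there (no bending)",
            stacklevel=3,
        )
    out[ok] = beta * (Tstd[ok] / sstd[ok])[:, None] * shape[ok]
    return out


def elastic_torque(
    T: np.ndarray, kappa: np.ndarray, beta: float = 0.4
) -> tuple[np.ndarray, np.ndarray]:
    """Elastic correction T_e and the muscle-required torque T + T_e."""
    T_e = _scaled_correction(T, kappa, beta, "kappa")
    return T_e, T + T_e


def viscous_torque(
    T: np.ndarray, kappadot: np.ndarray, beta: float = 0.4
) -> tuple[np.ndarray, np.ndarray]:
    """Viscous correction T_v and the muscle-required torque T + T_v."""
    T_v = _scaled_correction(T, kappadot, beta, "kappadot")
    return T_v, T + T_v


def negative_power_area(P: np.ndarray, s: np.ndarray, t: np.ndarray,
                        period: float = 1.0) -> float:
    """Magnitude of the negative-power region: int int max(-P, 0) ds dt / cycle."""
    ncyc = n_cycles(t, period)
    dt = check_uniform(t)
    return float(np.trapezoid(np.sum(np.maximum(-P, 0.0), axis=1) * dt, s) / ncyc)


def correction_sweep(
    T: np.ndarray,
    kappa: np.ndarray,
    kappadot: np.ndarray,
    s: np.ndarray,
    t: np.ndarray,
    betas=(0.0, 0.2, 0.4, 0.6, 0.8),
    mode: str = "elastic",
    period: float = 1.0,
    s_window: tuple[float, float] = (0.2, 0.9),
) -> pd.DataFrame:
    """Trend table of wave speed, W+ total, and negative-power area vs beta."""
    if mode not in ("elastic", "viscous"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    rows = []
    for beta in betas:
        if not 0.0 <= beta <= 0.8:
            raise ConfigurationError("beta_list must lie in [0, 0.8]")
        if mode == "elastic":
            _, Tc = elastic_torque(T, kappa, beta)
        else:
            _, Tc = viscous_torque(T, kappadot, beta)
        P = Tc * kappadot
        wb = work_budget(P, s, t, period)
        est = wave_speed(Tc, s, t, s_window=s_window, period=period)
        rows.append({
            "beta": beta,
            "v_T": est.speed,
            "W_plus_total": wb.P_tot_plus * period,
            "neg_area": negative_power_area(P, s, t, period),
        })
    return pd.DataFrame(rows)
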