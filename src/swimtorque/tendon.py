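"""Two-joint rope model of tendon torque and energy transfer.

A long tendon couples the torque demand at an anterior joint (1, at s1)
and a posterior joint (2, at s2 > s1).  A muscle acting through the
tendon ("tendon muscle") is recruited only when the torques required at
the two joints share a sign, and then supplies the torque both joints
can use:

    T_d = sgn(T_1) * min(|T_1|, |T_2|)       if sgn(T_1) == sgn(T_2), else 0.

The cycle splits into four sign-pattern stages of (T_1, T_2, kdot_1,
kdot_2); energy is saved during the stages where the curvature rates at
the two joints have opposite signs (II and IV), by the amount
min(|T_d kdot_1|, |T_d kdot_2|) per unit time.  Negative muscle power is
treated as wasted (counted as zero work), including on the tendon muscle.

Torque from a muscle of force F_m on a strut of height H_s is
T_m = H_s * F_m, and the muscle length tracks curvature as
dL_m = H_s * kappa * ds; strut height, joint spacing, and rest length
cancel from the power bookkeeping and default to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._spectral import check_uniform, n_cycles
from .errors import ConfigurationError

STAGES = ("I", "II", "III", "IV")


def _inherited_sign(x: np.ndarray) -> np.ndarray:
    """Sign with exact zeros inheriting the nearest preceding nonzero sign.

    The series is treated as periodic, so leading zeros inherit from the
    end of the cycle.  All-zero input maps to +1 everywhere (degenerate).
    """
    s = np.sign(np.asarray(x, dtype=float)).astype(int)
    nz = np.flatnonzero(s)
    if nz.size == 0:
        return np.ones_like(s)
    last = s[nz[-1]]
    out = np.empty_like(s)
    for i in range(s.size):
        if s[i] != 0:
            last = s[i]
        out[i] = last
    return out


def tendon_torque(T_1: np.ndarray, T_2: np.ndarray) -> np.ndarray:
    """T_d = sgn(T_1) min(|T_1|, |T_2|) where the signs agree, else 0."""
    T_1 = np.asarray(T_1, dtype=float)
    T_2 = np.asarray(T_2, dtype=float)
    same = np.sign(T_1) * np.sign(T_2) > 0
    return np.where(same, np.sign(T_1) * np.minimum(np.abs(T_1), np.abs(T_2)), 0.0)


def classify_stages(
    T_1: np.ndarray, T_2: np.ndarray, kd_1: np.ndarray, kd_2: np.ndarray
) -> np.ndarray:
    """Label every sample with its sign-pattern stage.

    I   : T_1 and T_2 have different signs (tendon inactive).
    II  : T_1, T_2, kdot_1 share a sign, kdot_2 opposite (transfer 1 -> 2).
    III : all four share a sign (tendon has no energetic effect).
    IV  : T_1, T_2, kdot_2 share a sign, kdot_1 opposite (transfer 2 -> 1).

    Exact zeros inherit the sign of the nearest preceding nonzero sample
    so the partition is exhaustive.  The sign pattern with both curvature
    rates opposing the torques (all muscle power negative, no possible
    transfer) is labelled I: the tendon is equally ineffective there.
    """
    sT1 = _inherited_sign(T_1)
    sT2 = _inherited_sign(T_2)
    sk1 = _inherited_sign(kd_1)
    sk2 = _inherited_sign(kd_2)
    out = np.empty(sT1.shape, dtype="<U3")
    diff = sT1 != sT2
    out[diff] = "I"
    same = ~diff
    out[same & (sk1 == sT1) & (sk2 == sT1)] = "III"
    out[same & (sk1 == sT1) & (sk2 != sT1)] = "II"
    out[same & (sk1 != sT1) & (sk2 == sT1)] = "IV"
    out[same & (sk1 != sT1) & (sk2 != sT1)] = "I"
    return out


@dataclass
class TendonBudget:
    """Per-sample bookkeeping and cycle-integrated energy summary."""

    t: np.ndarray
    T_1: np.ndarray
    T_2: np.ndarray
    kd_1: np.ndarray
    kd_2: np.ndarray
    T_d: np.ndarray
    stage: np.ndarray
    P_1: np.ndarray            # muscle 1 power (clamped at 0)
    P_2: np.ndarray            # muscle 2 power (clamped at 0)
    P_d: np.ndarray            # tendon-muscle power (negative part counted 0)
    P_without: np.ndarray      # positive muscle power without the tendon
    saved: np.ndarray          # instantaneous energy-saving rate
    totals: dict = field(default_factory=dict)


def power_budget(
    T_1: np.ndarray,
    T_2: np.ndarray,
    kd_1: np.ndarray,
    kd_2: np.ndarray,
    t: np.ndarray,
    period: float = 1.0,
) -> TendonBudget:
    """Cycle energy bookkeeping with and without the tendon.

    Requires a uniform time grid covering a whole number of periods.
    Totals are per cycle.  Ratios reported: savings over the muscle-2
    work without the tendon, and savings over the total recoverable
    negative power.
    """
    t = np.asarray(t, dtype=float)
    ncyc = n_cycles(t, period)
    dt = check_uniform(t)
    T_1, T_2 = np.asarray(T_1, float), np.asarray(T_2, float)
    kd_1, kd_2 = np.asarray(kd_1, float), np.asarray(kd_2, float)

    T_d = tendon_torque(T_1, T_2)
    stage = classify_stages(T_1, T_2, kd_1, kd_2)

    P_1 = np.maximum((T_1 - T_d) * kd_1, 0.0)
    P_2 = np.maximum((T_2 - T_d) * kd_2, 0.0)
    P_d_raw = T_d * (kd_1 + kd_2)
    P_d = np.maximum(P_d_raw, 0.0)
    P_without = np.maximum(T_1 * kd_1, 0.0) + np.maximum(T_2 * kd_2, 0.0)

    saved = np.where(
        np.isin(stage, ("II", "IV")),
        np.minimum(np.abs(T_d * kd_1), np.abs(T_d * kd_2)),
        0.0,
    )

    def cyc(x):
        return float(np.sum(x) * dt / ncyc)

    W_with = cyc(P_1 + P_2 + P_d)
    W_without = cyc(P_without)
    W2_without = cyc(np.maximum(T_2 * kd_2, 0.0))
    recoverable = cyc(np.maximum(-T_1 * kd_1, 0.0) + np.maximum(-T_2 * kd_2, 0.0))
    saved_total = cyc(saved)
    wasted_tendon = cyc(np.maximum(-P_d_raw, 0.0))

    totals = {
        "W_with": W_with,
        "W_without": W_without,
        "W1_without": cyc(np.maximum(T_1 * kd_1, 0.0)),
        "W2_without": W2_without,
        "saved": saved_total,
        "saved_over_muscle2": saved_total / W2_without if W2_without > 0 else 0.0,
        "saved_over_recoverable": (saved_total / recoverable
                                   if recoverable > 0 else 0.0),
        "recoverable_negative": recoverable,
        "wasted_tendon": wasted_tendon,
        "stage_fractions": {
            st: float(np.mean(stage == st)) for st in STAGES
        },
    }
    return TendonBudget(
        t=t, T_1=T_1, T_2=T_2, kd_1=kd_1, kd_2=kd_2, T_d=T_d, stage=stage,
        P_1=P_1, P_2=P_2, P_d=P_d, P_without=P_without, saved=saved,
        totals=totals,
    )


def activation_prediction(budget: TendonBudget) -> dict:
    """Predicted activation durations (fractions of the period).

    A muscle is counted active, on the side bending it positively, while
    it produces positive power under the tendon strategy; the tendon
    muscle is active whenever it carries torque (T_d != 0).  Durations
    are reported for the positive-torque side; the other side mirrors by
    the half-period antisymmetry of steady undulation.
    """
    pos1 = budget.T_1 > 0
    pos2 = budget.T_2 > 0
    posd = budget.T_d > 0
    frac = lambda m: float(np.mean(m))
    muscle1 = frac(pos1 & (budget.P_1 > 0))
    muscle2 = frac(pos2 & (budget.P_2 > 0))
    tendon = frac(posd)
    joint1_combined = frac((pos1 & (budget.P_1 > 0)) | posd)
    return {
        "muscle1": muscle1,
        "muscle2": muscle2,
        "tendon_muscle": tendon,
        "joint1_combined": joint1_combined,
        "joint2": muscle2,
    }


def joint_series_from_fields(
    T: np.ndarray,
    kappadot: np.ndarray,
    s: np.ndarray,
    s1: float = 0.47,
    s2: float = 0.71,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Sample torque and curvature-rate series at the two joint stations.

    Defaults s1 = 0.47, s2 = 0.71 (the worked carangiform example).
    """
    if not s1 < s2:
        raise ConfigurationError("joint positions must satisfy s1 < s2")
    i1 = int(np.argmin(np.abs(s - s1)))
    i2 = int(np.argmin(np.abs(s - s2)))
    return T[i1], T[i2], kappadot[i1], kappadot[i2]
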