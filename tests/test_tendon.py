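"""Tendon rope model: torque transfer, stage labels, and energy bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hs

import swimtorque as st
from swimtorque.synthetic import JointSeriesSpec, make_joint_series
from swimtorque.tendon import (
    activation_prediction,
    classify_stages,
    power_budget,
    tendon_torque,
)


def brute_force_budget(T1, T2, kd1, kd2, t):
    """Sample-by-sample bookkeeping, written directly from the stage rules.

    Independent of the vectorized implementation: walks the series one
    sample at a time, applies the per-stage power formulas literally, and
    accumulates the cycle totals.
    """
    n = len(t)
    dt = t[1] - t[0]

    def sgn(x, series, i):
        if x != 0:
            return 1 if x > 0 else -1
        # inherit the nearest preceding nonzero sign (periodic)
        for back in range(1, n + 1):
            v = series[(i - back) % n]
            if v != 0:
                return 1 if v > 0 else -1
        return 1

    with_t = without = saved = 0.0
    for i in range(n):
        a, b, c, d = T1[i], T2[i], kd1[i], kd2[i]
        sa, sb = sgn(a, T1, i), sgn(b, T2, i)
        sc, sd = sgn(c, kd1, i), sgn(d, kd2, i)
        without += max(a * c, 0.0) + max(b * d, 0.0)
        if sa != sb:
            td = 0.0
            with_t += max(a * c, 0.0) + max(b * d, 0.0)
        else:
            td = (1 if sa > 0 else -1) * min(abs(a), abs(b))
            if sc == sa and sd == sa:                      # stage III
                with_t += (a - td) * c + (b - td) * d + td * (c + d)
            elif sc == sa:                                 # stage II
                with_t += (a - td) * c + max((b - td) * d, 0.0)
                with_t += max(td * (c + d), 0.0)
                saved += min(abs(td * c), abs(td * d))
            elif sd == sa:                                 # stage IV
                with_t += (b - td) * d + max((a - td) * c, 0.0)
                with_t += max(td * (c + d), 0.0)
                saved += min(abs(td * c), abs(td * d))
            else:                                          # no transfer possible
                with_t += max((a - td) * c, 0.0) + max((b - td) * d, 0.0)
                with_t += max(td * (c + d), 0.0)
    return {"W_with": with_t * dt, "W_without": without * dt, "saved": saved * dt}


class TestTendonTorque:
    @pytest.mark.parametrize("T1,T2,expected", [
        (3.0, -2.0, 0.0),     # opposite signs: tendon inactive
        (3.0, 2.0, 2.0),
        (-5.0, -1.0, -1.0),
    ])
    def test_published_examples(self, T1, T2, expected):
        assert tendon_torque(np.array([T1]), np.array([T2]))[0] == expected

    def test_bounded_by_both_torques(self):
        rng = np.random.default_rng(0)
        T1, T2 = rng.normal(size=200), rng.normal(size=200)
        Td = tendon_torque(T1, T2)
        assert np.all(np.abs(Td) <= np.minimum(np.abs(T1), np.abs(T2)) + 1e-15)
        opp = np.sign(T1) != np.sign(T2)
        assert not Td[opp].any()


class TestClassifyStages:
    @pytest.mark.parametrize("pattern,expected", [
        ((+1, -1, +1, +1), "I"),
        ((+1, +1, +1, -1), "II"),
        ((+1, +1, +1, +1), "III"),
        ((+1, +1, -1, +1), "IV"),
    ])
    def test_published_sign_patterns(self, pattern, expected):
        arrs = [np.array([float(v)]) for v in pattern]
        assert classify_stages(*arrs)[0] == expected

    def test_zero_inherits_preceding_sign(self):
        T1 = np.array([1.0, 0.0, -1.0, 0.0])
        T2 = np.array([1.0, 1.0, 1.0, 1.0])
        kd = np.ones(4)
        stages = classify_stages(T1, T2, kd, kd)
        assert stages[1] == "III"   # zero T1 inherits +
        assert stages[3] == "I"     # zero T1 inherits -

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(hs.integers(min_value=0, max_value=2**31 - 1))
    def test_partition_is_exhaustive_and_exclusive(self, seed):
        rng = np.random.default_rng(seed)
        series = rng.normal(size=(4, 64))
        stages = classify_stages(*series)
        assert set(stages) <= {"I", "II", "III", "IV"}
        assert stages.shape == (64,)


class TestPowerBudget:
    def test_all_stage_three_leaves_total_unchanged(self):
        t = np.arange(64) / 64.0
        base = np.sin(2 * np.pi * t)
        b = power_budget(2 * base, base, 3 * base, 0.5 * base, t)
        assert set(b.stage) == {"III"}
        assert b.totals["W_with"] == pytest.approx(b.totals["W_without"], abs=1e-14)
        assert b.totals["saved"] == 0.0

    def test_zero_posterior_torque_saves_nothing(self):
        t = np.arange(64) / 64.0
        base = np.sin(2 * np.pi * t)
        b = power_budget(base, np.zeros_like(base), base, base, t)
        assert not b.T_d.any()
        assert b.totals["saved"] == 0.0

    def test_matches_brute_force_oracle_on_carangiform_ordering(self):
        t, T1, T2, kd1, kd2 = make_joint_series(JointSeriesSpec.carangiform_ordering())
        b = power_budget(T1, T2, kd1, kd2, t)
        ref = brute_force_budget(T1, T2, kd1, kd2, t)
        for key in ("W_with", "W_without", "saved"):
            assert b.totals[key] == pytest.approx(ref[key], abs=1e-10)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(hs.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force_on_random_harmonics(self, seed):
        rng = np.random.default_rng(seed)
        t = np.arange(128) / 128.0
        amps = rng.uniform(0.2, 2.0, size=4)
        phis = rng.uniform(-np.pi, np.pi, size=4)
        T1, T2, kd1, kd2 = (a * np.sin(2 * np.pi * t + p)
                            for a, p in zip(amps, phis))
        b = power_budget(T1, T2, kd1, kd2, t)
        ref = brute_force_budget(T1, T2, kd1, kd2, t)
        for key in ("W_with", "W_without", "saved"):
            assert b.totals[key] == pytest.approx(ref[key], abs=1e-10)

    def test_bookkeeping_conserves_energy(self):
        t, T1, T2, kd1, kd2 = make_joint_series(JointSeriesSpec.carangiform_ordering())
        b = power_budget(T1, T2, kd1, kd2, t)
        assert (b.totals["W_without"] - b.totals["W_with"]
                == pytest.approx(b.totals["saved"], abs=1e-14))
        assert b.totals["saved"] >= 0
        assert b.totals["W_with"] <= b.totals["W_without"] + 1e-14

    def test_savings_vanish_without_stages_two_and_four(self):
        t = np.arange(64) / 64.0
        base = np.sin(2 * np.pi * t + 0.2)
        b = power_budget(base, 0.5 * base, base, base, t)
        assert not np.isin(b.stage, ("II", "IV")).any()
        assert b.totals["saved"] == 0.0

    def test_partial_cycle_rejected(self):
        t = np.arange(50) / 64.0
        x = np.sin(2 * np.pi * t)
        with pytest.raises(st.ConfigurationError):
            power_budget(x, x, x, x, t)


class TestActivationPrediction:
    def test_in_phase_posterior_joint_is_active_half_the_period(self):
        t = np.arange(256) / 256.0
        T2 = np.sin(2 * np.pi * t + 0.23)
        kd2 = 0.8 * np.sin(2 * np.pi * t + 0.23)
        # antiphase torque at joint 1 keeps the tendon inactive (stage I)
        T1 = np.sin(2 * np.pi * t + 0.23 + np.pi)
        kd1 = np.sin(2 * np.pi * t + 0.23 + np.pi)
        act = activation_prediction(power_budget(T1, T2, kd1, kd2, t))
        assert act["muscle2"] == pytest.approx(0.5, abs=2 / 256)

    def test_carangiform_ordering_shortens_posterior_activation(self):
        t, T1, T2, kd1, kd2 = make_joint_series(JointSeriesSpec.carangiform_ordering())
        act = activation_prediction(power_budget(T1, T2, kd1, kd2, t))
        assert act["muscle2"] < 0.5 - 2 / len(t)
        assert act["joint1_combined"] == pytest.approx(0.5, abs=2 / len(t))

    def test_identical_joints_have_equal_durations(self):
        t = np.arange(128) / 128.0
        x = np.sin(2 * np.pi * t + 0.37)
        act = activation_prediction(power_budget(x, x, x, x, t))
        assert act["muscle1"] == act["muscle2"]
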