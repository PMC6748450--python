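# swimtorque

Internal-driving analysis of undulatory fish swimming: given a prescribed
traveling wave of midline curvature, the package reconstructs the motion in
a momentum-conserving body frame, evaluates hydrodynamic force closures (or
imports externally computed force fields), and computes the internal torque
and power that the muscles, passive tissue, and tendons must supply along
the body.

It is aimed at biomechanists and bio-inspired-robotics researchers who want
to connect swimming kinematics to muscle activation (EMG) timing: why the
muscle-activation wave travels faster than the curvature wave
("neuromechanical phase lag"), why activation bursts shorten toward the
tail in carangiform swimmers, and how body viscoelasticity and long tendons
reshape the torque wave and the energy budget.

## Model

Body length and undulation period are the units (so the tail-beat frequency
is `f = 1` and `omega_u = 2*pi`).  The deformation is a curvature wave

    kappa(s, t) = A(s) sin(k s - omega_u t),        s in [0, 1], head at 0,

with an anguilliform envelope `A(s) = a_max exp(s - 1)` (eel:
`a_max = 11.41`, `lambda = 0.59`) or a carangiform envelope
`A(s) = a0 + a1 s + a2 s^2` (mackerel: `a0 = 1, a1 = -3.2, a2 = 5.6`,
`lambda = 1.0`).  The midline is the arc-length integral of the tangent
angle, and the whole-body rotation/translation left free by the curvature
prescription is fixed so the free motion conserves linear and angular
momentum for the body's mass distribution `m_b(s)` (total masses 0.0019 for
the eel-like body, 0.0101 for the mackerel-like body at fluid density 1).

With a force per unit length `F(s, t)` from a resistive closure
(`F = -c_n v_n n - c_t v_t t`), a reactive closure
(`F = -d/dt(m_a v_n n)`), or an imported table, the internal bending moment
follows from the force balance of either body portion, treating inertia as
the d'Alembert load:

    T_post(s) = -e_z . int_s^1 (r' - r(s)) x (F - m_b a) dl
    T_ant(s)  = +e_z . int_0^s (r' - r(s)) x (F - m_b a) dl
    T = s T_post + (1 - s) T_ant               (free ends: T(0) = T(1) = 0)

Internal power per unit length is `P_T = T * kappadot`, power delivered to
the fluid is `P_F = -F . v`; over whole cycles the two integrate to the
same total (the package's main numerical check).  On top of this the
package provides viscoelastic torque corrections
(`T_e = beta <T> kappa / <kappa>`, `T_v = beta <T> kappadot / <kappadot>`,
`<.>` the temporal standard deviation), a two-joint tendon rope model with
stage-by-stage energy bookkeeping, closed-form small-amplitude
torque/power patterns used as an independent oracle, and a reduced-order
3-DOF free-swimming (recoil) integrator.

## Worked example

```python
import swimtorque as st
from swimtorque.tendon import joint_series_from_fields, power_budget

fx = st.synthetic.fixture_suite()["mackerel"]
mid, body = fx.midline, fx.body
force = st.reactive_force(mid, body)
torque = st.torque_from_forces(force, mid, body)
P_T = st.internal_power(torque, mid.kappadot)
P_F = st.external_power(force, mid)
wb = st.work_budget(P_T, mid.s, mid.t, P_F=P_F)

print(st.wave_speed(mid.kappa, mid.s, mid.t).speed)   # 1.000 L/period
print(st.wave_speed(torque.T, mid.s, mid.t).speed)    # 3.018 L/period
print(wb.P_tot, wb.P_tot_plus)                        # 4.200e-05 4.680e-04

budget = power_budget(*joint_series_from_fields(torque.T, mid.kappadot, mid.s),
                      mid.t)
print(budget.totals["saved"])                         # 4.807e-04
```

The torque wave (3.02 body lengths/period) travels three times faster than
the curvature wave (1.0) — the neuromechanical phase lag.  The positive-only
work `P_tot+` exceeds the net work `P_tot` more than tenfold, which is the
energy a tendon spanning s = 0.47 to 0.71 can partly recover: here the
bookkeeping saves 4.8e-4 per cycle, and the posterior muscle's activation
shrinks to 0.21 of the period (less than the half-period of a plain
alternating-torque pattern).

A thin CLI mirrors the library (`swimtorque kinematics|forces|torque|power|
wavespeed|viscoelastic|tendon|freeswim|fixtures -c config.toml -o rundir`);
each subcommand reads one TOML config and writes CSV tables plus a
`summary.json` and log into the run directory.

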