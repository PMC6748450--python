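# Methods

## Model and assumptions

The swimmer is a slender, inextensible 2-D midline of unit length whose
deformation is fully prescribed as a traveling curvature wave
`kappa(s, t) = A(s) sin(ks - omega_u t)` with the undulation period as the
time unit (`omega_u = 2 pi`).  Out-of-plane motion, fins other than a
massless caudal membrane, and the full Navier–Stokes flow are outside the
model: hydrodynamic loading enters either through local force closures
(resistive/drag-type, reactive/added-mass-type, or a convex mix) or
through an imported force-per-unit-length table from an external flow
solver.  All analysis operates on rectangular (s, t) grids with the time
axis covering whole periods.

Internal torque is defined by static balance of either body portion under
the effective load `G = F - m_b a` (d'Alembert inertia).  The two one-sided
integrals agree only when `G` carries zero net force and torque; the
reported torque is the end-weighted average `T = s T_post + (1 - s) T_ant`,
which pins the free-end values to exactly zero and suppresses the
end-point error amplification of either one-sided integral alone.

## Momentum-conserving frame

The curvature prescription leaves a rigid-body motion free.  It is fixed
by requiring that the deformation, with no external forces, conserves
linear and angular momentum for the mass profile `m_b(s)`: the center of
mass is pinned at the origin (exact), and a per-time yaw rate
`phidot = -L(t)/I(t)` cancels the angular momentum `L` of the deforming
body about its center of mass.  In two dimensions the scalar cross product
is rotation-invariant, so this correction is exact in continuous time; on
the grid, spectral differentiation does not commute exactly with the
rotation, so the correction is iterated as a fixed point until the
normalized residuals fall below 1e-8 (default; they typically reach ~1e-15
in two passes).  The yaw angle is the zero-mean spectral antiderivative of
`phidot`; for the bilaterally symmetric kinematics used here the mean yaw
rate vanishes by symmetry, so the frame stays periodic.

## Rigid-mode projection of closure forces

An external flow solution satisfies the free-swimming Newton–Euler
equations, so its `F - m_b a` is momentum-consistent by construction.  A
theoretical closure evaluated on prescribed kinematics is not: the body
would recoil under it.  `torque_from_forces` therefore (by default)
removes the rigid modes of the effective load by subtracting the
mass-weighted distribution `m_b [F_net/M + alpha J(r - r_c)]` with
`alpha = tau_net / I` — exactly the inertial reaction of the free body.
In the momentum-conserving frame this projection provably leaves the
cycle-integrated power unchanged, so the energy-closure diagnostic is not
affected.  A `balance="strict"` mode instead raises an error when the
input field's normalized net force or torque exceeds a tolerance, which is
the appropriate setting for validating imported force tables.  For the
massless-body configuration used by the analytic oracle the projection
weights fall back to a uniform distribution.

## Numerical choices

- Grids: `Ns = 201` points in s, `Nt = 256` samples per period, 2 periods
  analyzed (all configurable).  These sizes keep every pipeline run in
  the seconds range while placing discretization errors far below the
  physical effects of interest.
- Time derivatives and antiderivatives are spectral over the periodic
  time axis (the kinematics are exactly periodic), eliminating endpoint
  bias in velocity, acceleration, and `kappadot` (which is additionally
  available in closed form and is used analytically).
- Arc-length integration (midline reconstruction, cumulative torque
  integrals, rigid-mode projection, work totals) uses composite Simpson
  rules with matching quadrature across the projection and the torque
  integration, so the projected load has exactly zero net force/torque
  under the quadrature that integrates it.  With this pairing the
  internal/external power totals agree to ~1e-5 relative at the default
  grid (the structural bound asserted in the tests is 3%, with 0.1% at
  doubled resolution).
- The midline is parametrized by arc length, so inextensibility is exact
  in the continuum; the chord-sum estimate of the path length on the grid
  deviates from 1 by O(h^2) (about 1e-4 at `Ns = 201` for the eel's
  curvature amplitudes) and is tested with that scaling, not at machine
  precision.
- Wave speeds come from the per-station phase of the fundamental temporal
  harmonic, unwrapped along the body (2 pi continuity) and fitted linearly
  over `s in [0.2, 0.9]` by default, avoiding the head/tail regions where
  phase is ill-behaved.  A wave is reported as standing — speed above the
  resolvable bound rather than a number — when the fitted slope implies a
  speed above 50 body lengths/period or when the complex phase profile is
  phase-locked (after rotating by half the phase of `sum(c^2)`, the
  profile is real to within 5%), which also catches the pi phase steps at
  amplitude nodes.
- Stage classification in the tendon model resolves exact zeros by
  inheriting the sign of the nearest preceding nonzero sample
  (periodically), keeping the stage partition exhaustive on the grid.
  The sign pattern with both curvature rates opposing both torques (no
  transfer possible, all muscle power negative) is labelled stage I,
  where the tendon is equally ineffective; the generalized power formulas
  `P_1 = max((T_1 - T_d) kd_1, 0)`, `P_2 = max((T_2 - T_d) kd_2, 0)`,
  `P_d = max(T_d (kd_1 + kd_2), 0)` reproduce the four published stage
  rules exactly and cover that degenerate pattern.
- The 3-DOF recoil integrator treats the added-mass part of the reactive
  closure implicitly (a 3x3 solve per stage) because fish-like bodies are
  nearly massless (`M ~ 1e-3`) relative to their hydrodynamic loading;
  the remaining stiffness from the resistive damping is handled by RK4
  substepping (default 4 substeps per stored sample, on a
  Fourier-resampled deformation).

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| `a_max`, (`a0`,`a1`,`a2`), `k` | published eel/mackerel values | 1/L, rad/L | curvature envelope and wavelength |
| `m_b(s)` | profile scaled to M = 0.0019 / 0.0101 | mass/L | recoil frame, inertial load |
| `m_a(s)` | `pi h(s)^2 / 4` | mass/L | added mass of a section of height h (fluid density 1) |
| `c_n`, `c_t` | 1.0, 0.1 | force/(L·velocity) | resistive closure coefficients |
| `beta` | 0.4 (swept to 0.8) | – | viscoelastic torque prefactor relative to `<T>` |
| `s1`, `s2` | 0.47, 0.71 | L | tendon joint stations |
| `H_s`, `ds`, `L_m0` | 1 | L | strut height, joint spacing, muscle rest length (cancel from power) |

The closure coefficients are package choices: the underlying force
measurements the analysis was designed around come from a 3-D flow
solution, which provides no coefficient values; `c_n = 1` sets the force
scale (results of interest are phases, wave speeds, and ratios, which are
insensitive to it) and `c_t = 0.1 c_n` reflects the order-of-magnitude
tangential/normal drag anisotropy of slender bodies.  A quadratic
`|v_n| v_n` resistive variant exists behind a flag; the linear law is the
default so the small-amplitude closed forms apply.

## Body profiles

The mass and geometry profiles are parametric stand-ins for scanned fish
geometries: monotone-cubic (PCHIP) envelopes through morphological anchor
stations — a blunt head and near-cylindrical trunk with gradual tail taper
for the lamprey/eel-like body (plus the documented height increase near
s = 0.7), and a fusiform scombrid shape with maximal section near s = 0.35,
narrow caudal peduncle (< 10% of the maximal section), and a membranous
caudal lobe that carries height (added mass) but almost no body mass.
Cross-sections are elliptical, `m_b = (pi/4) w h`, at fluid density 1,
jointly rescaled to the target total masses.  These envelopes preserve the
mass-distribution physics that the recoil frame and torque integrals
depend on, but they are approximations: quantities that weight the tail
strongly (notably the tail excursion `A_pp`) inherit their uncertainty.

## The synthetic generators

`synthetic.make_force_field` emulates the phase structure of
externally computed lateral force fields: the per-station fundamental
phase interpolates (parameter `alpha in [0, pi/2]`) between the negated
local velocity (resistive-like) and the negated local acceleration
(reactive-like), with optional Gaussian noise under a fixed seed.  By
default the generated field is projected to zero net force and torque so
torque integration is well-posed; the projection slightly shifts the
per-station phases, so the exact phase-recovery property is stated (and
tested) for the unprojected field.  `synthetic.make_joint_series`
produces harmonic joint torque/curvature-rate series with exact requested
phases; the `carangiform_ordering` preset realizes the phase ordering
`phi_kd1 ~ phi_T1 > phi_T2 > phi_kd2` under which only stages I–III occur.
What the generators do not emulate: broadband temporal content, the
head/tail phase anomalies of real force fields, or any Reynolds-number
dependence — so passing generator-recovery tests demonstrates correctness
of the analysis operators, not fidelity of any closure to real flows.

## Small-amplitude oracle

For a uniform body, uniform infinitesimal curvature amplitude, and
wavelength equal to body length, the torque and power fields have closed
forms: linearize the midline (`y'' = kappa`), fix the two rigid modes by
zero lateral momentum and angular momentum (`int y = int s y = 0`, which
simultaneously balances both the `-c ydot` and `-m_a yddot` loads), and
double-integrate the load with free ends.  Both load types share the same
complex double integral up to a constant phase factor, so their torque
patterns are time-shifted copies with identical wave speed (~4 L/period,
faster than the curvature wave at 1), while their power fields differ
genuinely: the reactive pattern carries a pronounced negative-work region
(minimum below -0.3 of the power maximum) and the resistive pattern's
cycle work is nonnegative up to a small (< 2.5%) end effect — both locked
as regression tests.  The numerical pipeline run in this configuration
(with a mass-free load, since the closed forms consider hydrodynamic
forces only) agrees with the closed forms to ~3e-8 normalized RMS at
amplitude 1e-3, and the discrepancy scales quadratically with amplitude
in the regime where linearization error dominates the discretization
floor (amplitudes above ~4e-3 at the default grids).

## Free-swimming (recoil) integration and the Strouhal caveat

`integrate_rigid_recoil` advances forward, lateral, and yaw degrees of
freedom under a closure until the cycle-mean speed is steady, reporting
`U` and `St = f A_pp / U` with `A_pp` the peak-to-peak tail excursion
perpendicular to the realized swimming direction.  This reduced-order
model is a diagnostic, not a flow solver: with order-one closure
coefficients it reaches speeds near the 0.3 initial value and — notably —
its lab-frame tail excursion is smaller than the vacuum-frame excursion,
because the fluid reaction (especially the large caudal added mass)
recoils the body against the tail swing.  Consequently a Strouhal number
formed from the vacuum (momentum-conserving) reconstruction and a
published swimming speed overestimates a lab-frame Strouhal number; with
the default body profiles the vacuum-frame values are ~0.77 (eel) and
~0.81 (mackerel) against published coupled-simulation values of 0.63 and
0.65.  The gap is a property of the frame in which the excursion is
measured, not of the reconstruction, whose momentum residuals are ~1e-15.

## Known limitations

- Closure forces are local and linear; suction-type (leading-edge /
  tail-edge) contributions are omitted, so closure-driven torque fields
  reproduce coupled-simulation torque patterns qualitatively (wave-speed
  orderings, sign structure of the work profile), not numerically.
- The viscoelastic corrections are phenomenological scalings of the
  measured torque, not a constitutive tissue model; their crossover
  station (where torque and curvature rate are in phase) is detected from
  the fields rather than asserted at any particular position.
- The tendon model is a two-joint rope with an inextensible tendon; the
  elastic-tendon refinement (storing energy during tendon-muscle
  lengthening) is out of scope, and the wasted lengthening energy is
  reported separately instead.
- Everything is 2-D and prescribed-deformation: no feedback from forces
  to kinematics except the 6 rigid degrees of freedom (3 used).
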