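# Model and methods

## The physical model

`xbgroup` simulates the active mechanics and energetics of a cardiac
half-sarcomere with a Huxley-type cross-bridge model in which neighboring
cross-bridges are *not* independent: consecutive binding sites are coupled
by the elastic tropomyosin strand that gates them.  The central object is a
**group** of `q` consecutive cross-bridges (default `q = 3`) flanked by two
permanently unbound boundary sites.  Each cross-bridge occupies one of five
biochemical states:

| state  | meaning                                   | Ca bound | force | tropomyosin |
|--------|-------------------------------------------|----------|-------|-------------|
| T      | detached, binding site blocked            | no       | no    | T (blocked) |
| W_Ca   | detached, site open (Ca on troponin-C)    | yes      | no    | W (open)    |
| S1_Ca  | strongly bound, pre-stroke                | yes      | yes   | S (shifted) |
| S2_Ca  | strongly bound, post-stroke               | yes      | yes   | S           |
| S2     | strongly bound, post-stroke, Ca released  | no       | yes   | S           |

The six reversible reactions are T↔W_Ca, W_Ca↔S1_Ca, S1_Ca↔S2_Ca,
W_Ca↔S2_Ca, S2_Ca↔S2 and T↔S2; only single-site transitions are allowed
within a group.

**Free energies.**  Cross-bridge state free energies depend on the strain
coordinate `x`, the axial offset of the nearest actin site (one
regulatory-unit period, `x ∈ [−d/2, d/2)`, `d = 36 nm`).  T is the
reference (`G_T ≡ 0`), W_Ca is flat at `G_W`, and the strong states are
parabolas (`F = ∂G/∂x`, so linear force): S1_Ca with minimum `G_S1min` at
`x₁ > 0`, and S2_Ca/S2 sharing one parabola with minimum `G_S2min` at the
origin.  The S1→S2 shift of the minimum from `x₁` to 0 is the working
stroke.

**Tropomyosin coupling.**  Each of the `q + 1` tropomyosin fragments
between neighboring sites contributes an elastic energy depending on the
azimuthal positions (T/W/S) at its two ends: `U_{T;W}` and `U_{W;S}` are
elementary parameters and `U_{T;S} = (U_{T;W}^{1/4} + U_{W;S}^{1/4})^4`
follows from the fragment geometry (elongation energy scales as the fourth
power of the transverse displacement, and the T→S displacement is the sum
of the T→W and W→S displacements).  The exact geometric form is kept as an
internal oracle; the fourth-root approximation deviates from it by
`≈ 3·√(U/U_tr)` relatively (1.4 % at the reference energies), where
`U_tr = N_A K_tr d²/2 ≈ 3270 RT` at 310 K is the relaxed-fragment baseline
that cancels from every transition and never enters kinetics.

**Rates and thermodynamic consistency.**  Every directed rate is

```
k_AB(x,t) = exp(−ΔG_xb(x)/2RT) · h_AB · f_{αβ}(x) · p_{αβ}(l(t))
```

with a symmetric conformational factor, a tropomyosin factor `h` carrying
the fragment-energy change on one designated direction of each pair, a
fitted position profile `f` (a shared constant for the two Ca on/off
reactions, continuous piecewise-linear for the rest, with nodal *locations*
anchored to the free-energy landscape — profile minima and crossings — and
nodal *values* free parameters), and a symmetric sarcomere-length factor
`p` (hyperbolic `L1` class on the Ca reactions, quartic-exponential `L2` on
myosin attachment).  Calcium enters as a bimolecular factor: the transient
`Ca(t)` (quartic rise to `T_p`, Gaussian decay with `T_d`) multiplies the
two association directions only.

**ATP drive.**  The two cycle-completing detachments (S2→T and
S2_Ca→W_Ca) carry the hydrolysis free-energy drop: their symmetric factor
is boosted by `exp(+ΔG_ATP/2RT)` and the reverses suppressed equally
(`ΔG_ATP = 60 kJ/mol ≈ 23.3 RT` at 310 K).  This is the classical basic
free-energy convention for driven cycles: microscopic reversibility holds
exactly against the *full* thermodynamic force, and each completed cycle
dissipates one ATP.  This choice is load-bearing.  With a zero-affinity
reading (no drive anywhere) the clamped-calcium stationary state is a true
equilibrium whose stress reduces to a partition-function boundary term, the
resting state is a rigor-like strongly-bound pool, per-beat ATP counts are
non-positive for near-periodic beats, and no parameter set produces
sustained steady-state force–Ca curves — none of which resembles working
myocardium.  With the drive, the resting state is detached (strong states
drain through the boosted detachments), twitches relax, ATP per beat is
positive, and the clamped-Ca steady state is a genuine non-equilibrium
stationary state with sustained force.  The module invariant is therefore
`ln(k₊/k₋) = −(ΔG_conformational − ΔG_ATP·s)/RT` with `s = ±1` on the two
driven pairs and 0 elsewhere, verified exhaustively to 1e−12.

## Ensemble dynamics and numerics

Under the equal-position simplification (all cross-bridges of a group share
one strain coordinate), the group-state fractions obey an advection–reaction
system: `∂n_A/∂t + v(t) ∂n_A/∂x = Σ_B (k_BA C_BA n_B − k_AB C_AB n_A)` on a
periodic, cell-centered, uniform grid over one period (default 36–72
points; cell-centering makes odd force integrands cancel exactly).  `v` is
the half-sarcomere lengthening rate, which displaces `x` one-to-one.

- Reaction: linear and stiff (rates span ~15 orders of magnitude because of
  the `exp(±ΔG/2)` factors).  Long clamped-length integrations use BDF with
  the analytic sparse Jacobian (the group-transition graph lifted to the
  grid).  Short operator-split intervals on small group spaces (`5^q ≤ 30`
  states) use per-grid-point matrix exponentials with coefficients frozen
  at the interval midpoint — exact for the frozen system at any stiffness.
- Advection: first-order upwind with internal sub-stepping (CFL ≤ 1),
  operator-split (Strang) around the reaction step.  Each split interval is
  additionally limited to about one grid cell of total shift so that the
  steeply growing detachment rates act on dragged heads before the periodic
  re-parameterization could carry a bound head across the window.  Two
  boundary policies exist: `periodic` (default) and `reset-to-unbound`,
  which feeds the inflow edge with fully unbound groups.  Shortening
  protocols use reset-to-unbound — a bound head dragged past ±d/2 is
  force-detached rather than wrapped with its strain reset.
- Normalization (`Σ_A n_A = 1` per grid point) is monitored each step with
  a 1e−8 drift guard and restored after each split step; densities are
  clipped at zero.
- The clamped-Ca stationary state is solved per grid point from the linear
  balance system with one row replaced by normalization; on
  ill-conditioning it falls back to an SVD nullspace solve, and on genuine
  reducibility (e.g. zero calcium with closed pathways) it returns the
  all-unbound absorbing solution with a logged note.  An independent
  closed-form oracle (Boltzmann weights with a calcium fugacity) applies
  when the ATP drive is switched off and is used as a cross-check in tests.

**Protocols.**  Isometric beats integrate one period at fixed length.
Afterloaded (physiologic) beats run isometric until the active stress
reaches the afterload, then solve — per 1 ms interval, with a directional
bracket around the previous rate and Brent root-finding, quartering the
interval down to 1/64 ms on failure — for the constant sliding rate that
holds the end-of-interval stress at the afterload (within a ±8 nm/ms
physiological bound); once the solved motion re-lengthens the sarcomere to
its end-diastolic length the length is clamped there and relaxation is
isometric.  The end-systolic point is the point of minimum length.  When
the afterload exceeds the isometric peak the beat reduces exactly to the
isometric one.

**Observables.**  Active Cauchy stress is `m·l/(2d) · Σ_A ∫ n_A F_A dx`
per cross-bridge (group integrals divided by `q`); the alternative `m·l/d`
prefactor convention is available (`stress_prefactor_mode="full"`) because
both conventions circulate in this model family — the default halves the
stress scale relative to the alternative, and reported stress values in the
literature do not always state which one they use.  ATP turnover counts the net
flux through the two driven detachment directions, per cross-bridge;
per-beat consumption is its time integral.  The stress–strain area (SSA)
is the polygon bounded by the end-systolic stress–length relation (built
from isometric peaks, monotone-interpolated), the end-diastolic line (zero
here: passive stress is out of scope, so the isometric SSA reduces to the
strip under the ES line left of the working length) and the systolic
trajectory, evaluated in strain units referenced to the beat's
end-diastolic length (kPa·strain = kJ/m³).  Efficiency is
`SSA / (ATP_per_beat · c_myosin · ΔG_ATP)` with `c_myosin = 0.18 mol/m³`.
Force–Ca curves normalize the stationary stress by a plateau: either the
maximum over the evaluated grid (default) or the stress at a deeply
saturating anchor concentration — the anchor avoids a spurious divergence
of the logit slope near the top grid point and is used for all Hill-slope
analyses.  Hill slopes are centered differences of `logit(F_norm)` against
`log₁₀ Ca`.

## Reference parameter set (fixture)

Measured constants: `d = 36 nm`, `K_tr = 21.6 pN/nm`, `U_TW = 0.1 RT`,
`U_WS = 0.05 RT`, length window 0.8–1.1 μm, `c_myosin = 0.18 mol/m³`,
`ΔG_ATP = 60 kJ/mol`, T = 310 K.  Everything else — profile depths and
stiffnesses (`G_W = −0.8`, `G_S1min = −3`, `x₁ = 8.5 nm`, `K_S1 = 0.2`,
`G_S2min = −17`, `K_S2 = 0.4 RT/nm²`), rate nodal values, length factors
(`p_L1 = 0.24`, `p_L2 = 4.08`), calcium times (`T_p = 35 ms`,
`T_d = 80 ms`, amplitude 1 by convention, beat period 400 ms) — is a
package fixture.  It was calibrated once, with the package's own
least-squares machinery, to the conditions the energetic formalism
specifies: a physiological isometric twitch family (peak stress rising from
16 to 61 kPa across 0.95–1.1 μm, relaxation below 5 % of peak within the
beat), positive ATP turnover, and the energetic constraint that
`V_ATP/SSA` approaches `η = 0.142 kJ⁻¹m³` (65 % efficiency) across runs.
The detachment reactions carry the `e^{ΔG_ATP/2RT} ≈ 10⁵` drive, so their
nodal values are of order 1e−5 — the *rates* they produce are ordinary
(0.01–1 /ms).

Known tensions of the fixture, measured explicitly:

- **Linearity vs efficiency.**  The SSA–ATP relation across the sweep
  (four isometric lengths plus afterloads 20–80 kPa) is strongly linear,
  R² = 0.97, but the trade-off frontier between linearity and the 60–70 %
  efficiency band was mapped and R² ≥ 0.98 is only reachable at ~55 %
  efficiency.  Two real mechanisms cause the residual scatter: the
  shortest-length beat has an ATP floor (cycling falls more slowly with
  length than the ES-line area), and shortening beats consume extra ATP
  relative to their SSA — the Fenn effect, which the model genuinely
  expresses.  The efficiency band was prioritized since it is an
  experimental constraint.
- **Single-site Hill bound.**  The maximum Hill slope of the q=1,
  zero-coupling model is ≈ 1 for the reference fixture (0.999) and for
  most random fixture-family draws, but it is *not* a structural bound:
  the five-state scheme has two calcium-binding reactions per site
  (troponin activation and Ca rebinding to the post-stroke head), so the
  stationary occupancies are degree-2 rational functions of Ca and
  individual parameter sets can reach slopes up to ~1.2.  Genuine
  cooperativity through tropomyosin coupling is far stronger: scaling
  (U_TW, U_WS) by 10–20× raises the maximum slope to 2.5–3.0 (q=3) and
  2.8–3.6 (q=4), always steeper below half-activation than above it.
- Afterloads of 60 and 80 kPa exceed the fixture's isometric peak at the
  1.05 μm working length, so those sweep members legitimately reduce to
  the isometric beat.

## What the synthetic data do and do not emulate

`generate_twitch_dataset` produces isometric stress transients at several
lengths sampled every 5 ms with independent Gaussian noise, end-systolic
points and the afterload list — the record shapes the fitting residuals
consume.  It emulates sampling cadence and additive measurement noise of
force-transducer recordings; it does not emulate autocorrelated noise,
run-to-run drift, sarcomere-length measurement error, passive (titin/ECM)
stress, or twitch-to-twitch calcium variability.  Passing recovery tests
therefore demonstrate identifiability of the rate parameters under the
model's own dynamics, not robustness to real experimental artifacts.

## Fitting

The residual has three parts: (I) isometric stress transients, weighted by
`(P_max − P_co)·N_isom/10` with `P_max` the maximum measured stress (the
source leaves it undefined) and the weight denominator floored at
`0.05·P_max`; (II) end-systolic length gaps between afterloaded beats and
the monotone-interpolated isometric ES relation, weighted by
`(l_phy − l_min)·N_isot/5` with `l_phy = 1.05 μm`, `l_min = 0.8 μm`; and
(III) the energetic constraint `(V_ATP/SSA − η)/(η·N_SSA)`.  Optimization
is two-tier: an exhaustive outer grid over free-energy/coupling parameters
(`G_S1min`, `x₁`, `G_S2min`, `U_TW`, `U_WS`; the latter two pinned to zero
for q=1) and, per combination, bounded trust-region damped least squares
over the rate nodal values.  Nodal x-locations are recomputed from the
current profiles at every evaluation, since they move with the profile
parameters; nodal values are the optimized quantities.

## Stochastic oracle

A single group at fixed strain, clamped calcium and fixed length is a
continuous-time Markov chain; `ctmc_simulate` runs a Gillespie simulation
(exponential waiting times, categorical next states), discards the first
10 % of events as burn-in from the all-unbound start, and reports
time-weighted occupancies with batch-means standard errors (50 batches).
Agreement with the deterministic stationary solution within three standard
errors (plus a 1e−3 absolute floor for states whose error bars are
unresolved at 10⁵ events, where batch means under-estimate the serial
correlation) is the package's central cross-check between its stochastic
and ensemble descriptions.

## Problem sizes used by the test and acceptance runs

Twitch-level checks run at q = 1 (5 group states) or q = 3 (125) on a
36-point grid with 400 ms beats; steady-state analyses extend to q = 4
(625 states).  The grid-refinement property is checked at 64 vs 128 points
(first-order scheme, ~1 % stress agreement).  These sizes resolve the
strong-state parabolas (0.5–1 nm spacing) and were chosen as the package's
standard working resolution; all are configurable.

## Known limitations

- Only the equal-position simplification of the general q-dimensional
  ensemble density is implemented; arbitrary initial group-position
  distributions and the associated coordinate transformation are out of
  scope.
- No passive stress, sarcomere inhomogeneity, explicit nucleotide
  (ATP/ADP/Pi) concentration dependence, or beat-to-beat calcium dynamics.
- The periodic strain window with forced detachment at its edges is an
  approximation for shortening beats whose travel exceeds one
  regulatory-unit period.
- The stress prefactor convention (factor of two) is genuinely ambiguous
  in this model family; both are implemented and the choice is a
  configuration switch.
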