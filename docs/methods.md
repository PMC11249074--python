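# Methods

## Model

`fibersim` integrates a two-variable mechanohydraulic model of a single
elongating cotton fiber. The state is fiber volume $V$ (m³) and fiber
osmotic pressure $\pi_\mathrm{fiber}$ (Pa); fiber turgor is recovered
algebraically at every instant. The assumptions, in decreasing order of
importance:

- **Purely hydraulic volume change.** Water is incompressible, so
  $dV/dt$ equals the sum of the membrane flux
  $F_m = L_r V(\Delta\pi - \Delta P)$ and the plasmodesmal flux
  $F_p = -\mu \Delta P$. The membrane area of a long cylinder is
  proportional to its volume, which is why a single *relative*
  conductivity $L_r$ (Pa⁻¹ s⁻¹) suffices and no radius appears.
- **Viscoplastic wall, no elasticity.** Irreversible expansion follows the
  Lockhart law $(1/V)\,dV/dt = \phi (P_\mathrm{fiber}-Y)_+$. Elastic
  strains (≲10% even for soft walls) are negligible against the fiber's
  thousand-fold elongation, so they are not modeled; consequently volume
  never decreases.
- **Turgor eliminated, not integrated.** Pressure equilibrates much faster
  than volume or composition change, so expansion and net influx balance
  instantaneously. Solving that balance gives the piecewise-linear closed
  form for $\Delta P$ (growth and no-growth branches, continuous at the
  switching surface). The simulator always advances $dV/dt$ as
  $\mathrm{rgr}\cdot V$ from this closed form; $F_m + F_p$ is kept as an
  independent cross-check of the same quantity (the test suite verifies
  the identity to rounding relative to the gross flux scale
  $L_r V |\Delta\pi|$, against which the two fluxes can cancel almost
  exactly in the no-growth branch).
- **Solutes as one pool, advection only.** A single normalized source
  $\alpha$ (Pa s⁻¹) lumps uptake, synthesis and cleavage (e.g. by
  invertases). Plasmodesmal transport carries the upstream concentration
  — seed on inflow, fiber on outflow — and diffusive exchange is
  neglected, justified because concentration differences are small
  whenever the channels are open. Concentrations are expressed as osmotic
  pressures throughout ($\pi = cRT$, dilute limit), so the gas constant
  and temperature never appear explicitly.
- **Stationary environment.** The seed coat has stopped expanding:
  $\pi_\mathrm{seed}$, $P_\mathrm{seed}$ and the apoplast water potential
  are constants (or, in dynamic scenarios, only $\phi$, $\mu$, $\alpha$
  vary in time).

## Parameters

All internal computation is strict SI (m³, Pa, s); hours, mm³ and MPa occur
only at the I/O boundary with exact conversion constants (3,600 s/h,
10⁻⁹ m³/mm³, 10⁶ Pa/MPa). The packaged biological ranges and the derived
reference values (geometric means of the range limits — appropriate for
ranges spanning up to five decades):

| parameter | meaning | unit | range | reference |
|---|---|---|---|---|
| $L_r$ | relative membrane hydraulic conductivity | Pa⁻¹ s⁻¹ | 5×10⁻⁹ – 5×10⁻⁶ | 1.58×10⁻⁷ |
| $\mu$ | total plasmodesmal permeability | m³ Pa⁻¹ s⁻¹ | 1.35×10⁻²⁶ – 3.3×10⁻¹⁹ | 6.67×10⁻²³ |
| $\alpha$ | normalized solute source | Pa s⁻¹ | 83 – 167 | 118 |
| $\pi_\mathrm{seed}$ | seed osmotic pressure | Pa | 0.99×10⁶ – 1.29×10⁶ | 1.13×10⁶ |
| $P_\mathrm{seed}$ | seed turgor | Pa | 0.7×10⁵ – 1.8×10⁵ | 1.12×10⁵ |
| $Y$ | yield turgor threshold | Pa | 0.6×10⁵ – 2.0×10⁵ | 1.10×10⁵ |
| $\phi$ | wall extensibility | Pa⁻¹ s⁻¹ | 1.1×10⁻¹² – 2.5×10⁻¹¹ | 5.24×10⁻¹² |

Standard initial conditions: $V(0) = 1.88\times10^{-13}$ m³ and
$\pi_\mathrm{fiber}(0) = \pi_\mathrm{seed}$; horizon 500 h (the natural
duration of fiber elongation) except for the closure-timing sweep, which
runs to 3,000 h so that late or long closures can still express their
effect on final size. Only the first few hours of any run depend on the
initial osmotic pressure.

A wall thickness and a wall yield *stress* could be added to a more
mechanical wall description; in this volume-based formulation only the
yield *turgor* $Y$ is meaningful, and no wall-geometry parameter exists.

## Numerics

- **State and stepper.** The integrated state is $(\ln V,
  \pi_\mathrm{fiber})$: volume grows by factors up to $e^{200}$ over
  3,000 h horizons and log-volume keeps relative error uniform (a test
  confirms results are tolerance-invariant against a tighter
  integration). The stepper is LSODA (adaptive, switches to BDF when
  stiff); extreme corners of the ranges — large $\mu$, large $L_r$ — make
  the osmotic relaxation orders of magnitude faster than the growth
  timescale, and an explicit-only method would crawl there.
- **Non-smoothness.** The positive parts in the growth law and the solute
  advection terms are implemented exactly, not smoothed: smoothing would
  shift the growth threshold, to which the sensitivity table is directly
  sensitive. The right-hand side is therefore only piecewise smooth.
  Schedule discontinuities (closure windows, pulses, the decay endpoint)
  are handled by splitting the integration at every breakpoint rather
  than letting the solver discover them; window membership within a
  segment is frozen at the segment midpoint, so the solver never
  evaluates across an edge. Window boundaries belong to the window
  (closed interval) — a measure-zero convention fixed for deterministic
  output.
- **Default tolerances.** `rel_tol = 1e-8` (absolute: 10⁻¹⁰ on $\ln V$,
  10⁻² Pa on $\pi$) for ordinary runs; 10⁻¹⁰ for finite-difference
  sensitivity work, where the smallest tabulated responses are of order
  10⁻⁵ and solver noise must sit well below the signal. Output is 2,001
  uniform samples by default — enough to resolve 50 h windows in a
  3,000 h horizon.
- **Sensitivity.** $S(X,x) = (x_\mathrm{ref}/X)\,\partial X/\partial x$ is
  estimated by central differences with step $h = 1\%$ of the reference
  value (inside the ±10% exploration window; a step-halving test confirms
  convergence to well under 1%). $S$ of the log volume ratio is invariant
  to the logarithm's base — the base constant cancels between $X$ and its
  derivative — so natural log is used without loss. The maximal-change
  statistic uses a log-spaced grid (default 33 points) with endpoints
  included, so monotone observables get their exact extremes.
- **Steady state and extrema.** A pressure counts as stationary when its
  current rate, extrapolated over the whole horizon, would change it by
  less than 1% of itself. Extremum detection discards the first 5% of the
  horizon (initial-condition transient) and requires a point to exceed
  both neighbors by 10⁻⁹ of the variable's scale, suppressing solver
  ripple. Flat trajectories classify as `monotonic_increasing` by
  convention. A trajectory with a maximum followed by a minimum — the
  shape transient plasmodesmata closure produces — is labelled
  `non_monotonic_other` by the classifier; the scenario runners therefore
  report the extrema list itself, from which "peak followed by transient
  drop" is read off directly.

## Behavior analysis and scenarios

With constant parameters anywhere in the biological ranges, both pressures
are monotonic. The package carries this result in two forms. First, an
analytic screen: a pressure peak under constant parameters requires
$\alpha < \phi L_r (Y - P_\mathrm{seed})\,
(\phi (Y-P_\mathrm{seed}) - L_r \pi_\mathrm{seed})$
*and* fiber turgor initially below seed turgor. The inequality is
evaluated verbatim in this product form even though its two sides do not
carry the same units (the diagnostics helper flags this known defect);
within the biological ranges its right side is either negative or
vanishingly small against $\alpha \geq 83$ Pa s⁻¹, so the condition fails
everywhere, and the second requirement contradicts the measured initial
state. Second, and authoritatively, the numerical classifier: random
constant-parameter models drawn log-uniformly from the ranges all
classify monotonic (500 draws in the test suite).

The dynamic scenarios make one parameter time-dependent:

- `phi_decay` — extensibility falls linearly from its reference value at
  0 h to zero at 500 h: growth arrests exactly when $\phi$ reaches zero,
  with final pressures below the reference run's.
- `mu_closure` — plasmodesmata shut ($\mu = 0$) during [200 h, 250 h]:
  both pressures spike (the solute leak to the seed is interrupted while
  the source keeps running) and transiently drop after reopening.
- `alpha_pulse` — the source steps to its range maximum (167 Pa s⁻¹)
  during [200 h, 250 h]. The pulse window mirrors the closure window;
  onset, duration, and plateau are configurable, and the rectangular
  shape is a deliberate simplification (a trapezoid can be substituted
  via a custom schedule). Its pressure peak is much smaller than the
  closure peak — solute dynamics is a minor contributor compared with
  plasmodesmata gating.
- `combined` — decay and closure together: a pressure peak on a
  background that later rises again as extensibility vanishes.
- the closure sweep — final volume at 3,000 h over a grid of closure
  start times $t_0$ and durations $t_\mathrm{dist}$ (default 0–500 h in
  50 h steps each), normalized by the cell at $t_0 = 200$ h,
  $t_\mathrm{dist} = 50$ h. Earlier and longer closure both favor longer
  fibers; closures starting after the fiber has grown large have no
  effect, because the plasmodesmal leak scales as $\mu/V$ and is already
  negligible.

## What the fixture generator emulates — and does not

`generate_fixture` draws parameter sets log-uniformly and independently
per parameter from the biological ranges (log-uniform because the ranges
span decades and the reference point is itself a geometric mean). This
emulates *parametric* uncertainty across tissues, species and
measurement methods. It does not emulate measurement noise on
trajectories, correlations between parameters (e.g. co-regulation of
aquaporins and solute transporters), spatial heterogeneity along the
fiber, or the mechanism of plasmodesmata gating itself — scheduled
closure is imposed, not emergent. Tests passing on these draws therefore
establish the model's behavior over the stated ranges, not the model's
fidelity to any particular fiber dataset.

## Known limitations

- One spatial degree of freedom: no tip geometry, no radius dynamics, no
  gradients along the fiber, no mechanical coupling to neighboring
  fibers.
- The analytic peak screen is a necessary-condition check only; the full
  enumeration of qualitative behavior types is out of scope, and the
  numerical classifier is the source of truth.
- Solute biology is compressed into one source constant; no distinct
  sugars, ions, or transporter kinetics.
- The model deliberately keeps growing exponentially once pressures
  plateau; physical arrest requires the extensibility-decay scenario.
  Long-horizon volumes are meaningful as comparative measures (ratios),
  not as literal fiber sizes.

## Problem sizes used in the checks

The test suite and the acceptance script run the model at the defaults
stated above: 2,001-sample output grids, 500 h horizons (3,000 h for the
closure sweep's 11×11 grid), 500 random draws for the classifier scan and
1,000 for the analytic screen and the root-finding cross-check. The full
suite completes in well under a minute on one core.
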