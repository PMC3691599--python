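# Methods

This note documents the models implemented in `remethyl`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer should know about.

## 1. Phenomenological recovery model

A demethylated locus recovering its methylation is described by

    f(t) = y0 + y1 * tanh(m*t - b),

with `t` in days since the end of treatment. The exact sigmoid is not
essential; what matters is that the function captures a climb from one
level to another with two extractable characteristics: the climb rate
`m` (day⁻¹) and a delay. Because `b` is a *scaled* time (the argument
`m*t - b` is dimensionless), `m` and fitted `b` co-vary strongly, and
the physically meaningful delay is `b' = b/m` in days — equivalently
`f(t) = y0 + y1*tanh(m*(t - b'))`. Fitting is performed in the `(m, b)`
parameterization and `b'` derived afterwards. Derived levels:
initial `y0 - y1*tanh(b)`, target `y0 + y1`.

### Fitting

Nonlinear least squares (`scipy.optimize.least_squares`, trust-region
reflective, tolerances 1e-14) with a data-driven start (`y0` = mean
level, `y1` = half the range, `m` from the steepest finite-difference
slope divided by `y1`, `b` = `m` × time of half-rise) plus three
restarts that jitter `m` (lognormal, sd 0.7) and `b` (normal, sd 2):
the rate/delay trade-off along the tanh plateau creates local minima.

Bounds: `y1 > 0`; levels within [−25, 125] (25 points of slack lets a
still-rising curve extrapolate past 100); `b ∈ [−10, 60]`; and
`m ∈ (1e-4, 1.0]` day⁻¹. The upper rate bound is an identifiability
cut: with samples 3–5 days apart, a rise completed between two adjacent
samples (`m` ≳ 1) carries no rate information, and unbounded fits of
step-like noise produce arbitrary large rates. A fit pinned at any
bound is flagged non-converged and the run is excluded as erratic.

### Run triage

Runs are classified before entering any correlation analysis, in order:
`base_too_low` (baseline `B` < 5 percentage points), `insufficient_drop`
(relative drop `(B-A)/B` < 0.10), `no_reclimb` (negative linear trend,
or fitted net climb over the window < 5 points), `erratic` (fit failed
to converge), else `successful`. The three thresholds are package
defaults — the source screening narrative is verbal, not numeric — and
are configurable per run; every exclusion is logged with its reason.
`A` is read as the first post-treatment observation (a convention; the
drop level has no operational definition in the source narrative).

## 2. Correlation screen

Quantities screened: fitted (`m`, `b`, `b'`, `y0`, `y1`, `y0+y1`) and
directly read (`B`, `A`, `(B-A)/B`, `L`, `L/B`). For every unordered
pair: Pearson `r` with a two-sided p from `t = r*sqrt((n-2)/(1-r²))` on
`n-2` df; Spearman rho on average ranks with the same `t` transform
(an exact permutation p is available for `n ≤ 10`; enumeration of `n!`
permutations, so practical up to `n ≈ 8`); OLS slope and intercept.
Diagonal pairs are defined as `r = 1, p = 0`; constant columns or pairs
with fewer than 4 complete observations are reported as missing, never
silently dropped or zeroed. Raw p-values are the primary output
(matching the presentation this screen reproduces); a Benjamini–
Hochberg–adjusted column is emitted alongside, labelled as an
extension. Two-sided tests throughout.

Note on the synthetic panels: because the generator gives CIMP lines
both high baselines and near-zero onset delays, `b'` and `B` are
negatively correlated *in the synthetic panels by construction*. In the
screen on real data the delay `b'` need not correlate with baseline —
the two regimes' delay structure, not the panel's correlation pattern,
is the feature being emulated.

## 3. Feedback ODE model

States: locus methylation `x` (capacity `k1`), aggregate feedback-sensor
methylation `w` (capacity `k2`), production cascade `y1..yn` whose last
element `yn` is active MTase:

    dx/dt  = lam*yn*(1 - x/k1) - a1*x      (a1 only during treatment)
    dw/dt  = gam*yn*(1 - w/k2) - a2*w      (a2 only during treatment)
    dy1/dt = P(w) - q*y1
    dyi/dt = q*(y_{i-1} - y_i)             (1 < i < n)
    dyn/dt = q*y_{n-1} - delta*yn

with `P(w) = eta*max(c - w, 0)` in the feedback (non-CIMP) mode and
`P(w) = eta` in the constant (CIMP) mode — the mode switch itself is
the CIMP lesion. Reference parameters: `lam=0.4, k1=0.04, a1=4, gam=80,
k2=100, a2=0.4, eta=2, c=10, q=0.8, delta=4000`, time in days.
Treatment is a 72-hour window during which `a1, a2` act; leaving them
permanently on would drive `x` to zero after feedback shutoff, so they
are strictly window-gated. Reported methylation is `100*x/k1` (and
`100*w/k2`): capacities are arbitrary units, percent of capacity is the
observable.

Key consequences, all covered by tests:

* `delta` is 3–4 orders of magnitude above every other rate, so `yn` is
  a quasi-steady readout `P/delta` of the cascade input, and the system
  is stiff.
* Untreated feedback mode from a fully unmethylated start: eliminating
  time between the `x` and `w` equations (both driven by `yn`) gives
  `x*/k1 = 1 - (1 - c/k2)^(lam*k2/(gam*k1))` — 73.2% at the reference
  parameters (exponent 12.5). This closed form is verified against
  direct integration (within 0.2 points) and is independent of the
  cascade length `n`, which only shapes transients.
* Post-treatment, sensors retain more methylation than the locus
  (`a2 << a1`), so they regain the set-point first and shut production
  down before the locus regains its old level: the locus stabilizes
  *below* its pre-treatment baseline.
* `n_stages` (default 3; never fixed by the source, so exposed as a
  knob) sets the re-activation delay of the feedback mode.

### Numerics

`solve_ivp` with LSODA, `rtol 1e-8`, `atol 1e-12` (states range from
~4e-2 down to ~5e-4). Integration is piecewise between treatment-window
edges — the only genuine discontinuities — with a non-terminal event at
`w = c` to keep steps honest around the set-point; the production gate
itself is continuous (`max(c-w, 0) → 0` at the threshold). Scenario
timelines (300 days equilibration, 3-day treatment, 300 days recovery,
4 output points/day) are reconstructions chosen so every state settles;
only the 72-hour treatment duration is prescribed by the source design.

### Recovery metrics

For a post-treatment trajectory we report the final level, the maximum
finite-difference slope of `x_pct`, and an **onset delay** defined as
the classic lag time: the maximum-slope tangent extrapolated back to
the post-treatment floor, measured from treatment end (clipped at 0).
A concave climb that is fastest immediately has zero lag; a sigmoid
that gains momentum later has positive lag. A "time to reach a fixed
fraction of the eventual gain" statistic was rejected: the CIMP mode's
recovery is an immediate exponential saturation with time constant
`k1*delta/(lam*eta)` = 200 days, so any fixed-fraction time scales with
the observation window and cannot express "starts immediately". The
tangent definition yields 0.0 days (CIMP) vs ≈0.55 days (non-CIMP) at
the reference parameters. Runs with no treatment window or no
post-treatment gain (< 0.5 points) are flagged undefined.

## 4. Growth kinetics

`x(t) = A0*e^{g*t}` is fitted to live counts by least squares on the
natural scale (the log-linear fit is only the initializer — the model
is fitted, not its logarithm). With dead cells removed at each count,
the expected dead count over `(t_{i-1}, t_i]` is
`phi_i*d` with `phi_i = (A0/g)(e^{g t_i} - e^{g t_{i-1}})`
(limit `A0*Δt` for `|g| < 1e-8`); linearity in `d` makes the estimate
the exact ratio `Σ y_obs*phi / Σ phi²` (unweighted intervals). `phi_i`
is positive for any `g`, so non-negative counts always give `d ≥ 0`;
a negative estimate (possible only for inconsistent inputs) is
truncated to 0 with a warning. Division rate `b = g + d`. Scaling all
counts by `k` scales `A0` by `k` and leaves `g, d` unchanged.

## 5. Synthetic-data generator

The generator emulates the *statistical structure* of the study design:
4 cell lines (2 CIMP, 2 non-CIMP) × 7 loci, ~10 sampling days over 50
days (denser early), percent-scale observations.

Per-run true parameters:

* Baseline `B ~ N(60, 8)` for CIMP, `N(25, 8)` for non-CIMP (clipped to
  [1, 99]) — CIMP lines are hypermethylated at baseline.
* Rate `log m ~ N(log 0.063, 0.7)`, i.e. `m` spanning roughly
  0.01–0.40 day⁻¹, drawn conditionally on the standardized baseline so
  that corr(`m`, `B`) over the panel equals the planted coefficient
  (default −0.6). The Gaussian-scale coefficient is pre-compensated by
  `sqrt(e^{σ²}-1)/σ` because exponentiation attenuates correlations;
  the group contrast in `m` (CIMP slower) then *emerges from* the
  planted negative correlation rather than being imposed separately.
* Onset delay `b' ~ U(0, 2)` days for CIMP (immediate), `U(8, 20)` for
  non-CIMP (delayed); `b = m*b'`.
* Levels: post-drop level `A = U(0.10, 0.35)*B`, target
  `y0 + y1 = U(0.80, 1.00)*B`, with `(y0, y1)` solved so the curve
  starts exactly at `A`.

Observations are the curve plus i.i.d. Gaussian noise (default sd 2
percentage points — no noise model is stated by the source, so this is
a configurable stand-in) clipped to [0, 100] after noise (simpler than
truncated sampling and faithful to a bounded percent readout).

Cell counts: live `A0*e^{g*t}` and interval dead counts from the closed
form above, each multiplied by independent lognormal noise of given
relative sd (mean-one parameterization). The pipeline's growth study
draws per-line rates independently of methylation (a null), with
control/treated means 0.45/0.25 day⁻¹ (growth) and 0.03/0.12 day⁻¹
(death).

**What passing tests do and do not show.** The generator produces
locus-level percent methylation that lies exactly on a delayed-tanh
curve up to additive noise. Real pyrosequencing data carry per-CpG
structure, bisulfite-conversion and PCR biases, non-Gaussian and
level-dependent noise, and recovery shapes that need not be tanh.
Recovery and calibration results on these panels therefore validate the
*procedure* (estimator consistency, screen calibration, planted-signal
detection), not the biological adequacy of the tanh form.

## 6. Problem sizes and reproducibility

Every stochastic stage takes an explicit integer seed; the pipeline
spawns per-stage seeds from one root seed via `numpy.random.SeedSequence`,
and a fixed configuration reproduces byte-identical outputs. Test-suite
simulation sizes — 1000 seeded panels for the planted-correlation
check, 100 noise replicates for parameter recovery, 2000 replicates for
screen calibration (drawn as n=18 bivariate-normal pairs at the planted
correlation, which is the property under test), ODE spans of 600–1500
days — were chosen as the smallest sizes at which the Monte-Carlo error
is well below the asserted tolerances.

## 7. Known limitations

* The tanh rate `m` is weakly identified when the climb is much faster
  than the sampling interval; such runs are excluded rather than
  reported with meaningless rates.
* `b'` for near-immediate runs (`b' ≈ 0`) has large *relative* error by
  definition; recovery guarantees are stated for the delayed regime.
* The ODE model is deliberately phenomenological: the cascade stands in
  for unknown regulatory steps, sensors are an aggregate, and no
  stochastic (per-cell or per-molecule) effects are modelled.
* The growth model assumes constant exponential growth and constant
  death rate over the counting window; no density dependence.
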