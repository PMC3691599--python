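# remethyl

Tools for quantifying **DNA remethylation kinetics** in cancer cell lines
after treatment with a demethylating agent (5-aza-2′-deoxycytidine,
"5-AZA"), and for exploring a mechanistic explanation of why CpG-island
methylator phenotype (CIMP) cells — despite their hypermethylated genomes —
re-methylate *more slowly* than non-CIMP cells once demethylated.

The package is aimed at computational epigenetics groups who have
locus-level percent-methylation time-series (e.g. from bisulfite
pyrosequencing) for a panel of cell lines, and at modellers who want a
compact dynamical model of feedback-regulated de novo methyltransferase
(DNMT/MTase) activity.

## What it does

1. **Delayed-tanh curve fitting** (`remethyl.tanh_fit`). Each run's
   recovery is fitted with

   *f*(*t*) = *y*₀ + *y*₁ tanh(*mt* − *b*) = *y*₀ + *y*₁ tanh(*m*(*t* − *b*′)),

   where *m* (day⁻¹) is the remethylation rate, *b* the dimensionless
   onset, *b*′ = *b*/*m* the onset delay in days, *y*₀ − *y*₁ tanh(*b*)
   the post-treatment level and *y*₀ + *y*₁ the target level. Runs are
   triaged (successful / baseline too low / insufficient drop / no
   re-climb / erratic) before analysis.

2. **Systematic correlation screen** (`remethyl.correlations`). Every
   pair drawn from the fitted quantities (*m*, *b*, *b*′, *y*₀, *y*₁,
   *y*₀+*y*₁) and the directly-read ones (baseline *B*, post-drop level
   *A*, (*B*−*A*)/*B*, final level *L*, *L*/*B*) gets Pearson *r* (p from
   the *t* transform), Spearman ρ (*t* approximation; exact permutation
   available for n ≤ 10) and an OLS slope, plus a symmetric p-value grid
   with sign annotations and per-cell-line means.

3. **Feedback ODE model** (`remethyl.feedback_ode`). A locus *x* and a
   pool of feedback-sensor loci *w* are methylated by active MTase *yₙ*
   fed by a production cascade *y₁…yₙ*. In non-CIMP cells production is
   η(*c* − *w*), shutting off when sensors reach the set-point *c*; in
   CIMP cells the feedback is corrupted and production is the constant η.
   This reproduces the observed contrast: non-CIMP cells re-methylate
   fast after a delay, CIMP cells immediately but slowly. An analytic
   steady state, *x*\*/*k*₁ = 1 − (1 − *c*/*k*₂)^(λ*k*₂/γ*k*₁), serves as
   an independent oracle for the stiff integrator.

4. **Growth kinetics** (`remethyl.growth`). Net growth rate *g* from an
   exponential fit *A*₀e^{gt} to live counts, death rate *d* from the
   closed-form interval dead counts (linear in *d*, so the estimate is
   exact), division rate *b* = *g* + *d*.

5. **Synthetic study panels** (`remethyl.synthetic`). Seeded generators
   for methylation panels (4 lines × 7 loci by default, CIMP lines with
   high baselines and short onset delays, a planted negative rate-vs-
   baseline correlation) and cell-count series, retaining the true
   parameters for recovery testing.

6. **Pipeline** (`remethyl.pipeline`, CLI `remethyl`). One seeded run of
   generate → fit → classify → correlate → simulate → growth → report.

## Worked example

```bash
remethyl all --seed 11 --out demo
```

runs the full pipeline on a synthetic 28-run panel and prints the
headline tests from `demo/summary.json`. With seed 11:

* 24 of 28 runs fit successfully; 4 are excluded as erratic (the fit did
  not converge), each logged with its reason.
* Rate vs baseline: Pearson *r* = −0.474 (p = 0.019), Spearman
  ρ = −0.502 (p = 0.012), n = 24 — the planted negative correlation is
  recovered: lines with the highest baseline methylation re-methylate
  slowest.
* Rate vs onset: *r* = +0.887 (p ≈ 8×10⁻⁹) — *m* and *b* co-vary by
  construction, which is why the delay is better measured by
  *b*′ = *b*/*m*.
* Mean rate by phenotype: non-CIMP 0.122 day⁻¹ vs CIMP 0.055 day⁻¹.
* ODE scenarios: the feedback run (`feedback`) equilibrates at 73.2% locus
  methylation, then after a 72-hour treatment recovers with a 0.55-day
  lag and a maximum slope of 2.78 %/day to a *lower* final level
  (60.4%); the constant-production run (`constant`) restarts with zero lag
  but a 0.50 %/day maximum slope.

Library use mirrors the CLI:

```python
from remethyl import PanelConfig, generate_methylation_panel, fit_tanh

panel = generate_methylation_panel(PanelConfig(seed=11))
fit = fit_tanh(panel[0])
print(fit.m, fit.b_prime)   # rate (1/day), onset delay (days)
```

## Layout

```
src/remethyl/      synthetic.py, tanh_fit.py, correlations.py,
                   feedback_ode.py, growth.py, pipeline.py, cli.py
tests/             pytest suite (unit, property and end-to-end checks)
docs/methods.md    model, assumptions, parameter choices, limitations
```
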