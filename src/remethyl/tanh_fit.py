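"""Delayed-tanh fitting of remethylation time-series.

A run's percent-methylation recovery after a demethylating pulse is
modelled as

    f(t) = y0 + y1 * tanh(m * t - b)

where ``m`` (per day) is the remethylation rate, ``b`` the dimensionless
onset, ``y0 - y1 * tanh(b)`` the initial (post-treatment) level and
``y0 + y1`` the target level.  Since ``m`` and ``b`` vary together, the
natural time-scale of the delay is ``b' = b / m`` (days), i.e. the
equivalent parameterization f(t) = y0 + y1 * tanh(m * (t - b')).  The fit
is done on the (m, b) parameterization and ``b'`` derived afterwards.

Runs are classified as successful or excluded (baseline too low, no
post-treatment drop, no re-climb, erratic/non-convergent) before they
enter any correlation screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .synthetic import MethylationTimeSeries

__all__ = [
    "TanhFitResult",
    "FitThresholds",
    "RunStatus",
    "RunSummary",
    "eval_tanh",
    "fit_tanh",
    "derive_quantities",
    "classify_run",
    "analyze_panel",
]

#: extra headroom above 100% allowed for y0 and y0+y1 during fitting, so a
#: curve still rising at the last day may extrapolate slightly past 100.
AMPLITUDE_SLACK = 25.0


@dataclass(frozen=True)
class TanhFitResult:
    """Least-squares estimates of the delayed-tanh parameters."""

    y0: float
    y1: float
    m: float
    b: float
    rss: float
    converged: bool

    @property
    def b_prime(self) -> float:
        """Onset delay in days, b / m."""
        return self.b / self.m

    @property
    def initial_level(self) -> float:
        return self.y0 - self.y1 * math.tanh(self.b)

    @property
    def target_level(self) -> float:
        return self.y0 + self.y1


@dataclass(frozen=True)
class FitThresholds:
    """Exclusion thresholds, in the units of the quantities they gate.

    The screening narrative gives no numeric cut-offs, so these defaults
    are package choices and configurable per run.
    """

    base_pct: float = 5.0      # minimum baseline B to analyze a run
    drop_frac: float = 0.10    # minimum relative drop (B - A) / B
    climb_pct: float = 5.0     # minimum fitted net climb over the window


@dataclass(frozen=True)
class RunStatus:
    status: str  # successful | base_too_low | no_reclimb | insufficient_drop | erratic
    reason: str = ""

    @property
    def successful(self) -> bool:
        return self.status == "successful"


@dataclass(frozen=True)
class RunSummary:
    """One row of the correlation screen: fitted and directly-read quantities."""

    cell_line: str
    locus: str
    m: float
    b: float
    b_prime: float
    y0: float
    y1: float
    B: float           # baseline methylation, %
    A: float           # first post-treatment observation, %
    rel_drop: float    # (B - A) / B
    L: float           # last observed level, %
    rel_final: float   # L / B
    target: float      # y0 + y1


def eval_tanh(y0: float, y1: float, m: float, b: float, t):
    """Evaluate y0 + y1 * tanh(m * t - b); vectorized over ``t``."""
    return y0 + y1 * np.tanh(m * np.asarray(t, dtype=float) - b)


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------

def _initial_guess(days: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """Data-driven start: y0 = mean, y1 = half range, m from the steepest
    finite-difference slope, b = m * (time of half-rise)."""
    y0 = float(levels.mean())
    y1 = max(float(levels.max() - levels.min()) / 2.0, 1e-3)
    slopes = np.diff(levels) / np.diff(days)
    m = max(float(slopes.max()) / y1, 1e-3) if slopes.size else 1e-2
    half = levels.min() + (levels.max() - levels.min()) / 2.0
    above = np.nonzero(levels >= half)[0]
    t_half = float(days[above[0]]) if above.size else float(days[len(days) // 2])
    b = m * t_half
    return np.array([y0, y1, m, b])


def fit_tanh(series: MethylationTimeSeries, n_restarts: int = 3, seed: int = 0) -> TanhFitResult:
    """Nonlinear least squares for (y0, y1, m, b) with multi-start.

    The delay/rate trade-off of the tanh plateau creates local minima, so
    on top of the data-driven start a few restarts jitter m and b.  The
    ``converged`` flag is False when the optimizer fails or the solution
    sits on a bound (rate or amplitude pinned at its limit).
    """
    days = np.asarray(series.days, dtype=float)
    levels = np.asarray(series.level_pct, dtype=float)
    if days.size < 5:
        raise ValueError("need at least 5 time points to fit 4 parameters")
    if np.ptp(days) <= 0:
        raise ValueError("time points must span a positive interval")

    lo = np.array([-AMPLITUDE_SLACK, 1e-6, 1e-4, -10.0])
    hi = np.array([100.0 + AMPLITUDE_SLACK, 100.0 + AMPLITUDE_SLACK, 1.0, 60.0])

    def residuals(p: np.ndarray) -> np.ndarray:
        return eval_tanh(*p, days) - levels

    x0 = np.clip(_initial_guess(days, levels), lo, hi)
    rss0 = float(np.sum(residuals(x0) ** 2))
    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(n_restarts):
        jit = x0.copy()
        jit[2] = np.clip(x0[2] * rng.lognormal(0.0, 0.7), lo[2], hi[2])
        jit[3] = np.clip(x0[3] + rng.normal(0.0, 2.0), lo[3], hi[3])
        starts.append(jit)

    best = None
    for start in starts:
        try:
            sol = optimize.least_squares(
                residuals, start, bounds=(lo, hi),
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=5000,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol

    if best is None:
        p = x0
        return TanhFitResult(*p, rss=rss0, converged=False)

    p = best.x
    rss = float(2.0 * best.cost)
    at_bound = bool(np.any(np.isclose(p[1:], lo[1:], atol=1e-8)) or np.any(np.isclose(p, hi, atol=1e-8)))
    converged = bool(best.success) and not at_bound and rss <= rss0 + 1e-9
    return TanhFitResult(y0=float(p[0]), y1=float(p[1]), m=float(p[2]), b=float(p[3]),
                         rss=rss, converged=converged)


# ----------------------------------------------------------------------
# derived quantities and run classification
# ----------------------------------------------------------------------

def derive_quantities(series: MethylationTimeSeries, fit: TanhFitResult) -> RunSummary:
    """Assemble the screen row from a converged fit and the raw series.

    ``A`` is taken as the first post-treatment observation, a convention
    needed because the drop level is defined verbally, not operationally.
    """
    if not fit.converged:
        raise ValueError("derive_quantities requires a converged fit")
    B = float(series.baseline_pct)
    if B == 0:
        raise ValueError("baseline B = 0: relative quantities undefined, run must be excluded")
    A = float(series.level_pct[0])
    L = float(series.level_pct[-1])
    return RunSummary(
        cell_line=series.cell_line,
        locus=series.locus,
        m=fit.m,
        b=fit.b,
        b_prime=fit.b_prime,
        y0=fit.y0,
        y1=fit.y1,
        B=B,
        A=A,
        rel_drop=(B - A) / B,
        L=L,
        rel_final=L / B,
        target=fit.target_level,
    )


def classify_run(
    series: MethylationTimeSeries,
    fit: TanhFitResult,
    thresholds: FitThresholds = FitThresholds(),
) -> RunStatus:
    """Decide whether a run enters the analysis or why it is excluded."""
    B = float(series.baseline_pct)
    if B < thresholds.base_pct:
        return RunStatus("base_too_low", f"baseline {B:.2f}% < {thresholds.base_pct}%")
    A = float(series.level_pct[0])
    if B > 0 and (B - A) / B < thresholds.drop_frac:
        return RunStatus("insufficient_drop",
                         f"relative drop {(B - A) / B:.3f} < {thresholds.drop_frac}")
    trend = stats.linregress(series.days, series.level_pct).slope
    if trend < 0:
        return RunStatus("no_reclimb", f"declining trend ({trend:.3f} %/day)")
    if fit.converged:
        climb = float(eval_tanh(fit.y0, fit.y1, fit.m, fit.b, series.days[-1])
                      - eval_tanh(fit.y0, fit.y1, fit.m, fit.b, series.days[0]))
        if climb < thresholds.climb_pct:
            return RunStatus("no_reclimb",
                             f"fitted net climb {climb:.2f}% < {thresholds.climb_pct}%")
    else:
        return RunStatus("erratic", "fit did not converge")
    return RunStatus("successful")


def analyze_panel(
    panel,
    thresholds: FitThresholds = FitThresholds(),
    seed: int = 0,
) -> list[tuple[MethylationTimeSeries, TanhFitResult, RunStatus, RunSummary | None]]:
    """Fit and classify every run; summaries are built for successful runs."""
    out = []
    for i, series in enumerate(panel):
        fit = fit_tanh(series, seed=seed + i)
        status = classify_run(series, fit, thresholds)
        summary = derive_quantities(series, fit) if status.successful and fit.converged else None
        out.append((series, fit, status, summary))
    return out
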