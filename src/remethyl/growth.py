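"""Division and death-rate estimation from live/dead cell counts.

Two-step procedure: first the exponential x(t) = A0 * exp(g t) is fitted
to the live counts by ordinary least squares on the natural scale (a
log-linear fit only provides the starting point), giving the net growth
rate g.  Then, with (A0, g) fixed, the death rate d is estimated from
the per-interval dead counts, whose model prediction is the closed form

    y(t_i) = (d * A0 / g) * (exp(g t_i) - exp(g t_{i-1}))

(the limit d * A0 * (t_i - t_{i-1}) as g -> 0), reflecting that dead
cells are removed after each count.  The model is linear in d, so the
least-squares estimate is the exact ratio sum(y_obs * phi) / sum(phi^2)
with phi the bracketed factor.  The division rate is b = g + d.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .correlations import CorrelationResult, _pair_result
from .synthetic import CellCountSeries

__all__ = [
    "KineticRates",
    "fit_growth_rate",
    "estimate_death_rate",
    "estimate_rates",
    "dead_count_basis",
    "rates_to_frame",
    "rates_vs_methylation",
]

_G_LINEAR_LIMIT = 1e-8  # below this |g| the dead-count bracket uses its limit


@dataclass(frozen=True)
class KineticRates:
    """Estimated growth kinetics of one (cell line, condition)."""

    cell_line: str
    condition: str
    A0: float   # fitted initial live count
    g: float    # net growth rate, per day
    d: float    # death rate, per day

    @property
    def div(self) -> float:
        """Division rate b = g + d, per day."""
        return self.g + self.d


def fit_growth_rate(series: CellCountSeries) -> tuple[float, float]:
    """Least-squares (A0, g) for A0 * exp(g t) against the live counts.

    The fit is on the natural scale; a log-linear regression seeds it.
    """
    t = series.days
    live = series.live
    if t.size < 3:
        raise ValueError("need at least 3 live counts")
    if np.any(live <= 0):
        raise ValueError("live counts must be positive")
    if np.ptp(t) <= 0:
        raise ValueError("degenerate time grid")

    logy = np.log(live)
    g0, loga0 = np.polyfit(t, logy, 1)

    def residuals(p):
        return p[0] * np.exp(p[1] * t) - live

    sol = optimize.least_squares(residuals, [math.exp(loga0), g0],
                                 xtol=1e-15, ftol=1e-15, gtol=1e-15)
    if not sol.success:
        raise RuntimeError(f"growth fit failed: {sol.message}")
    return float(sol.x[0]), float(sol.x[1])


def dead_count_basis(days: np.ndarray, A0: float, g: float) -> np.ndarray:
    """phi_i = (A0/g)(exp(g t_i) - exp(g t_{i-1})), one per interval."""
    t = np.asarray(days, dtype=float)
    if abs(g) < _G_LINEAR_LIMIT:
        return A0 * np.diff(t)
    return (A0 / g) * np.diff(np.exp(g * t))


def estimate_death_rate(series: CellCountSeries, A0: float, g: float) -> float:
    """Exact linear least-squares d from the interval dead counts."""
    phi = dead_count_basis(series.days, A0, g)
    denom = float(np.sum(phi * phi))
    if denom == 0:
        raise ValueError("all interval factors are zero; no usable intervals")
    y_obs = series.dead_interval[1:]
    d = float(np.sum(y_obs * phi) / denom)
    if d < 0:
        warnings.warn(f"negative death-rate estimate {d:.3g} truncated to 0 "
                      "(model misfit)", stacklevel=2)
        d = 0.0
    return d


def estimate_rates(series: CellCountSeries) -> KineticRates:
    A0, g = fit_growth_rate(series)
    d = estimate_death_rate(series, A0, g)
    return KineticRates(series.cell_line, series.condition, A0, g, d)


def rates_to_frame(rates) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_line": [r.cell_line for r in rates],
            "condition": [r.condition for r in rates],
            "A0": [r.A0 for r in rates],
            "g": [r.g for r in rates],
            "d": [r.d for r in rates],
            "div": [r.div for r in rates],
        }
    )


def rates_vs_methylation(
    rates: pd.DataFrame,
    baselines: pd.DataFrame,
    low_n_threshold: int = 8,
) -> pd.DataFrame:
    """Correlate division and death rates with mean baseline methylation.

    ``baselines`` maps cell_line -> mean baseline percent (column ``B``).
    One test per (rate in {div, d}) x condition.  With a handful of cell
    lines the estimates are wide; rows with n below ``low_n_threshold``
    carry ``low_n = True``.
    """
    merged = rates.merge(baselines[["cell_line", "B"]], on="cell_line", how="inner")
    rows = []
    for condition, grp in merged.groupby("condition", sort=True):
        for rate_col in ("div", "d"):
            res: CorrelationResult = _pair_result(
                rate_col, "B", grp[rate_col].to_numpy(float), grp["B"].to_numpy(float)
            )
            rows.append(
                {
                    "condition": condition,
                    "rate": rate_col,
                    "n": res.n,
                    "pearson_r": res.pearson_r,
                    "spearman_rho": res.spearman_rho,
                    "p_pearson": res.p_pearson,
                    "p_spearman": res.p_spearman,
                    "low_n": res.n < low_n_threshold,
                }
            )
    return pd.DataFrame(rows)
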