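"""Seeded synthetic data with the statistical structure of a 5-AZA
remethylation study.

The generator emulates a panel of colorectal-cancer cell lines (CIMP and
non-CIMP) assayed by pyrosequencing at several loci after a demethylating
5-AZA pulse: a high pre-treatment baseline ``B`` for CIMP lines, a deep
post-treatment drop, and a delayed-tanh recovery

    f(t) = y0 + y1 * tanh(m * (t - b_prime))

with a cell-line-dependent rate ``m`` (per day) and onset delay ``b_prime``
(days).  A negative correlation between the recovery rate and the baseline
level is planted across the panel so that downstream correlation screens
have a known signal to find.

True generating parameters are retained on every series for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PanelConfig",
    "TrueParams",
    "MethylationTimeSeries",
    "CellCountSeries",
    "generate_methylation_panel",
    "generate_cell_counts",
    "panel_to_frame",
    "true_params_frame",
    "baselines_frame",
    "write_panel_csv",
    "panel_from_frames",
    "read_panel_csv",
    "DEFAULT_SAMPLE_DAYS",
]

#: ~10 sampling days over a 50-day observation window, denser early on
#: when the post-treatment drop and the onset of re-methylation happen.
DEFAULT_SAMPLE_DAYS: tuple[float, ...] = (0.0, 3.0, 7.0, 10.0, 14.0, 21.0, 28.0, 35.0, 42.0, 50.0)


@dataclass(frozen=True)
class PanelConfig:
    """Design of a synthetic methylation panel.

    Defaults mirror the study design this package targets: 4 cell lines
    (2 CIMP + 2 non-CIMP) x 7 loci = 28 runs, sampled ~10 times over
    50 days, with 2 percentage points of measurement noise.
    """

    n_cell_lines: int = 4
    n_loci: int = 7
    cimp_flags: tuple[bool, ...] = (False, False, True, True)
    sample_days: tuple[float, ...] = DEFAULT_SAMPLE_DAYS
    noise_sd: float = 2.0
    planted_rate_base_correlation: float = -0.6
    seed: int = 0

    # population used to draw per-run true parameters -------------------
    baseline_mean_cimp: float = 60.0
    baseline_mean_noncimp: float = 25.0
    baseline_sd: float = 8.0
    log_rate_mean: float = math.log(0.063)  # geometric center of 0.01-0.40 /day
    log_rate_sd: float = 0.7                # spread covering that rate range
    delay_range_cimp: tuple[float, float] = (0.0, 2.0)
    delay_range_noncimp: tuple[float, float] = (8.0, 20.0)
    drop_fraction_range: tuple[float, float] = (0.10, 0.35)
    recovery_fraction_range: tuple[float, float] = (0.80, 1.00)

    def __post_init__(self) -> None:
        if self.n_cell_lines < 1 or self.n_loci < 1:
            raise ValueError("panel needs at least one cell line and one locus")
        if len(self.cimp_flags) != self.n_cell_lines:
            raise ValueError("cimp_flags must have one entry per cell line")
        days = np.asarray(self.sample_days, dtype=float)
        if days.size < 2 or np.any(np.diff(days) <= 0):
            raise ValueError("sample_days must be strictly increasing")
        if days[0] < 0:
            raise ValueError("sample_days must start at day >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not -1.0 <= self.planted_rate_base_correlation <= 1.0:
            raise ValueError("planted_rate_base_correlation must lie in [-1, 1]")

    @property
    def cell_line_names(self) -> list[str]:
        return [f"CL{i + 1}" for i in range(self.n_cell_lines)]

    @property
    def locus_names(self) -> list[str]:
        return [f"locus{j + 1}" for j in range(self.n_loci)]


@dataclass(frozen=True)
class TrueParams:
    """Generating parameters of one run, kept for recovery tests."""

    baseline_pct: float  # B
    m: float             # per-day recovery rate
    b_prime: float       # onset delay, days
    b: float             # dimensionless onset, m * b_prime
    y0: float
    y1: float

    @property
    def initial_level(self) -> float:
        return self.y0 - self.y1 * math.tanh(self.b)

    @property
    def target_level(self) -> float:
        return self.y0 + self.y1


@dataclass(frozen=True)
class MethylationTimeSeries:
    """Percent methylation of one (cell line, locus) over time."""

    cell_line: str
    locus: str
    days: np.ndarray
    level_pct: np.ndarray
    baseline_pct: float
    cimp: bool
    true_params: TrueParams | None = None

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        levels = np.asarray(self.level_pct, dtype=float)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "level_pct", levels)
        if days.shape != levels.shape:
            raise ValueError("days and level_pct must have equal length")
        if np.any((levels < 0) | (levels > 100)):
            raise ValueError("level_pct must lie in [0, 100]")
        if not 0 <= self.baseline_pct <= 100:
            raise ValueError("baseline_pct must lie in [0, 100]")


@dataclass(frozen=True)
class CellCountSeries:
    """Live counts and per-interval dead counts for one culture.

    ``dead_interval[i]`` is the number of dead cells accumulated between
    ``days[i-1]`` and ``days[i]``; dead cells are removed at each count,
    so the tally restarts from zero after every sampling day.
    """

    cell_line: str
    condition: str
    days: np.ndarray
    live: np.ndarray
    dead_interval: np.ndarray

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        live = np.asarray(self.live, dtype=float)
        dead = np.asarray(self.dead_interval, dtype=float)
        for name, arr in (("days", days), ("live", live), ("dead_interval", dead)):
            object.__setattr__(self, name, arr)
        if not (days.shape == live.shape == dead.shape):
            raise ValueError("days, live and dead_interval must have equal length")
        if np.any(np.diff(days) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(live < 0) or np.any(dead < 0):
            raise ValueError("counts must be non-negative")


# ----------------------------------------------------------------------
# methylation panel
# ----------------------------------------------------------------------

def _tanh_curve(t: np.ndarray, y0: float, y1: float, m: float, b_prime: float) -> np.ndarray:
    return y0 + y1 * np.tanh(m * (t - b_prime))


def _mixture_baseline_moments(config: PanelConfig) -> tuple[float, float]:
    """Mean and sd of B over the whole panel (mixture of the two groups)."""
    flags = np.asarray(config.cimp_flags, dtype=bool)
    means = np.where(flags, config.baseline_mean_cimp, config.baseline_mean_noncimp)
    mu = float(means.mean())
    var = config.baseline_sd**2 + float(((means - mu) ** 2).mean())
    return mu, math.sqrt(var)


def generate_methylation_panel(config: PanelConfig) -> list[MethylationTimeSeries]:
    """Draw a seeded panel of remethylation time-series.

    Per run, the baseline ``B`` is drawn around the group mean (CIMP high,
    non-CIMP low) and ``log m`` is drawn conditionally on the standardized
    baseline so that corr(log m, B) over the panel equals the planted
    coefficient exactly in population.  Because CIMP lines sit at high B,
    a negative planted coefficient automatically gives them the smaller
    recovery rates.  Onset delays are ~0 for CIMP lines and positive for
    non-CIMP lines.  Observations are the delayed-tanh curve plus i.i.d.
    Gaussian noise, clipped to [0, 100].
    """
    rng = np.random.default_rng(config.seed)
    days = np.asarray(config.sample_days, dtype=float)
    mu_pop, sd_pop = _mixture_baseline_moments(config)
    # The association is planted between log m and B on the Gaussian scale,
    # but exponentiation attenuates a correlation by sigma/sqrt(e^sigma^2-1);
    # pre-compensate so the requested coefficient holds for (m, B) itself.
    rho = config.planted_rate_base_correlation
    sig = config.log_rate_sd
    if sig > 0 and rho != 0:
        rho = float(np.clip(rho * math.sqrt(math.expm1(sig * sig)) / sig, -1.0, 1.0))

    panel: list[MethylationTimeSeries] = []
    for line, cimp in zip(config.cell_line_names, config.cimp_flags):
        mu_b = config.baseline_mean_cimp if cimp else config.baseline_mean_noncimp
        for locus in config.locus_names:
            baseline = float(np.clip(rng.normal(mu_b, config.baseline_sd), 1.0, 99.0))
            z_b = (baseline - mu_pop) / sd_pop
            z = rho * z_b + math.sqrt(1.0 - rho**2) * rng.standard_normal()
            m = math.exp(config.log_rate_mean + config.log_rate_sd * z)
            lo, hi = config.delay_range_cimp if cimp else config.delay_range_noncimp
            b_prime = float(rng.uniform(lo, hi))
            b = m * b_prime

            drop = float(rng.uniform(*config.drop_fraction_range))
            recov = float(rng.uniform(*config.recovery_fraction_range))
            post_drop_level = drop * baseline          # level right after treatment
            target_level = recov * baseline
            # solve y0, y1 so that f(0) = post_drop_level and y0 + y1 = target
            y1 = (target_level - post_drop_level) / (1.0 + math.tanh(b))
            y0 = target_level - y1

            clean = _tanh_curve(days, y0, y1, m, b_prime)
            noisy = clean + rng.normal(0.0, config.noise_sd, size=days.size) if config.noise_sd > 0 else clean
            observed = np.clip(noisy, 0.0, 100.0)

            panel.append(
                MethylationTimeSeries(
                    cell_line=line,
                    locus=locus,
                    days=days.copy(),
                    level_pct=observed,
                    baseline_pct=baseline,
                    cimp=bool(cimp),
                    true_params=TrueParams(baseline, m, b_prime, b, y0, y1),
                )
            )
    return panel


# ----------------------------------------------------------------------
# cell counts
# ----------------------------------------------------------------------

def generate_cell_counts(
    g: float,
    d: float,
    A0: float,
    days: Sequence[float],
    noise_sd_rel: float = 0.0,
    seed: int = 0,
    cell_line: str = "CL1",
    condition: str = "control",
) -> CellCountSeries:
    """Simulate live counts ``A0 * exp(g t)`` and interval dead counts.

    The expected dead count over (t_{i-1}, t_i] is
    ``(d * A0 / g) * (exp(g t_i) - exp(g t_{i-1}))`` (the limit
    ``d * A0 * dt`` as g -> 0), reflecting that dead cells are removed
    after each count.  Multiplicative lognormal noise of the given
    relative sd is applied independently to every count.
    """
    if A0 <= 0:
        raise ValueError("A0 must be positive")
    if d < 0:
        raise ValueError("death rate must be non-negative")
    if noise_sd_rel < 0:
        raise ValueError("noise_sd_rel must be non-negative")
    t = np.asarray(days, dtype=float)
    if t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("days must be strictly increasing with >= 2 points")

    rng = np.random.default_rng(seed)
    live = A0 * np.exp(g * t)
    dead = np.zeros_like(t)
    if abs(g) < 1e-8:
        dead[1:] = d * A0 * np.diff(t)
    else:
        dead[1:] = (d * A0 / g) * np.diff(np.exp(g * t))

    if noise_sd_rel > 0:
        sigma = math.sqrt(math.log(1.0 + noise_sd_rel**2))
        live = live * rng.lognormal(-0.5 * sigma**2, sigma, size=t.size)
        noise = rng.lognormal(-0.5 * sigma**2, sigma, size=t.size)
        dead = dead * noise
        dead[0] = 0.0
    return CellCountSeries(cell_line, condition, t, live, dead)


# ----------------------------------------------------------------------
# tabular I/O (CSV, UTF-8, '.' decimal, header row)
# ----------------------------------------------------------------------

def panel_to_frame(panel: Sequence[MethylationTimeSeries]) -> pd.DataFrame:
    """Long-format observations: one row per (cell line, locus, day)."""
    rows = [
        {"cell_line": s.cell_line, "locus": s.locus, "day": day, "methylation_pct": lvl}
        for s in panel
        for day, lvl in zip(s.days, s.level_pct)
    ]
    return pd.DataFrame(rows, columns=["cell_line", "locus", "day", "methylation_pct"])


def baselines_frame(panel: Sequence[MethylationTimeSeries]) -> pd.DataFrame:
    rows = [
        {"cell_line": s.cell_line, "locus": s.locus, "baseline_pct": s.baseline_pct, "cimp": s.cimp}
        for s in panel
    ]
    return pd.DataFrame(rows, columns=["cell_line", "locus", "baseline_pct", "cimp"])


def true_params_frame(panel: Sequence[MethylationTimeSeries]) -> pd.DataFrame:
    rows = []
    for s in panel:
        p = s.true_params
        if p is None:
            continue
        rows.append(
            {
                "cell_line": s.cell_line,
                "locus": s.locus,
                "cimp": s.cimp,
                "B": p.baseline_pct,
                "m": p.m,
                "b_prime": p.b_prime,
                "b": p.b,
                "y0": p.y0,
                "y1": p.y1,
            }
        )
    return pd.DataFrame(rows, columns=["cell_line", "locus", "cimp", "B", "m", "b_prime", "b", "y0", "y1"])


def write_panel_csv(panel: Sequence[MethylationTimeSeries], observations_path, baselines_path=None,
                    true_params_path=None) -> None:
    panel_to_frame(panel).to_csv(observations_path, index=False)
    if baselines_path is not None:
        baselines_frame(panel).to_csv(baselines_path, index=False)
    if true_params_path is not None:
        true_params_frame(panel).to_csv(true_params_path, index=False)


def panel_from_frames(observations: pd.DataFrame, baselines: pd.DataFrame) -> list[MethylationTimeSeries]:
    """Assemble series objects from long-format observations + baselines."""
    base = baselines.set_index(["cell_line", "locus"])
    panel = []
    for (line, locus), grp in observations.groupby(["cell_line", "locus"], sort=False):
        grp = grp.sort_values("day")
        info = base.loc[(line, locus)]
        panel.append(
            MethylationTimeSeries(
                cell_line=str(line),
                locus=str(locus),
                days=grp["day"].to_numpy(float),
                level_pct=grp["methylation_pct"].to_numpy(float),
                baseline_pct=float(info["baseline_pct"]),
                cimp=bool(info.get("cimp", False)),
            )
        )
    return panel


def read_panel_csv(observations_path, baselines_path) -> list[MethylationTimeSeries]:
    return panel_from_frames(pd.read_csv(observations_path), pd.read_csv(baselines_path))
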