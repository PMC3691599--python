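"""Feedback-regulated de novo methylation model.

A single locus with methylation state ``x`` (capacity ``k1``) and a pool
of feedback-sensor loci with aggregate methylation ``w`` (capacity
``k2``) are both methylated by active MTase ``y_n``, the last element of
a production cascade ``y_1 .. y_n``:

    dx/dt  = lam * y_n * (1 - x/k1) - a1 * x        (a1 only during treatment)
    dw/dt  = gam * y_n * (1 - w/k2) - a2 * w        (a2 only during treatment)
    dy1/dt = P(w) - q * y1
    dyi/dt = q * (y_{i-1} - y_i)        1 < i < n
    dyn/dt = q * y_{n-1} - delta * yn

Production ``P(w)`` distinguishes the two cell phenotypes:

* non-CIMP — negative feedback: P = eta * (c - w) while w < c, else 0.
  Sensors rise to the set-point c and shut de novo methylation down.
* CIMP — the feedback is corrupted: P = eta, a constant low level.

Demethylating (5-AZA) treatment is modelled by the decay terms a1, a2
being switched on during configured treatment windows.  The MTase decay
``delta`` is orders of magnitude faster than every other rate, which
makes the system stiff and y_n a quasi-steady readout P/delta of the
cascade input.

For the untreated non-CIMP model started fully unmethylated, eliminating
time between the x and w equations (both driven by the same y_n) gives a
closed-form steady locus methylation

    x*/k1 = 1 - (1 - c/k2) ** (lam * k2 / (gam * k1))

which serves as an independent oracle for the integrator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "OdeParameters",
    "TreatmentProtocol",
    "Trajectory",
    "RecoveryMetrics",
    "REFERENCE_PARAMS",
    "production_rate",
    "simulate",
    "steady_state_fraction",
    "recovery_metrics",
    "scenario",
]


@dataclass(frozen=True)
class OdeParameters:
    """Rate constants of the feedback model (time unit: days).

    Defaults are the reference parameter set used throughout:
    lam=0.4, k1=0.04, a1=4, gam=80, k2=100, a2=0.4, eta=2, c=10, q=0.8,
    delta=4000.  ``delta`` is the MTase decay rate (the model's fast
    time-scale); ``n_stages`` is the cascade length, which sets the
    re-activation delay but leaves all steady states unchanged.
    """

    lam: float = 0.4      # locus methylation rate
    k1: float = 0.04      # locus methylation capacity
    a1: float = 4.0       # locus demethylation rate under treatment
    gam: float = 80.0     # sensor methylation rate
    k2: float = 100.0     # sensor capacity
    a2: float = 0.4       # sensor demethylation rate under treatment
    eta: float = 2.0      # production rate constant
    c: float = 10.0       # feedback threshold on sensor methylation
    q: float = 0.8        # cascade transfer rate
    delta: float = 4000.0 # MTase decay rate
    n_stages: int = 3     # cascade length n (y1 .. yn)
    mode: str = "non_cimp"  # "non_cimp" (feedback) or "cimp" (constant)

    def __post_init__(self) -> None:
        for name in ("lam", "a1", "gam", "a2", "eta", "q", "delta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("capacities k1, k2 must be positive")
        if not 0 <= self.c <= self.k2:
            raise ValueError("threshold c must lie in [0, k2]")
        if self.n_stages < 1:
            raise ValueError("cascade needs at least one stage")
        if self.mode not in ("non_cimp", "cimp"):
            raise ValueError("mode must be 'non_cimp' or 'cimp'")


#: the reference parameter set (non-CIMP feedback mode by default)
REFERENCE_PARAMS = OdeParameters()


@dataclass(frozen=True)
class TreatmentProtocol:
    """Time windows (start, end) in days during which a1, a2 act."""

    windows: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        prev_end = -math.inf
        for start, end in self.windows:
            if end <= start:
                raise ValueError("each window must satisfy end > start")
            if start < prev_end:
                raise ValueError("windows must be ordered and non-overlapping")
            prev_end = end

    def active(self, t: float) -> bool:
        return any(start <= t < end for start, end in self.windows)

    @property
    def last_end(self) -> float | None:
        return self.windows[-1][1] if self.windows else None


@dataclass(frozen=True)
class Trajectory:
    times: np.ndarray
    x: np.ndarray
    w: np.ndarray
    y: np.ndarray  # shape (n_stages, len(times))
    params: OdeParameters

    @property
    def x_pct(self) -> np.ndarray:
        return 100.0 * self.x / self.params.k1

    @property
    def w_pct(self) -> np.ndarray:
        return 100.0 * self.w / self.params.k2

    @property
    def yn(self) -> np.ndarray:
        return self.y[-1]

    def to_frame(self) -> pd.DataFrame:
        data = {"time": self.times, "x": self.x, "w": self.w}
        for i in range(self.y.shape[0]):
            data[f"y{i + 1}"] = self.y[i]
        data["x_pct"] = self.x_pct
        data["w_pct"] = self.w_pct
        return pd.DataFrame(data)


def production_rate(w: float, params: OdeParameters) -> float:
    """Cascade input P(w): eta*(c - w) gated at the set-point for
    non-CIMP cells, the constant eta for CIMP cells."""
    if params.mode == "cimp":
        return params.eta
    return params.eta * max(params.c - w, 0.0)


def _rhs(t: float, state: np.ndarray, p: OdeParameters, treating: bool) -> np.ndarray:
    x, w = state[0], state[1]
    y = state[2:]
    yn = y[-1]
    ds = np.empty_like(state)
    ds[0] = p.lam * yn * (1.0 - x / p.k1) - (p.a1 * x if treating else 0.0)
    ds[1] = p.gam * yn * (1.0 - w / p.k2) - (p.a2 * w if treating else 0.0)
    prod = production_rate(w, p)
    if p.n_stages == 1:
        ds[2] = prod - p.delta * y[0]
        return ds
    ds[2] = prod - p.q * y[0]
    for i in range(1, p.n_stages - 1):
        ds[2 + i] = p.q * (y[i - 1] - y[i])
    ds[-1] = p.q * y[-2] - p.delta * y[-1]
    return ds


def simulate(
    params: OdeParameters,
    protocol: TreatmentProtocol = TreatmentProtocol(),
    initial_state: np.ndarray | None = None,
    t_span: tuple[float, float] = (0.0, 600.0),
    output_grid: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> Trajectory:
    """Integrate the stiff system piecewise across treatment windows.

    The treatment terms switch discontinuously at window edges, so each
    window boundary starts a fresh solver segment; inside a segment the
    feedback gate max(c - w, 0) is continuous and an event at w = c keeps
    the step size honest around the set-point crossing.  Default state is
    fully unmethylated (all zeros).
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    if t1 <= t0:
        raise ValueError("t_span must be increasing")
    if output_grid is None:
        output_grid = np.linspace(t0, t1, 1201)
    output_grid = np.asarray(output_grid, dtype=float)
    if output_grid[0] < t0 or output_grid[-1] > t1:
        raise ValueError("output grid must lie within t_span")

    state = np.zeros(2 + params.n_stages) if initial_state is None else np.asarray(initial_state, dtype=float).copy()
    if state.size != 2 + params.n_stages:
        raise ValueError("initial state must have length 2 + n_stages")

    edges = sorted({t0, t1} | {e for win in protocol.windows for e in win if t0 < e < t1})

    def crossing(t, s, p=params, treating=None):
        return s[1] - params.c

    times_out: list[np.ndarray] = []
    states_out: list[np.ndarray] = []
    for seg_start, seg_end in zip(edges[:-1], edges[1:]):
        treating = protocol.active(0.5 * (seg_start + seg_end))
        mask = (output_grid >= seg_start) & (output_grid <= seg_end)
        t_eval = np.unique(np.concatenate([[seg_start], output_grid[mask], [seg_end]]))
        sol = solve_ivp(
            _rhs, (seg_start, seg_end), state,
            method="LSODA", t_eval=t_eval, args=(params, treating),
            events=crossing, rtol=rtol, atol=atol, max_step=seg_end - seg_start,
        )
        if not sol.success:
            raise RuntimeError(f"ODE solver failed on [{seg_start}, {seg_end}]: {sol.message}")
        keep = np.isin(sol.t, output_grid[mask])
        times_out.append(sol.t[keep])
        states_out.append(sol.y[:, keep])
        state = sol.y[:, -1]

    t = np.concatenate(times_out)
    s = np.hstack(states_out)
    t, idx = np.unique(t, return_index=True)
    s = s[:, idx]
    return Trajectory(times=t, x=s[0], w=s[1], y=s[2:], params=params)


def steady_state_fraction(params: OdeParameters) -> float:
    """Closed-form untreated steady locus methylation, as a fraction of k1.

    Valid for the feedback (non-CIMP) mode started fully unmethylated:
    dividing the x and w equations eliminates y_n and time, and
    integrating from (0, 0) to (x*, c) yields
    1 - (1 - c/k2) ** (lam*k2 / (gam*k1)).
    """
    if params.mode != "non_cimp":
        raise ValueError("closed form applies to the feedback (non_cimp) mode")
    if params.c > params.k2:
        raise ValueError("threshold c must not exceed sensor capacity k2")
    if params.c == params.k2:
        return 1.0
    exponent = params.lam * params.k2 / (params.gam * params.k1)
    return 1.0 - (1.0 - params.c / params.k2) ** exponent


@dataclass(frozen=True)
class RecoveryMetrics:
    """Post-treatment recovery summary of a trajectory."""

    onset_delay_days: float
    max_slope_pct_per_day: float
    final_level_pct: float
    defined: bool = True
    reason: str = ""


def recovery_metrics(traj: Trajectory, protocol: TreatmentProtocol,
                     min_gain_pct: float = 0.5) -> RecoveryMetrics:
    """Quantify the post-treatment re-methylation: lag, speed, final level.

    The onset delay is the lag time of the recovery curve: the maximum-
    slope tangent is extrapolated back to the post-treatment floor, and
    the delay is the time from treatment end to that intercept (clipped
    at zero).  A curve that climbs fastest immediately has zero lag; a
    sigmoid whose climb gains momentum only later has a positive lag.
    The maximum slope is the largest finite-difference slope of x_pct
    after treatment, and the final level is x_pct at the end of the span.
    """
    t_end = protocol.last_end
    if t_end is None:
        return RecoveryMetrics(math.nan, math.nan, math.nan, False, "no treatment window")
    mask = traj.times >= t_end
    if mask.sum() < 3:
        return RecoveryMetrics(math.nan, math.nan, math.nan, False,
                               "trajectory does not extend beyond treatment")
    t = traj.times[mask]
    x = traj.x_pct[mask]
    floor = float(x.min())
    final = float(x[-1])
    if final - floor < min_gain_pct:
        return RecoveryMetrics(math.nan, math.nan, final, False, "no post-treatment gain")
    slopes = np.gradient(x, t)
    i_max = int(np.argmax(slopes))
    max_slope = float(slopes[i_max])
    lag = (t[i_max] - t_end) - (x[i_max] - floor) / max_slope
    return RecoveryMetrics(max(float(lag), 0.0), max_slope, final)


# ----------------------------------------------------------------------
# reference scenarios
# ----------------------------------------------------------------------

def scenario(name: str, n_stages: int = 3,
             pre_days: float = 300.0, post_days: float = 300.0,
             treatment_days: float = 3.0, points_per_day: float = 4.0):
    """Reconstructed reference scenarios for the two phenotypes.

    ``feedback``: feedback (non-CIMP) mode; ``constant``: constant-production
    (CIMP) mode; both with the reference parameter set.  The timeline —
    equilibration from a fully unmethylated start, one 72-hour treatment
    window, then recovery — is a reconstruction: only the treatment
    duration is prescribed, the phase lengths are package choices long
    enough for every state to settle.

    Returns (params, protocol, t_span, output_grid).
    """
    if name == "feedback":
        params = replace(REFERENCE_PARAMS, mode="non_cimp", n_stages=n_stages)
    elif name == "constant":
        params = replace(REFERENCE_PARAMS, mode="cimp", n_stages=n_stages)
    else:
        raise ValueError(f"unknown scenario {name!r} (expected 'feedback' or 'constant')")
    protocol = TreatmentProtocol(windows=((pre_days, pre_days + treatment_days),))
    t_end = pre_days + treatment_days + post_days
    grid = np.linspace(0.0, t_end, int(round(t_end * points_per_day)) + 1)
    return params, protocol, (0.0, t_end), grid
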