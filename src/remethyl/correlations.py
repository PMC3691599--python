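"""Systematic pairwise correlation screen over remethylation quantities.

The screen takes one row per successful run — fitted quantities
(m, b, b', y0, y1, y0+y1) and directly-read ones (B, A, (B-A)/B, L, L/B) —
and computes, for every unordered pair, the Pearson correlation with a
two-sided p-value from the t transform r*sqrt((n-2)/(1-r^2)), the
Spearman rank correlation (ties averaged) with a p-value from the same
t approximation, and the ordinary least-squares slope/intercept.  Raw
p-values are reported (no multiplicity correction, matching the screen
this reproduces); a Benjamini-Hochberg column is emitted alongside as a
clearly-labelled extension.

The headline contrasts of the analysis are rate-vs-baseline (m, B),
onset-vs-baseline (b, B), rate-vs-onset (m, b) and delay-vs-baseline
(b', B).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "DEFAULT_QUANTITIES",
    "HEADLINE_PAIRS",
    "pairwise_correlations",
    "correlations_frame",
    "p_value_grid",
    "aggregate_by_cell_line",
    "headline_tests",
    "spearman_exact_p",
]

DEFAULT_QUANTITIES: tuple[str, ...] = (
    "m", "b", "b_prime", "y0", "y1", "target", "B", "A", "rel_drop", "L", "rel_final",
)

HEADLINE_PAIRS: tuple[tuple[str, str], ...] = (
    ("m", "B"), ("b", "B"), ("m", "b"), ("b_prime", "B"),
)

MIN_PAIRS = 4


@dataclass(frozen=True)
class CorrelationResult:
    pair: tuple[str, str]
    n: int
    pearson_r: float
    spearman_rho: float
    slope: float
    intercept: float
    p_pearson: float
    p_spearman: float

    @property
    def sign(self) -> str:
        if math.isnan(self.pearson_r) or self.pearson_r == 0:
            return ""
        return "+" if self.pearson_r > 0 else "-"

    @property
    def defined(self) -> bool:
        return not math.isnan(self.pearson_r)


def _t_pvalue(r: float, n: int) -> float:
    """Two-sided p from the Student-t transform of a correlation."""
    if n <= 2:
        return float("nan")
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _pair_result(name_x: str, name_y: str, x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = int(x.size)
    if name_x == name_y:
        return CorrelationResult((name_x, name_y), n, 1.0, 1.0, 1.0, 0.0, 0.0, 0.0)
    nan = float("nan")
    if n < MIN_PAIRS or np.ptp(x) == 0 or np.ptp(y) == 0:
        # constant column or too few complete pairs: flagged missing, not zero
        return CorrelationResult((name_x, name_y), n, nan, nan, nan, nan, nan, nan)
    r = float(stats.pearsonr(x, y).statistic)
    rho = float(stats.spearmanr(x, y).statistic)
    ols = stats.linregress(x, y)
    return CorrelationResult(
        (name_x, name_y), n, r, rho,
        float(ols.slope), float(ols.intercept),
        _t_pvalue(r, n), _t_pvalue(rho, n),
    )


def pairwise_correlations(
    table: pd.DataFrame,
    quantities=DEFAULT_QUANTITIES,
    include_diagonal: bool = True,
) -> list[CorrelationResult]:
    """Correlate every unordered pair of quantities present in ``table``."""
    quantities = [q for q in quantities if q in table.columns]
    results = []
    for i, qx in enumerate(quantities):
        start = i if include_diagonal else i + 1
        for qy in quantities[start:]:
            results.append(
                _pair_result(qx, qy, table[qx].to_numpy(float), table[qy].to_numpy(float))
            )
    return results


def correlations_frame(results, bh_alpha: float = 0.05) -> pd.DataFrame:
    """Long-format table of the screen, with a Benjamini-Hochberg column
    (``p_pearson_bh``, an extension over the raw-p presentation)."""
    df = pd.DataFrame(
        {
            "quantity_x": [r.pair[0] for r in results],
            "quantity_y": [r.pair[1] for r in results],
            "n": [r.n for r in results],
            "pearson_r": [r.pearson_r for r in results],
            "spearman_rho": [r.spearman_rho for r in results],
            "slope": [r.slope for r in results],
            "intercept": [r.intercept for r in results],
            "p_pearson": [r.p_pearson for r in results],
            "p_spearman": [r.p_spearman for r in results],
            "sign": [r.sign for r in results],
        }
    )
    off_diag = (df["quantity_x"] != df["quantity_y"]) & df["p_pearson"].notna()
    bh = pd.Series(np.nan, index=df.index)
    if off_diag.any():
        bh.loc[off_diag] = multipletests(df.loc[off_diag, "p_pearson"], alpha=bh_alpha,
                                         method="fdr_bh")[1]
    df["p_pearson_bh"] = bh
    return df


def p_value_grid(
    results,
    quantities=DEFAULT_QUANTITIES,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Square symmetric grid of Pearson p-values with sign annotations.

    Diagonal cells are exactly 0; below-``alpha`` cells carry the sign of
    the correlation in the companion annotation grid.
    """
    quantities = list(quantities)
    p = pd.DataFrame(np.nan, index=quantities, columns=quantities)
    signs = pd.DataFrame("", index=quantities, columns=quantities)
    np.fill_diagonal(p.values, 0.0)
    for res in results:
        qx, qy = res.pair
        if qx not in p.index or qy not in p.index:
            continue
        if qx == qy:
            p.loc[qx, qy] = 0.0
            continue
        p.loc[qx, qy] = p.loc[qy, qx] = res.p_pearson
        if res.defined and res.p_pearson < alpha:
            signs.loc[qx, qy] = signs.loc[qy, qx] = res.sign
    return p, signs


def plot_p_value_grid(p: pd.DataFrame, signs: pd.DataFrame, path) -> None:
    """Optional heatmap of the p-value grid (lighter = smaller p)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    with np.errstate(divide="ignore"):
        img = ax.imshow(-np.log10(p.to_numpy(float) + 1e-12), cmap="viridis")
    ax.set_xticks(range(len(p.columns)), p.columns, rotation=90)
    ax.set_yticks(range(len(p.index)), p.index)
    for i in range(len(p.index)):
        for j in range(len(p.columns)):
            if signs.iat[i, j]:
                ax.text(j, i, signs.iat[i, j], ha="center", va="center", color="white")
    fig.colorbar(img, ax=ax, label="-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def aggregate_by_cell_line(table: pd.DataFrame, quantities=DEFAULT_QUANTITIES) -> pd.DataFrame:
    """Arithmetic mean of each quantity per cell line, with run counts."""
    quantities = [q for q in quantities if q in table.columns]
    agg = table.groupby("cell_line", sort=True)[quantities].mean()
    agg["n_runs"] = table.groupby("cell_line", sort=True).size()
    if "cimp" in table.columns:
        agg["cimp"] = table.groupby("cell_line", sort=True)["cimp"].first()
    return agg.reset_index()


def headline_tests(table: pd.DataFrame) -> dict[str, CorrelationResult]:
    """The four named contrasts: (m, B), (b, B), (m, b) and (b', B)."""
    out = {}
    for qx, qy in HEADLINE_PAIRS:
        out[f"{qx}_vs_{qy}"] = _pair_result(
            qx, qy, table[qx].to_numpy(float), table[qy].to_numpy(float)
        )
    return out


def spearman_exact_p(x, y) -> float:
    """Exact permutation two-sided p-value for Spearman's rho (n <= 10).

    Enumerates all n! rank permutations; intended for small samples where
    the t approximation is coarse.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n > 10:
        raise ValueError("exact enumeration supported only for n <= 10")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    observed = abs(np.corrcoef(rx, ry)[0, 1])
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(np.corrcoef(rx, perm)[0, 1]) >= observed - 1e-12:
            count += 1
    return count / total
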