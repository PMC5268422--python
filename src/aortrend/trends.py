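"""Mann-Kendall trend testing and Monte-Carlo trend aggregation.

The Mann-Kendall test is a rank-based test for monotonic change in an
ordered series: S = sum over pairs i < j of sign(x_j - x_i), with a
normal approximation for the p-value that uses the tie-adjusted variance

    Var(S) = [n(n-1)(2n+5) - sum_t t(t-1)(2t+5)] / 18

and a continuity correction.  The reported correlation is Kendall's
tau-b (tie-corrected).  Because the test is rank-based, series with
missing years are handled by simply omitting them; spacing is ignored.

Across Monte-Carlo iterations, per-iteration tau values are aggregated
into a mean tau-bar with an empirical percentile 95% CI; a trend is
called significant when that interval excludes zero.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import math

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

INDEX_COLUMNS = ("slope", "intercept", "r_squared")


@dataclass(frozen=True)
class TrendResult:
    tau: float
    s_statistic: int
    p_value: float
    n: int


def mann_kendall(series) -> TrendResult:
    """Mann-Kendall test on an ordered numeric series (n >= 3).

    Returns tau-b, the integer S score, and the two-sided p-value from
    the continuity-corrected normal approximation with tie-adjusted
    variance.  A constant series gives tau = 0, p = 1.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    n = x.size
    if n < 3:
        raise ValueError(f"Mann-Kendall needs n >= 3, got {n}")
    if np.any(~np.isfinite(x)):
        raise ValueError("series contains non-finite values")

    diffs = np.sign(x[None, :] - x[:, None])
    s = int(np.triu(diffs, k=1).sum())

    tie_counts = [c for c in Counter(x).values() if c > 1]
    var_s = (
        n * (n - 1) * (2 * n + 5)
        - sum(t * (t - 1) * (2 * t + 5) for t in tie_counts)
    ) / 18.0

    n0 = n * (n - 1) / 2
    tie_term = sum(t * (t - 1) / 2 for t in tie_counts)
    denom = math.sqrt(n0 * (n0 - tie_term))  # time axis has no ties
    tau = s / denom if denom > 0 else 0.0

    if var_s <= 0 or s == 0:
        p = 1.0
    else:
        z = (s - np.sign(s)) / math.sqrt(var_s)
        p = 2.0 * stats.norm.sf(abs(z))
    return TrendResult(tau=float(tau), s_statistic=s, p_value=float(min(p, 1.0)), n=n)


@dataclass(frozen=True)
class TrendSummary:
    """Mean Kendall tau-bar over Monte-Carlo iterations with percentile 95% CI."""

    index: str
    measure: str
    mean_tau: float
    ci_low: float
    ci_high: float
    significant: bool
    prop_significant: float
    n_iterations: int


def aggregate_trends(
    results: list[TrendResult],
    index: str = "",
    measure: str = "",
    alpha: float = 0.05,
    ci_method: str = "percentile",
) -> TrendSummary:
    """Aggregate per-iteration Mann-Kendall results into a TrendSummary.

    ``mean_tau`` is the unweighted arithmetic mean; the CI is the empirical
    2.5th/97.5th percentile of the tau sample (``ci_method='normal'``
    substitutes mean +/- 1.96 SD).  ``prop_significant`` is the fraction of
    iterations with p < alpha; ``significant`` is True when the CI excludes
    zero.
    """
    if len(results) < 2:
        raise ValueError("need >= 2 iterations to aggregate")
    taus = np.array([r.tau for r in results])
    pvals = np.array([r.p_value for r in results])
    mean_tau = float(taus.mean())
    if ci_method == "percentile":
        lo, hi = np.percentile(taus, [2.5, 97.5])
    elif ci_method == "normal":
        half = 1.959963984540054 * float(taus.std(ddof=1))
        lo, hi = mean_tau - half, mean_tau + half
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return TrendSummary(
        index=index,
        measure=measure,
        mean_tau=mean_tau,
        ci_low=float(lo),
        ci_high=float(hi),
        significant=not (lo <= 0.0 <= hi),
        prop_significant=float((pvals < alpha).mean()),
        n_iterations=len(results),
    )


def iteration_trends(indices: pd.DataFrame) -> pd.DataFrame:
    """Per-iteration Mann-Kendall tau/p for each (measure, index) series.

    ``indices`` is the long per-iteration, per-year index table produced by
    the simulator (columns iteration, year, measure, slope, intercept,
    r_squared).  Iterations whose year series is shorter than 3 are dropped
    with a warning.
    """
    rows = []
    for (measure, iteration), grp in indices.groupby(["measure", "iteration"]):
        grp = grp.sort_values("year")
        if len(grp) < 3:
            logger.warning(
                "iteration %s (%s) has only %d usable years; dropped",
                iteration,
                measure,
                len(grp),
            )
            continue
        for index in INDEX_COLUMNS:
            r = mann_kendall(grp[index].to_numpy())
            rows.append(
                {
                    "measure": measure,
                    "iteration": iteration,
                    "index": index,
                    "tau": r.tau,
                    "s_statistic": r.s_statistic,
                    "p_value": r.p_value,
                    "n_years": r.n,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "measure",
            "iteration",
            "index",
            "tau",
            "s_statistic",
            "p_value",
            "n_years",
        ],
    )


def summarize_trends(
    indices: pd.DataFrame, alpha: float = 0.05, ci_method: str = "percentile"
) -> list[TrendSummary]:
    """TrendSummary for every (measure, index) in a per-iteration index table."""
    per_iter = iteration_trends(indices)
    out = []
    for (measure, index), grp in per_iter.groupby(["measure", "index"]):
        results = [
            TrendResult(t, int(s), p, int(n))
            for t, s, p, n in zip(
                grp["tau"], grp["s_statistic"], grp["p_value"], grp["n_years"]
            )
        ]
        out.append(
            aggregate_trends(
                results, index=index, measure=measure, alpha=alpha, ci_method=ci_method
            )
        )
    return sorted(out, key=lambda s: (s.measure, s.index))


def yearly_summary(indices: pd.DataFrame) -> pd.DataFrame:
    """Per-year mean and percentile 95% CI of each AOR index across iterations.

    Years present in fewer than 2 iterations are omitted with a warning.
    Returns a frame with columns measure, year, index, mean, ci_low, ci_high, n.
    """
    rows = []
    for (measure, year), grp in indices.groupby(["measure", "year"]):
        if len(grp) < 2:
            logger.warning(
                "year %s (%s) present in only %d iteration(s); omitted", year, measure, len(grp)
            )
            continue
        for index in INDEX_COLUMNS:
            vals = grp[index].to_numpy()
            lo, hi = np.percentile(vals, [2.5, 97.5])
            rows.append(
                {
                    "measure": measure,
                    "year": year,
                    "index": index,
                    "mean": float(vals.mean()),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "n": len(vals),
                }
            )
    return pd.DataFrame(
        rows, columns=["measure", "year", "index", "mean", "ci_low", "ci_high", "n"]
    )


def trend_summary_frame(summaries: list[TrendSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "measure": s.measure,
                "index": s.index,
                "mean_tau": s.mean_tau,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "significant": s.significant,
                "prop_significant": s.prop_significant,
                "n_iterations": s.n_iterations,
            }
            for s in summaries
        ]
    )
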