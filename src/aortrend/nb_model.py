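"""Yearly negative-binomial fitting of per-species catch distributions.

Each species-year is modelled as iid counts across tows from a negative
binomial with mean ``mu`` (individuals per tow) and size/aggregation
parameter ``k`` (dimensionless; smaller k = patchier spatial
distribution; variance = mu + mu**2 / k).  The success-probability
parameterization is p = k / (k + mu), giving the pmf

    P(x) = C(x + k - 1, x) * p**k * (1 - p)**x .

Fits use the NB maximum-likelihood property that mu-hat equals the
sample mean exactly, reducing the problem to a 1-D profile likelihood in
log k.  Underdispersed samples (variance <= mean) push k-hat to
infinity; k is capped at ``K_CAP`` and flagged ``boundary_k``, which
downstream simulation treats as effectively Poisson.

A species enters a year's fit only if the inclusion filter passes:
by default, present (count >= 1) in at least three tows of that
region-year ("tows" rule); an alternative "individuals" rule (total
catch >= 3) is available since survey write-ups are often ambiguous
about which was meant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .io_survey import CatchTable
from .trends import TrendResult, mann_kendall

logger = logging.getLogger(__name__)

#: upper cap on the fitted size parameter; at k = 1e4 the NB is
#: indistinguishable from Poisson at survey counts
K_CAP = 1e4

STATUS_OK = "ok"
STATUS_BOUNDARY = "boundary_k"
STATUS_NOT_FIT = "not_fit"


@dataclass(frozen=True)
class NBParams:
    mu: float
    k: float
    status: str
    n_tows: int = 0
    n_occupied: int = 0

    @property
    def usable(self) -> bool:
        return self.status in (STATUS_OK, STATUS_BOUNDARY)


def p_from_mu_k(mu: float, k: float) -> float:
    """Success probability p = k / (k + mu); p in (0, 1]."""
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if mu < 0:
        raise ValueError(f"mu must be non-negative, got {mu}")
    return k / (k + mu)


def nb_pmf(x, mu: float, k: float):
    """NB probability mass at count(s) ``x`` under the (mu, k) parameterization."""
    if mu <= 0 or k <= 0:
        raise ValueError(f"mu and k must be positive, got mu={mu}, k={k}")
    x = np.asarray(x)
    if np.any(x < 0) or np.any(x != np.floor(x)):
        raise ValueError("x must be non-negative integer count(s)")
    p = p_from_mu_k(mu, k)
    out = np.exp(stats.nbinom.logpmf(x, k, p))
    return float(out) if out.ndim == 0 else out


def _nb_negloglik_logk(log_k: float, counts: np.ndarray, mu: float) -> float:
    k = math.exp(log_k)
    p = k / (k + mu)
    return -float(np.sum(stats.nbinom.logpmf(counts, k, p)))


def fit_nb(counts) -> NBParams:
    """Maximum-likelihood (mu, k) for a vector of tow counts.

    mu-hat is the sample mean (exact NB MLE); k-hat maximizes the profile
    log-likelihood over log k in (log 1e-4, log K_CAP].  Returns status
    ``boundary_k`` when the optimum hits the cap (underdispersion) and
    ``not_fit`` for degenerate inputs (fewer than 3 counts, or all zero).
    """
    counts = np.asarray(counts, dtype=np.int64)
    n = counts.size
    n_occ = int(np.count_nonzero(counts))
    if n < 3 or n_occ == 0:
        return NBParams(float("nan"), float("nan"), STATUS_NOT_FIT, n, n_occ)
    mu = float(counts.mean())

    # method-of-moments start; variance <= mean has no interior optimum
    var = float(counts.var(ddof=1))
    k0 = max(mu**2 / (var - mu), 0.1) if var > mu else K_CAP

    res = optimize.minimize_scalar(
        _nb_negloglik_logk,
        bounds=(math.log(1e-4), math.log(K_CAP)),
        args=(counts, mu),
        method="bounded",
        options={"xatol": 1e-10},
    )
    k_hat = math.exp(res.x)
    # refine around the MoM start if bounded search stalled (rare flat cases)
    if var > mu and abs(math.log(k_hat / k0)) > 8:
        res2 = optimize.minimize_scalar(
            _nb_negloglik_logk,
            bracket=(math.log(k0) - 1, math.log(k0), math.log(k0) + 1),
            args=(counts, mu),
            method="brent",
        )
        if res2.fun < res.fun and math.exp(res2.x) <= K_CAP:
            k_hat = math.exp(res2.x)

    if k_hat >= K_CAP * (1 - 1e-6):
        return NBParams(mu, K_CAP, STATUS_BOUNDARY, n, n_occ)
    return NBParams(mu, k_hat, STATUS_OK, n, n_occ)


@dataclass
class ParamTable:
    """Fitted (mu, k) per (region, year, species), with fit metadata.

    Backed by a DataFrame with columns region, year, species, mu, k,
    status, n_tows, n_occupied.  Only species-years passing the inclusion
    filter are fitted; others carry status ``not_fit``.
    """

    frame: pd.DataFrame
    filter_rule: str = "tows"
    metadata: dict = field(default_factory=dict)

    COLUMNS = ("region", "year", "species", "mu", "k", "status", "n_tows", "n_occupied")

    def regions(self) -> list[str]:
        return sorted(self.frame["region"].unique())

    def years(self, region: str) -> list[int]:
        sub = self.frame[self.frame["region"] == region]
        if sub.empty:
            raise KeyError(f"no fitted parameters for region {region!r}")
        return sorted(sub["year"].unique())

    def year_params(self, region: str, year: int) -> dict[str, NBParams]:
        sub = self.frame[
            (self.frame["region"] == region) & (self.frame["year"] == year)
        ]
        return {
            row.species: NBParams(
                row.mu, row.k, row.status, int(row.n_tows), int(row.n_occupied)
            )
            for row in sub.itertuples()
        }

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ParamTable":
        frame = pd.read_csv(path)
        missing = set(cls.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"param CSV missing columns {sorted(missing)}")
        return cls(frame=frame)


def passes_filter(counts: np.ndarray, rule: str = "tows", threshold: int = 3) -> bool:
    """Inclusion filter for fitting a species-year.

    ``tows``: present in >= threshold tows; ``individuals``: total catch
    >= threshold individuals.
    """
    if rule == "tows":
        return int(np.count_nonzero(counts)) >= threshold
    if rule == "individuals":
        return int(counts.sum()) >= threshold
    raise ValueError(f"unknown filter rule {rule!r}")


def fit_yearly_params(
    table: CatchTable,
    community: list[str],
    regions: list[str] | None = None,
    filter_rule: str = "tows",
) -> ParamTable:
    """Fit yearly NB parameters for every community species in every year.

    Count vectors span the full tow roster (zeros included).  Species-years
    failing the inclusion filter are recorded with status ``not_fit``.
    """
    rows = []
    for region in regions or sorted({r for r, _ in table.tow_roster}):
        for year in table.years(region):
            roster_n = table.n_tows(region, year)
            if roster_n == 0:
                logger.warning("empty tow roster for %s %d; year skipped", region, year)
                continue
            mat = table.year_matrix(region, year, list(community))
            for i, sp in enumerate(community):
                counts = mat[i]
                n_occ = int(np.count_nonzero(counts))
                if passes_filter(counts, filter_rule):
                    params = fit_nb(counts)
                else:
                    params = NBParams(
                        float("nan"), float("nan"), STATUS_NOT_FIT, roster_n, n_occ
                    )
                rows.append(
                    {
                        "region": region,
                        "year": year,
                        "species": sp,
                        "mu": params.mu,
                        "k": params.k,
                        "status": params.status,
                        "n_tows": params.n_tows,
                        "n_occupied": params.n_occupied,
                    }
                )
    frame = pd.DataFrame(rows, columns=list(ParamTable.COLUMNS))
    return ParamTable(frame=frame, filter_rule=filter_rule)


def median_params(params: ParamTable, region: str) -> dict[str, NBParams]:
    """Per-species across-years median (mu, k) over years with status ``ok``.

    Medians are taken independently per parameter (standard midpoint
    convention for even year counts).  Species with no successfully fitted
    year are excluded with a warning.
    """
    sub = params.frame[
        (params.frame["region"] == region) & (params.frame["status"] == STATUS_OK)
    ]
    out: dict[str, NBParams] = {}
    for sp, grp in sub.groupby("species"):
        out[sp] = NBParams(
            mu=float(grp["mu"].median()),
            k=float(grp["k"].median()),
            status=STATUS_OK,
            n_tows=0,
            n_occupied=0,
        )
    all_species = set(params.frame[params.frame["region"] == region]["species"])
    for sp in sorted(all_species - set(out)):
        logger.warning("species %r has no fitted year in %s; excluded", sp, region)
    if not out:
        raise ValueError(f"no species with a fitted year in region {region!r}")
    return out


@dataclass(frozen=True)
class ParamTrend:
    """Mann-Kendall trend of the yearly cross-species mean of one NB parameter."""

    region: str
    parameter: str
    tau: float
    p_value: float
    series: pd.Series
    result: TrendResult


def parameter_series(params: ParamTable, region: str, parameter: str) -> pd.Series:
    """Yearly arithmetic mean of a parameter across successfully fitted species."""
    if parameter not in ("mu", "k"):
        raise ValueError("parameter must be 'mu' or 'k'")
    sub = params.frame[
        (params.frame["region"] == region) & (params.frame["status"] == STATUS_OK)
    ]
    if sub.empty:
        raise ValueError(f"no fitted parameters for region {region!r}")
    return sub.groupby("year")[parameter].mean().sort_index()


def parameter_trend(params: ParamTable, region: str, parameter: str) -> ParamTrend:
    """Mann-Kendall test on the yearly mean-parameter series (needs >= 3 years)."""
    series = parameter_series(params, region, parameter)
    if len(series) < 3:
        raise ValueError(
            f"need >= 3 fitted years for a trend test, got {len(series)}"
        )
    result = mann_kendall(series.to_numpy())
    return ParamTrend(
        region=region,
        parameter=parameter,
        tau=result.tau,
        p_value=result.p_value,
        series=series,
        result=result,
    )


def nb_pmf_gamma(x: int, mu: float, k: float) -> float:
    """Gamma-function form of the NB pmf, Γ(x+k)/(Γ(k)·x!)·p^k·(1−p)^x.

    Kept as an explicit alternative route for verification; prefer
    :func:`nb_pmf` in analysis code.
    """
    p = p_from_mu_k(mu, k)
    return (
        math.exp(special.gammaln(x + k) - special.gammaln(k) - special.gammaln(x + 1))
        * p**k
        * (1 - p) ** x
    )
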