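"""Occupancy, abundance, and the interspecific abundance-occupancy regression.

For one sampled community-year (a species x tows count matrix):

* occupancy ``O`` — proportion of tows with at least one individual;
* global mean abundance ``GMA`` — total catch / total tows;
* local mean abundance ``LMA`` — total catch / occupied tows only,
  undefined at zero occupancy.  The identity GMA = LMA * O holds exactly.

The yearly abundance-occupancy relationship (AOR) is the ordinary
least-squares regression

    asin(sqrt(O)) = s * ln(A) + C

across species, where A is GMA or LMA.  Its slope ``s``, intercept
``C`` and coefficient of determination R^2 serve as indices of
community spatial state; no mechanistic model is implied.  The
arcsine-square-root transform is the standard variance-stabilizer for
proportions; a plain-arcsine variant is available for comparison.
Species with zero sampled catch are excluded (ln A undefined), and the
number of species entering each regression is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

GMA = "GMA"
LMA = "LMA"
MEASURES = (GMA, LMA)

#: an OLS line plus one residual degree of freedom
MIN_POINTS = 3


class AORFitError(ValueError):
    """Too few usable species to fit a yearly AOR."""


@dataclass(frozen=True)
class AORIndices:
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    measure: str


def occupancy(sample: np.ndarray) -> np.ndarray:
    """Per-species proportion of tows occupied (count >= 1)."""
    sample = np.asarray(sample)
    if sample.ndim != 2 or sample.shape[1] < 1:
        raise ValueError("sample must be a species x tows matrix with >= 1 tow")
    return (sample > 0).mean(axis=1)


def abundance(sample: np.ndarray, measure: str = GMA) -> np.ndarray:
    """Per-species GMA (catch/all tows) or LMA (catch/occupied tows).

    LMA is NaN for species occupying zero tows; such species are excluded
    from downstream regressions anyway because ln(A) is undefined at A = 0.
    """
    sample = np.asarray(sample)
    if sample.ndim != 2 or sample.shape[1] < 1:
        raise ValueError("sample must be a species x tows matrix with >= 1 tow")
    totals = sample.sum(axis=1).astype(float)
    if measure == GMA:
        return totals / sample.shape[1]
    if measure == LMA:
        occupied = (sample > 0).sum(axis=1).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            lma = np.where(occupied > 0, totals / np.where(occupied > 0, occupied, 1), np.nan)
        return lma
    raise ValueError(f"measure must be one of {MEASURES}, got {measure!r}")


def transform_occupancy(o: np.ndarray, arcsine_sqrt: bool = True) -> np.ndarray:
    """asin(sqrt(O)) (default) or plain asin(O); O = 1 maps exactly to pi/2."""
    o = np.asarray(o, dtype=float)
    return np.arcsin(np.sqrt(o)) if arcsine_sqrt else np.arcsin(o)


def fit_aor(
    o: np.ndarray,
    a: np.ndarray,
    measure: str = GMA,
    min_points: int = MIN_POINTS,
    arcsine_sqrt: bool = True,
) -> AORIndices:
    """OLS of transformed occupancy on ln(abundance) across species.

    Species with A <= 0, O <= 0 or non-finite A (zero catch in the sample)
    are dropped first.  Raises :class:`AORFitError` when fewer than
    ``min_points`` species remain.
    """
    o = np.asarray(o, dtype=float)
    a = np.asarray(a, dtype=float)
    if o.shape != a.shape:
        raise ValueError("occupancy and abundance vectors must align")
    usable = np.isfinite(a) & (a > 0) & (o > 0)
    o, a = o[usable], a[usable]
    n = o.size
    if n < min_points:
        raise AORFitError(
            f"only {n} species with positive catch; need >= {min_points}"
        )
    y = transform_occupancy(o, arcsine_sqrt=arcsine_sqrt)
    x = np.log(a)
    if np.allclose(y, y[0]):
        # no y-variation: flat line, zero explained variance
        return AORIndices(0.0, float(y[0]), 0.0, n, measure)
    res = stats.linregress(x, y)
    return AORIndices(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=n,
        measure=measure,
    )


def aor_from_sample(
    sample: np.ndarray,
    measure: str = GMA,
    min_points: int = MIN_POINTS,
    arcsine_sqrt: bool = True,
) -> AORIndices:
    """Occupancy + abundance + regression for one sampled species x tows matrix."""
    o = occupancy(sample)
    a = abundance(sample, measure)
    return fit_aor(o, a, measure=measure, min_points=min_points, arcsine_sqrt=arcsine_sqrt)


def aor_points(sample: np.ndarray, species: list[str], measure: str = GMA):
    """Per-species (species, O, A, measure) rows for export or plotting."""
    o = occupancy(sample)
    a = abundance(sample, measure)
    return [
        {"species": sp, "O": float(oi), "A": float(ai), "measure": measure}
        for sp, oi, ai in zip(species, o, a)
    ]
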