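"""Monte-Carlo community simulation and survey resampling.

For each iteration and survey year, a community of species is realized
by drawing each species' abundance at every one of ``n_sites``
exchangeable sites from its (mu, k) negative binomial for that year
(species at the underdispersion boundary are drawn Poisson(mu), to
which the NB converges as k grows).  A trawl survey is then emulated by
sampling ``n_tows`` sites uniformly without replacement, and yearly AOR
indices are computed from the sampled matrix for each requested
abundance measure.

Three modes cover the study designs:

* ``baseline`` — each year uses that year's fitted parameters;
* ``constant_median`` — every year uses each species' across-years
  median (mu, k), nulling out intraspecific temporal variation so any
  residual index trend reflects sampling noise alone;
* ``species_removal`` — baseline with a named subset of species deleted
  from the community before simulation (e.g. the seven schooling /
  aggregating Gulf of Maine species of the 1973-1982 case study).

Randomness is organized as one root seed with a dedicated substream per
(iteration, year, species) and per (iteration, year) for site
selection, so any slice of the experiment is reproducible in isolation,
iterations are order-independent, and removal runs share random numbers
with baseline for the retained species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import aor
from .aor import AORFitError, AORIndices, aor_from_sample
from .nb_model import NBParams, ParamTable, median_params

logger = logging.getLogger(__name__)

MODE_BASELINE = "baseline"
MODE_CONSTANT_MEDIAN = "constant_median"
MODE_SPECIES_REMOVAL = "species_removal"

#: Gulf of Maine schooling/aggregating species removed in the case study
GOM_CASE_STUDY_SPECIES = (
    "Alosa pseudoharengus",       # Alewife
    "Alosa sapidissima",          # American shad
    "Argentina silus",            # Atlantic argentine
    "Clupea harengus",            # Atlantic herring
    "Doryteuthis pealeii",        # longfin squid
    "Illex illecebrosus",         # northern shortfin squid
    "Placopecten magellanicus",   # sea scallop
)

#: inclusive year window of the Gulf of Maine case study
GOM_CASE_STUDY_WINDOW = (1973, 1982)


@dataclass(frozen=True)
class SimConfig:
    """Monte-Carlo experiment configuration (defaults follow the study design)."""

    n_sites: int = 10_000
    n_tows: int = 55
    n_iterations: int = 500
    mode: str = MODE_BASELINE
    removed_species: tuple[str, ...] = ()
    seed: int = 0
    abundance_measures: tuple[str, ...] = (aor.GMA, aor.LMA)
    year_range: tuple[int, int] | None = None
    min_points: int = aor.MIN_POINTS
    arcsine_sqrt: bool = True

    def __post_init__(self):
        if self.n_tows > self.n_sites:
            raise ValueError("n_tows must not exceed n_sites")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        for m in self.abundance_measures:
            if m not in aor.MEASURES:
                raise ValueError(f"unknown abundance measure {m!r}")


@dataclass
class CommunityMatrix:
    counts: np.ndarray  # species x sites
    species_order: list[str]
    provenance: tuple = ()


@dataclass
class SampleMatrix:
    counts: np.ndarray  # species x tows
    site_ids: np.ndarray
    species_order: list[str] = field(default_factory=list)


def _substream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def _draw_species_row(params: NBParams, n_sites: int, rng: np.random.Generator):
    if params.status == "boundary_k":
        return rng.poisson(params.mu, size=n_sites)
    if params.mu == 0:
        return np.zeros(n_sites, dtype=np.int64)
    p = params.k / (params.k + params.mu)
    return rng.negative_binomial(params.k, p, size=n_sites)


def simulate_community(
    year_params: dict[str, NBParams],
    n_sites: int,
    rng,
    provenance: tuple = (),
) -> CommunityMatrix:
    """Draw a species x sites community from per-species NB parameters.

    ``rng`` is either a single Generator (species drawn in sorted-label
    order) or a mapping species -> Generator for per-species substreams.
    Species whose fit status is ``not_fit`` are omitted from the matrix.
    """
    usable = {sp: p for sp, p in year_params.items() if p.usable}
    if len(usable) < 2:
        raise ValueError(
            f"need >= 2 species with usable parameters, got {len(usable)}"
        )
    species = sorted(usable)
    rows = []
    for sp in species:
        gen = rng[sp] if isinstance(rng, dict) else rng
        rows.append(_draw_species_row(usable[sp], n_sites, gen))
    return CommunityMatrix(
        counts=np.vstack(rows).astype(np.int64),
        species_order=species,
        provenance=provenance,
    )


def sample_survey(
    community: CommunityMatrix, n_tows: int, rng: np.random.Generator
) -> SampleMatrix:
    """Uniform without-replacement sample of ``n_tows`` site columns."""
    n_sites = community.counts.shape[1]
    if n_tows > n_sites:
        raise ValueError(f"n_tows={n_tows} exceeds n_sites={n_sites}")
    site_ids = rng.choice(n_sites, size=n_tows, replace=False)
    return SampleMatrix(
        counts=community.counts[:, site_ids],
        site_ids=site_ids,
        species_order=list(community.species_order),
    )


def _year_param_sets(
    params: ParamTable, region: str, config: SimConfig
) -> tuple[dict[int, dict[str, NBParams]], dict[str, int]]:
    """Resolve per-year parameter sets for the configured mode.

    Also returns a stable species -> substream index map covering the full
    community, so removal runs reuse baseline streams for retained species.
    """
    years = params.years(region)
    if config.year_range is not None:
        lo, hi = config.year_range
        years = [y for y in years if lo <= y <= hi]
    if len(years) < 3:
        raise ValueError(f"need >= 3 years for region {region!r}, got {len(years)}")

    all_species = sorted(params.frame[params.frame["region"] == region]["species"].unique())
    species_index = {sp: i for i, sp in enumerate(all_species)}

    if config.mode == MODE_CONSTANT_MEDIAN:
        medians = median_params(params, region)
        return {y: dict(medians) for y in years}, species_index

    sets = {y: {sp: p for sp, p in params.year_params(region, y).items() if p.usable}
            for y in years}
    if config.mode == MODE_SPECIES_REMOVAL:
        unknown = [sp for sp in config.removed_species if sp not in all_species]
        if unknown:
            logger.warning("removal list species not in community, ignored: %s", unknown)
        removed = set(config.removed_species)
        sets = {y: {sp: p for sp, p in yp.items() if sp not in removed}
                for y, yp in sets.items()}
    elif config.mode != MODE_BASELINE:
        raise ValueError(f"unknown simulation mode {config.mode!r}")
    return sets, species_index


def run_simulation(
    year_param_sets: dict[int, dict[str, NBParams]],
    config: SimConfig,
    species_index: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Core Monte-Carlo loop over explicit per-year parameter sets.

    Returns the long index table (iteration, year, measure, slope,
    intercept, r_squared, n_points).  Substream indices default to the
    sorted order of all species appearing in any year.
    """
    if species_index is None:
        all_sp = sorted({sp for yp in year_param_sets.values() for sp in yp})
        species_index = {sp: i for i, sp in enumerate(all_sp)}
    years = sorted(year_param_sets)
    rows = []
    for iteration in range(config.n_iterations):
        for year in years:
            year_params = year_param_sets[year]
            usable = {sp: p for sp, p in year_params.items() if p.usable}
            if len(usable) < 2:
                logger.warning(
                    "iteration %d year %d: <2 usable species; year skipped",
                    iteration, year,
                )
                continue
            # dedicated substream per (iteration, year, species); index 0
            # of the species axis is reserved for site selection
            gens = {
                sp: _substream(config.seed, iteration, year, species_index[sp] + 1)
                for sp in usable
            }
            community = simulate_community(
                usable, config.n_sites, gens,
                provenance=(iteration, year, config.mode),
            )
            site_rng = _substream(config.seed, iteration, year, 0)
            sample = sample_survey(community, config.n_tows, site_rng)
            for measure in config.abundance_measures:
                try:
                    idx = aor_from_sample(
                        sample.counts, measure=measure,
                        min_points=config.min_points,
                        arcsine_sqrt=config.arcsine_sqrt,
                    )
                except AORFitError as exc:
                    logger.warning(
                        "iteration %d year %d (%s): %s", iteration, year, measure, exc
                    )
                    continue
                rows.append(
                    {
                        "iteration": iteration,
                        "year": year,
                        "measure": measure,
                        "slope": idx.slope,
                        "intercept": idx.intercept,
                        "r_squared": idx.r_squared,
                        "n_points": idx.n_points,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["iteration", "year", "measure", "slope", "intercept", "r_squared", "n_points"],
    )


def run_monte_carlo(params: ParamTable, region: str, config: SimConfig) -> pd.DataFrame:
    """Monte-Carlo AOR indices for one region under the configured mode."""
    year_sets, species_index = _year_param_sets(params, region, config)
    return run_simulation(year_sets, config, species_index)


def gom_case_study_config(config: SimConfig) -> SimConfig:
    """Specialize a config to the Gulf of Maine removal case study."""
    return replace(
        config,
        mode=MODE_SPECIES_REMOVAL,
        removed_species=tuple(config.removed_species) or GOM_CASE_STUDY_SPECIES,
        year_range=config.year_range or GOM_CASE_STUDY_WINDOW,
    )
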