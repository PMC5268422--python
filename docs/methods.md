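# Methods

## Data model

The unit of observation is a tow: one sampling event within a
(region, year). Input is a long-format CSV (region, year, tow, species,
count) plus, ideally, a tow roster giving every tow sampled per
region-year. The roster matters because zero catches are information:
occupancy denominators and the zero class of the count distribution both
need tows where a species was absent. Without a roster file the roster is
inferred from observed tows, which understates effort only if some tow
caught none of the ingested species. Duplicate rows for the same
(region, year, tow, species) are summed, since raw survey exports often
split one haul across length or sex classes; zero-count rows are accepted
and contribute their tow to the roster.

## Community selection

S_i = H_i/H_max + y_i/y_tot ranks species by combined relative total catch
and year coverage; the top n (default 30) are the community for all years
of a region. Rank ties are broken by species label so selection is
deterministic and order-invariant. The same community in every year keeps
the interspecific regression comparable across the series.

## Negative-binomial fitting

Counts across tows in a species-year are modelled iid NB(μ, k) with
p = k/(k + μ):

    P(x) = C(x + k − 1, x) · p^k · (1 − p)^x,   Var = μ + μ²/k.

k is the aggregation (size) parameter: small k concentrates mass at zero
and in large catches (patchy), k → ∞ recovers Poisson. The MLE of μ is the
sample mean exactly, so fitting reduces to 1-D maximization of the profile
log-likelihood in log k (scipy bounded scalar minimization, xatol 1e-10 on
log k, started at the method-of-moments value max(mean²/(var−mean), 0.1)).
Underdispersed samples (var ≤ mean) have no interior optimum; k is capped
at k_cap = 1e4 and flagged `boundary_k`, and simulation draws such species
Poisson(μ). Degenerate inputs (fewer than 3 counts, or all zeros) are
`not_fit`.

Inclusion filter: a species enters a year's fit only when "caught more
than twice". Two readings exist; the default interprets it as present in
≥ 3 tows of the region-year, with total catch ≥ 3 individuals available as
`filter_rule="individuals"`. The tow reading is the default because three
occupied tows is the minimal support for estimating a spatial-aggregation
parameter at all, whereas three individuals can sit in one tow.
Species-years failing the filter are `not_fit` and simply absent from that
year's simulated community and from cross-species parameter means.

Parameter trends: yearly arithmetic means of μ and of k across fitted
species, each Mann-Kendall-tested over years. Means (not medians) match
the cross-species summary convention used for the parameter-trend tables;
note the mean of fitted k is heavy-tailed at ~55 tows, so its series is
noisier than μ's.

## Simulation design

Per iteration × year, each usable species' abundance at n_sites
(default 10,000) exchangeable sites is drawn from its NB; the survey is
n_tows (default 55) sites sampled uniformly without replacement;
n_iterations defaults to 500. Sampling 55 of 10,000 NB-iid sites is
distributionally equivalent to 55 direct NB draws (verified by a KS check
in the tests); the large site pool is kept for fidelity to the survey
design and for manipulations that might later couple sites.

RNG: one root seed, with a dedicated PCG64 substream per
(iteration, year, species) via `SeedSequence(seed, spawn_key=...)` (key 0
in the species slot reserved for site selection). Consequences: any slice
of an experiment is reproducible in isolation; iterations are
order-independent; and removal runs share random numbers with baseline
for retained species, so baseline-vs-removal differences are not inflated
by fresh noise. Empty removal lists reproduce baseline bitwise.

Modes: `baseline` (each year's fitted parameters), `constant_median`
(across-years median μ and k per species, medians taken independently per
parameter over `ok` years, every year identical — the stochastic null),
`species_removal` (baseline minus a named species list; the packaged
default list is the seven schooling/aggregating Gulf of Maine species,
window 1973–1982 inclusive).

## AOR indices

Per sampled year: O_i = occupied tows / n_tows; GMA_i = total/n_tows;
LMA_i = total/occupied (undefined at zero occupancy). OLS of
asin(√O) on ln(A) gives slope, intercept and R². The arcsine-square-root
transform is the standard variance stabilizer for proportions; a plain
asin(O) variant is switchable (`arcsine_sqrt=False`) since wordings of
"arcsine transformed" vary. O = 1 needs no clamping (asin(1) = π/2).
Species with zero sampled catch are excluded (ln A undefined); years with
fewer than min_points = 3 usable species (a line plus one residual degree
of freedom) are dropped from trend series with a warning, and n_points is
recorded per fit. A year with no occupancy variation returns slope 0,
R² 0 exactly rather than a degenerate regression.

## Trend testing and aggregation

Mann-Kendall: S = Σ_{i<j} sign(x_j − x_i), tie-adjusted variance
[n(n−1)(2n+5) − Σ t(t−1)(2t+5)]/18, continuity-corrected two-sided normal
p-value, τ reported as tau-b (tie-corrected; equal to S/(n(n−1)/2) when
values are untied). Constant series give τ = 0, p = 1. Missing years are
dropped, not interpolated — the test uses order only. At series length
~45 the normal approximation's type-I error is nominal to within ±1%
(checked at 10,000 replicates).

Across iterations: mean τ̄ (unweighted), empirical 2.5/97.5 percentile CI
(normal-approximation CI available), significance = CI excludes zero, and
the fraction of iterations with p < 0.05 is reported alongside. Yearly
index summaries use the same percentile convention.

## Synthetic data generator

Scenarios place species on geometric parameter trajectories
μ_t = μ0·g_μ^t, k_t = k0·g_k^t — multiplicative so parameters stay
positive and log-linear trends are exact — with optional per-year presence
probability to exercise the intermittency/not_fit pathways. The reference
community draws μ0 log-uniform on [0.1, 20] individuals/tow and k0
log-uniform on [0.2, 5], spanning the spread of fitted groundfish
communities from sub-individual-per-tow rarities to abundant schoolers and
from strong clumping to near-Poisson. Default geometry: 45 years,
55 tows/year, 30 species, one region. The case-study scenario ramps 7 of
30 species (μ ×1.25/year, k ×0.8/year) over 10 years against a stationary
backdrop.

What the generator does **not** emulate: depth stratification and
area-weighted effort, spatial autocorrelation among sites, gear
selectivity or catchability drift, species interactions, and
non-geometric abundance dynamics. Passing tests therefore demonstrate
internal consistency of the estimator–simulator–test chain under the NB
sampling model, not robustness to survey-design artifacts in real data.

## Problem sizes and numerical choices

The packaged null-calibration experiment (tests and
`scripts/acceptance.py`) runs 30 species × 45 years × 200 iterations at
2,000 sites with 55-tow sampling — site-pool and iteration counts chosen
so the binomial uncertainty on a 5% rate (SE ≈ 1.5% at 200 iterations)
is tight enough to be informative while the run stays around a minute;
the 55-of-N subsample is distribution-equivalent across N, so the smaller
pool does not bias it. Examples scale further down. Optimizer tolerances
and the k cap are stated above; percentile CIs use numpy's default linear
interpolation.

## Known limitations

- LMA regressions lose species at low occupancy and are noisier than GMA;
  with heavy exclusion (small n_points) yearly indices can jump.
- k̂ is poorly determined at 55 tows for near-Poisson species; boundary
  flags should be inspected before interpreting k trends.
- Empirical trend comparisons treat tows as exchangeable; stratified
  designs with changing allocation will violate that silently.
- The Mann-Kendall normal approximation is used at all n ≥ 3; at very
  short series (n < 8) exact-null p-values would differ noticeably.
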