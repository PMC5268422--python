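# aortrend

Trend analysis of interspecific **abundance–occupancy relationships (AORs)**
for tow-based community surveys, built around Monte-Carlo simulation from
fitted negative-binomial spatial distributions.

## The problem

Marine community surveys (the motivating case is a multi-decadal fall
bottom-trawl groundfish survey split into contiguous shelf regions) record,
for each tow, how many individuals of each species were caught. Two summaries
of a species' spatial state in a year are its **occupancy** *O* — the
proportion of tows with at least one individual — and its mean abundance,
either per all tows (**GMA**, global mean abundance) or per occupied tow only
(**LMA**, local mean abundance; GMA = LMA × O). Across the species of a
community, occupancy rises with abundance; the yearly interspecific
regression

  asin(√O) = s·ln(A) + C

condenses a community's spatial organization into three indices: the slope
*s* (how occupied habitat is shared between rare and common species), the
intercept *C* (community-wide habitat occupation) and *R²* (the diversity of
occupancy strategies). Whether these indices trend over decades — and whether
an apparent trend could be manufactured by survey sampling noise alone — is
the question this package answers.

## The method

1. **Community selection.** Within a region, species are ranked by
   S = H_i/H_max + y_i/y_tot (relative total catch plus proportion of survey
   years present) and the top 30 form the community for all years.
2. **Yearly NB fits.** Each species-year's tow counts (zeros over the full
   tow roster included) are fit by maximum likelihood to a negative binomial
   with mean μ and aggregation parameter k (variance μ + μ²/k; smaller k =
   patchier). Species caught in fewer than 3 tows that year are left unfitted.
   Mann-Kendall tests on the yearly cross-species mean μ and k detect
   parameter drift.
3. **Monte-Carlo simulation.** Per iteration and year, every fitted species'
   abundance at each of 10,000 exchangeable sites is drawn from its NB; a
   55-tow survey is sampled without replacement; AOR indices are computed.
   Per-iteration Mann-Kendall τ on each index series is aggregated over 500
   iterations into a mean τ̄ with a percentile 95% CI (significant when the
   CI excludes zero), and compared with empirical trends computed directly
   from the catch data.
4. **Manipulations.** A *constant-median* null fixes each species at its
   across-years median (μ, k) — any remaining "trend" is sampling noise — and
   a *species-removal* case study re-runs the simulation without a named
   subset (e.g. seven schooling/aggregating species over 1973–1982) to
   attribute a community trend.

## Worked example

```bash
python examples/04_null_calibration.py
```

prints (scaled to 1,000 sites × 100 iterations):

```
GMA: 4.0% of 100 iterations significant, mean tau = -0.002
LMA: 4.0% of 100 iterations significant, mean tau = +0.006
```

With every species' (μ, k) held constant, only ~5% of iterations show a
"significant" Mann-Kendall trend in the AOR slope series — the nominal
false-positive rate — and the mean τ sits at zero: observed index trends in
real series are therefore not artifacts of year-to-year sampling
stochasticity. The other examples walk through community selection
(`01`), NB fitting and parameter trends (`02`), a full baseline
simulate-and-summarize run with its empirical comparison (`03`), and the
aggregator-removal case study (`05`).

A thin CLI mirrors the library (`aortrend synth | fit-params | simulate |
trends | run-all`); see `aortrend --help`.

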