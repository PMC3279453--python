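# Methods

## Scope and structure

The package estimates the chronic (not acute) health burden of nonbiological
air pollutants inhaled in U.S. residences, as DALYs lost per 100,000 persons
per year. The residential contribution is treated as an increment: in-home
inhalation of air at the population-mean indoor concentration, relative to a
hypothetical pollutant-free residence. Burden is linear (or effectively
linear) in concentration with no effect threshold, so only the mean of each
concentration distribution enters the main model; the threshold-sensitivity
module (below) quantifies what a threshold would change.

Five criteria pollutants (PM2.5, ozone, NO2, SO2, CO) run through the
epidemiology-based intake-incidence-DALY (IND) chain; the remaining
pollutants run through the toxicology-based intake-DALY (ID) extrapolation.
Ozone is the only pollutant eligible for both; the IND result enters the
aggregate total (epidemiology avoids interspecies extrapolation and carries
smaller uncertainty) and the ID result is reported alongside for comparison.

## Exposure

The occupancy table has three age bins (≤2, 2–16, ≥16 years) with population
fractions 0.03/0.19/0.78, time at home 0.75/0.75/0.69, air intake 7/13/15
m³/day and cancer age-dependent adjustment factors (ADAF) 10/3/1. Weighted
averages: time at home 0.7032 (reported as 70%), intake 14.38 m³/day, ADAF
1.65 (population-weighted; an intake-and-time-weighted alternative ≈1.5 is
exposed via `population_adaf(..., weighting="intake_time")` since the
aggregation convention is not fixed by the published rounding to 1.6).

The annual residential breathing volume V is computed group-wise,
Σ fraction·intake·time·365 = 3,680 m³/yr, not as the product of the two
population averages: V is an individual intake aggregated over people, and
intake and time-at-home co-vary across bins (the difference is <0.5% here).
Days per year are fixed at 365. The chronic exposure increment is
ΔC = occupancy × C_indoor with occupancy defaulting to the population
time-at-home.

## IND track

Per outcome, excess incidence is −y0·(exp(−β·ΔC)−1)·population, saturating
at y0·population. One outcome (NO2-associated respiratory illness indicated
by symptoms) has a symptom-based published form without a baseline
prevalence; it is evaluated as the linearization β·ΔC·population (y0 treated
as 1) and flagged in the output notes. β units are assumed to be per µg/m³,
matching the concentration table; outputs carry this assumption as a note
because the published table does not state units for the gaseous slopes.

Sampling conventions, chosen because the published procedure specifies
Monte Carlo sampling but not distribution families for slopes:

- β: normal with mean = central value and σ = (CI_high − CI_low)/(2·1.96),
  truncated at zero (negative slopes are not meaningful here).
- DALYs per case: lognormal with the printed central value as the median and
  σ_ln = ln(CI_high/CI_low)/(2·1.96). When a printed central value is
  inconsistent with the geometric midpoint of its CI, the printed central
  wins as the median. One tabulated record (PM2.5 total-mortality slope
  0.058 with CI (0.002, 0.010)) has a central value outside its own CI —
  likely a per-10-µg/m³ vs per-µg/m³ transcription in the source; it is
  stored as printed, the loader logs the inconsistency exactly once, and the
  sampler uses the printed values. Consequently the absolute PM2.5 (and
  ozone, which shares the unit ambiguity) IND magnitudes are assumption-tagged
  rather than treated as exact reproductions.
- Hospital-admission outcomes share a fixed 4×10⁻⁴ DALYs-per-admission
  factor applied to every admission category.
- Nonfatal stroke: predicted incidence is split across complication strata
  (0 / 1 / >1 complications, DALYs per case 9.5 / 11.7 / 13.1 with CIs).
  The split weights are not published; the default is the uninformative
  (1/3, 1/3, 1/3) and is configurable. Fatal stroke is not modelled
  separately.

Excluded by design: acute effects, PM2.5 hospital admissions (negligible
next to mortality/bronchitis/stroke), diabetes and lung-function end points,
and nonlinear response forms.

## ID track

DALYs/person/yr = C·V·(CF_cancer·ADAF + CF_noncancer) with factors in DALY
per kg inhaled and a single µg→kg conversion (1e-9) applied to the intake
term. ADAF multiplies only the cancer factor. Each factor's uncertainty is
lognormal, characterized by k = (97.5th/2.5th percentile)^0.5, i.e.
σ_ln = ln(k)/1.96 with the central estimate as median; cancer and noncancer
factors are sampled independently (no joint structure is published). Since V
and ADAF are already population-averaged, multiplying the per-person result
by 10⁵ gives DALYs per 100,000 persons directly.

The published characterization-factor database is external and is not
redistributed; `synthetic_data.generate_id_factors` emulates it with
log-uniform factors spanning 10⁻⁴–10² DALY/kg (chosen so per-pollutant
burdens spread over roughly 10⁻²–10² DALYs/100k/yr at typical indoor
concentrations) and log-uniform k in [1.5, 20]. Synthetic tables are always
labelled synthetic, never written into the fixtures directory, and carry no
per-pollutant toxicological meaning — so per-pollutant ID magnitudes from a
default pipeline run are illustrative, while unit handling, sampling and
aggregation are exact and tested against analytic oracles.

## Monte Carlo engine

Default n = 10,000 samples and seed 42, both exposed everywhere. Multi-
pollutant runs spawn one independent child seed per pollutant from the
master seed, keeping sample vectors aligned; the total is the element-wise
sum. Dominance (fraction of draws in which a pollutant is the largest
contributor) breaks ties toward the first-listed pollutant — a measure-zero
event for continuous draws. Summaries are empirical 50th/2.5th/97.5th
percentiles with linear interpolation. Fixed seeds give bit-identical
results on one platform.

## Attributed hazards

Secondhand smoke, radon and acute CO poisoning are estimated from
literature-attributed excess incidences × DALYs per case, normalized per
100,000 (national counts divide by a 3.0×10⁸ population default, chosen for
consistency with the attributed-total arithmetic; per-million death rates
rescale directly). Incidences printed with a CI are sampled lognormally with
the printed central as median (the radon CIs are strongly right-skewed);
values printed without a CI — including the SIDS factor of 78 DALYs/case
(a full life expectancy) and the per-1,000-case factors stored as per-case
decimals — are fixed. Point arithmetic gives radon medians of 84
(smokers) and 14 (nonsmokers) per 100k versus independently reported
stochastic medians of 79 and 13; the ~6–8% residual is a known
discrepancy whose source (population constant or distribution convention in
the original analysis) is not resolvable from the published inputs, and it
is carried as-is rather than tuned away. The radon-smoking interaction is
not corrected for, so the smoker radon figure overstates radon per se.

The SHS component scenario pushes measured in-home concentration increments
through the same two tracks: PM2.5 (+16 µg/m³, the measured smoking-home
elevation) via IND and a suite of volatile organics via ID, then multiplies
by the smoking-home fraction (default 0.11) for the population average. Only
the PM2.5 increment is a measured quantity; the VOC increments default to
synthetic stand-ins (each component's population-mean concentration, i.e. a
doubling; 1 µg/m³ for components without a tabulated mean), so results are
order-of-magnitude cross-checks of the attribution-based SHS figure.

## Threshold sensitivity

Home-to-home concentration variability is modelled lognormal, parameterized
by arithmetic mean and geometric standard deviation (the exposure
literature's reporting convention) and converted internally to log-scale
parameters. Two no-effect-threshold conventions are implemented, both in
closed form via lognormal partial expectations and cross-checked by
quadrature to 1e-6:

- **excess** (default): only concentration above the threshold harms,
  reduction = 1 − E[(C−T)⁺]/E[C]. A no-effect threshold most naturally
  zeroes the sub-threshold part of the dose, hence the default.
- **truncation**: sub-threshold homes contribute nothing, others their full
  concentration, reduction = 1 − E[C·1{C>T}]/E[C].

Truncation-mode reduction never exceeds excess-mode reduction (pointwise
(C−T)⁺ ≤ C·1{C>T}). `calibrate_gsd` inverts the forward model by bracketed
root search (tolerance 1e-6 on the reduction) to ask which GSD reproduces a
reported reduction, signalling non-existence distinctly. Because the GSDs
behind the published formaldehyde/acrolein reduction percentages are not
printed, those percentages are treated as qualitative calibration references,
not exact targets.

## Numerical and degenerate-input conventions

Collapsed CIs (or k = 1) degrade every sampler to a point mass, and the
Monte Carlo median then equals the closed-form chain to machine precision —
this is asserted in the tests and is the recommended way to verify a
configuration deterministically. Validation is eager: fractions outside
[0,1], ADAF < 1, inverted CIs, misaligned sample vectors, weights not
summing to 1 (tolerance 1e-9) and unknown tags all raise `ValidationError`
at construction. Derived child seeds stay below 2³¹.

## Problem sizes

Default runs use n = 10,000 Monte Carlo samples (the full 69-pollutant
pipeline takes well under a minute on one core); the reproduction script
uses n = 100,000 for the radon medians, where the Monte Carlo standard error
of the median is ≈0.2%. The test suite uses n between 200 and 50,000
depending on the tolerance being asserted.

## What the synthetic generator does and does not show

Synthetic factor tables reproduce the *structure* of the external toxicology
database (orders-of-magnitude spread, lognormal dispersion) but none of its
chemistry. Tests built on them therefore validate arithmetic, unit handling,
uncertainty propagation, aggregation and dominance recovery — not the
toxicological ranking of real pollutants. Real-data conclusions additionally
require the external characterization factors, measured concentration
distributions (for thresholds) and resolution of the slope-unit ambiguities
noted above.

## Known limitations

- No activity-pattern simulation beyond the three-bin occupancy table; no
  leap-year handling.
- No cross-pollutant correlation in sampling; no variance decomposition.
- The linearized NO2 symptom outcome is a stand-in for an unpublished
  functional form.
- Aggregate totals from default (synthetic-factor) runs are not comparable
  to published totals; the report flags totals whose upper CI exceeds the
  independent all-disease burden reference (7,700 DALYs/100k/yr) as
  implausible, mirroring the plausibility check used in this literature.
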