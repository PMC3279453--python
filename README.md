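# daly-iaq

Population-average chronic health burden of **indoor residential air
pollutants**, expressed in disability-adjusted life-years (DALYs) lost per
100,000 persons per year.

Indoor air in U.S. homes carries dozens of pollutants — fine particles,
aldehydes, volatile organics, combustion gases — each with different disease
end points and severities. Comparing them, and comparing indoor air with
other environmental hazards, requires a single metric that combines disease
incidence with disease severity. This package implements that impact
assessment for users in exposure science, indoor air quality and
environmental health policy: people evaluating ventilation standards, energy
retrofits or source-control measures at the population scale.

## The model

Burden is computed on two parallel tracks and aggregated by Monte Carlo:

**Intake-incidence-DALY (IND)** — for the criteria pollutants (PM2.5, ozone,
NO2, SO2, CO) with human epidemiology. Excess incidence of each outcome
follows the exponential concentration-response form

```
ΔIncidence = −y0 · (exp(−β·ΔC) − 1) · population
```

with baseline annual prevalence `y0`, slope `β` (per µg/m³) and chronic
exposure increment `ΔC = 0.70 × C_indoor` (the average resident spends 70% of
the day at home). Incidence is converted to burden with DALYs-lost-per-case
factors; nonfatal stroke is split across complication strata.

**Intake-DALY (ID)** — for the remaining pollutants, which lack human
concentration-response functions. Burden is extrapolated directly from
inhaled mass via toxicology-derived characterization factors:

```
DALYs/person/yr = C · V · (CF_cancer · ADAF + CF_noncancer)
```

where `V ≈ 3,680 m³/yr` is the demographics-weighted volume of residential
air breathed per person and `ADAF ≈ 1.65` is the cancer age-dependent
adjustment factor for early-life exposure. Each factor's uncertainty is
lognormal with dispersion `k = (P97.5/P2.5)^0.5`. The published factor
database is external and not redistributed; `daly_iaq.synthetic_data`
generates structurally matched synthetic stand-ins so the full pipeline runs
out of the box.

All uncertain inputs are propagated by seeded Monte Carlo (slopes: truncated
normal; DALY factors and skewed incidences: lognormal with the printed
central value as median). Aggregation works on aligned sample vectors, so the
total burden and the *dominance* statistic — which pollutant is the largest
contributor in each draw — come from one joint sample. Three established
hazards (secondhand smoke, radon, acute CO poisoning) are estimated from
literature-attributed incidences instead of concentrations, and a
threshold-sensitivity module quantifies how much predicted burden disappears
if a pollutant has a no-effect concentration threshold.

## Worked example

The attributed hazards, computed from the packaged incidence table with
100,000 Monte Carlo samples:

```text
$ daly-iaq attribution --samples 100000 --seed 1
SHS: median 50.8 (95% CI: 44.3, 62.3) DALY/100k/yr
acute_CO: median 4.9 (95% CI: 4.71, 5.09) DALY/100k/yr
radon_nonsmoker: median 14 (95% CI: 1.4, 138) DALY/100k/yr
radon_smoker: median 84.1 (95% CI: 26.2, 270) DALY/100k/yr
```

Secondhand smoke costs about 51 DALYs per 100,000 persons per year
(asthma episodes, otitis media, SIDS, cardiac and lung-cancer deaths
combined); radon-attributable lung cancer in smokers about 84, in nonsmokers
about 14; acute CO poisoning deaths about 4.9. The wide radon intervals
reflect the skewed uncertainty in attributed death counts.

Threshold sensitivity — if formaldehyde (mean indoor concentration
69 µg/m³, home-to-home GSD 2.5) caused no harm below 120 µg/m³:

```text
$ daly-iaq threshold --pollutant Formaldehyde --mean 69 --gsd 2.5 --threshold 120 --mode excess
Formaldehyde: 80.9% reduction in predicted DALY losses (threshold 120.0 ug/m3, excess mode, GSD 2.5)
```

A full two-track run over all 69 pollutants (`daly-iaq total --samples 10000
--seed 42`) prints the aggregate total and the dominance table; without a
user-supplied factor table the toxicology track uses synthetic
characterization factors, so the per-pollutant magnitudes are illustrative
while the pipeline mechanics (aggregation, dominance, report provenance) are
exact. Subcommands: `ind`, `id`, `attribution`, `total`, `threshold`, `shs`,
`synth`, `report`; all accept `--samples`, `--seed`, `--population`.

Input tables are plain CSV (schemas in `src/daly_iaq/data/`); outputs are
always labelled `DALY/100k/yr`, and JSON reports embed seed, sample count,
population and input checksums for reproducibility.

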