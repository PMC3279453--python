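"""Epidemiology track: intake -> incidence -> DALYs (criteria pollutants).

Excess disease incidence from a chronic exposure-concentration increment ΔC
follows the exponential concentration-response form

    ΔIncidence = -y0 * (exp(-β ΔC) - 1) * population,

with baseline annual prevalence y0 and slope β per µg/m³.  Incidence is then
multiplied by the DALYs lost per case of the outcome.  One outcome
(NO2-associated respiratory illness indicated by symptoms) uses a linearized
symptom-based form with no baseline prevalence; it is computed as
β·ΔC·population and flagged in the output notes.

Nonfatal stroke is the one outcome whose burden per case depends on severity:
the predicted incidence is split across complication strata (0 / 1 / >1
complications), each with its own DALYs-per-case distribution.

Uncertainty propagation is Monte Carlo: β is drawn from a normal fitted to
its 95% CI and truncated at zero; DALY factors are drawn from lognormals with
the printed central value as the median.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .core_data import (
    CREntry,
    CRFunction,
    DALYPerIncidence,
    Demographics,
    ImpactSummary,
    PollutantConcentration,
    US_POPULATION,
    ValidationError,
    load_stroke_strata,
)
from .exposure import exposure_concentration, population_time_at_home
from .uncertainty import sample_uncertain

__all__ = [
    "DEFAULT_STROKE_WEIGHTS",
    "cr_incidence",
    "cr_incidence_linearized",
    "split_stroke",
    "ind_impact_samples",
]

#: Default split of predicted stroke incidence across 0 / 1 / >1 complications.
#: The published source for the complication split does not print the weights;
#: an uninformative equal split is used and is configurable.
DEFAULT_STROKE_WEIGHTS = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)

_UNITS_NOTE = "beta assumed per ug/m3 (concentration-table units)"


def cr_incidence(
    crf: CRFunction, beta_value: float, delta_c: float, population: float
) -> float:
    """Excess cases/year from the exponential concentration-response form.

    Bounded above by y0 × population (saturation at large β·ΔC).
    """
    _check_inputs(beta_value, delta_c, population)
    y0 = crf.y0 if crf.y0 is not None else 1.0
    return -y0 * (math.exp(-beta_value * delta_c) - 1.0) * population


def cr_incidence_linearized(
    crf: CRFunction, beta_value: float, delta_c: float, population: float
) -> float:
    """First-order (linear-in-ΔC) incidence; equals the exponential form as
    β·ΔC → 0 and bounds it from above elsewhere."""
    _check_inputs(beta_value, delta_c, population)
    y0 = crf.y0 if crf.y0 is not None else 1.0
    return y0 * beta_value * delta_c * population


def _check_inputs(beta_value: float, delta_c: float, population: float) -> None:
    if beta_value < 0:
        raise ValidationError("beta must be nonnegative")
    if delta_c < 0:
        raise ValidationError("concentration increment must be nonnegative")
    if population <= 0:
        raise ValidationError("population must be positive")


def split_stroke(
    incidence: float,
    weights: Sequence[float],
    strata_dalys: Sequence[float] | Sequence[DALYPerIncidence],
) -> float:
    """DALYs/year from stroke incidence split across complication strata."""
    if incidence < 0:
        raise ValidationError("incidence must be nonnegative")
    weights = np.asarray(weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValidationError(f"stroke weights sum to {weights.sum()}, not 1")
    values = np.array(
        [s.value.central if isinstance(s, DALYPerIncidence) else float(s) for s in strata_dalys]
    )
    if values.size != weights.size:
        raise ValidationError("weights and strata lengths differ")
    return float(incidence * np.dot(weights, values))


def ind_impact_samples(
    conc: PollutantConcentration,
    entries: Sequence[CREntry],
    demo: Demographics,
    *,
    population: float = US_POPULATION,
    n: int = 10_000,
    seed: int = 42,
    occupancy: float | None = None,
    stroke_weights: Sequence[float] = DEFAULT_STROKE_WEIGHTS,
    stroke_strata: Sequence[DALYPerIncidence] | None = None,
) -> ImpactSummary:
    """Monte Carlo burden of one criteria pollutant, DALYs per 100,000 per year.

    Per sample: draw β for each outcome (truncated normal) and each DALY
    factor (lognormal), form the exposure increment ΔC = occupancy × indoor
    concentration, evaluate the concentration-response incidence, convert to
    DALYs, and sum over outcomes.  ``entries`` must all belong to
    ``conc.pollutant``; stroke entries (``daly is None``) require the
    complication strata (defaults to the packaged table).

    ``occupancy`` defaults to the population time-at-home from ``demo``.
    """
    if n < 1:
        raise ValidationError("need at least one sample")
    entries = list(entries)
    if not entries:
        raise ValidationError(f"no concentration-response entries for {conc.pollutant}")
    for e in entries:
        if e.crf.pollutant != conc.pollutant:
            raise ValidationError(
                f"entry for {e.crf.pollutant} passed with concentration for {conc.pollutant}"
            )
    if occupancy is None:
        occupancy = population_time_at_home(demo)
    delta_c = exposure_concentration(conc.mean_indoor, occupancy)

    rng = np.random.default_rng(seed)
    total = np.zeros(n)
    notes = [_UNITS_NOTE]
    weights = np.asarray(stroke_weights, dtype=float)

    for entry in entries:
        betas = sample_uncertain(entry.crf.beta, rng, n)
        y0 = entry.crf.y0 if entry.crf.y0 is not None else 1.0
        if entry.crf.form == "linearized":
            incidence = y0 * betas * delta_c * population
            notes.append(f"{entry.crf.outcome}: linearized symptom-based form")
        else:
            incidence = -y0 * (np.exp(-betas * delta_c) - 1.0) * population
        if entry.daly is not None:
            dalys = incidence * sample_uncertain(entry.daly.value, rng, n)
        else:
            if stroke_strata is None:
                stroke_strata = load_stroke_strata()
            if abs(weights.sum() - 1.0) > 1e-9:
                raise ValidationError("stroke weights must sum to 1")
            if len(stroke_strata) != weights.size:
                raise ValidationError("stroke weights and strata lengths differ")
            per_case = np.zeros(n)
            for w, stratum in zip(weights, stroke_strata):
                per_case += w * sample_uncertain(stratum.value, rng, n)
            dalys = incidence * per_case
        total += dalys

    per_100k = total / population * 1e5
    return ImpactSummary.from_samples(conc.pollutant, per_100k, seed=seed, notes=notes)
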