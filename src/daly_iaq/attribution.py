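"""Literature-based DALY attribution: secondhand smoke, radon, acute CO.

Three established indoor hazards are not run through the concentration-based
tracks; their burden comes from excess disease incidences attributed to them
in the literature, multiplied by DALYs lost per case and normalized to
100,000 persons.  Incidences published with a 95% CI are sampled from a
lognormal whose median is the printed central value (the radon CIs are
strongly right-skewed); incidences and DALY factors printed without a CI are
treated as fixed.

The module also provides the secondhand-smoke component cross-check: the
concentration increments measured in smoking homes (PM2.5 and a suite of
volatile organics) are pushed through the same two modelling tracks used for
the main analysis, yielding an independent, component-based estimate of the
SHS burden that can be compared with the attribution-based figure.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .core_data import (
    AttributedOutcome,
    CREntry,
    Demographics,
    IDFactor,
    ImpactSummary,
    PollutantConcentration,
    US_POPULATION,
    ValidationError,
)
from .id_model import id_impact_samples
from .ind_model import ind_impact_samples
from .uncertainty import sample_uncertain, spawn_seeds

__all__ = [
    "SHS_COMPONENT_VOCS",
    "attributed_dalys",
    "attributed_point_estimate",
    "default_shs_increments",
    "shs_component_scenario",
]

#: Volatile organic components of secondhand smoke with measured in-home
#: concentration increments (smoking vs nonsmoking homes).
SHS_COMPONENT_VOCS = (
    "1,3-Butadiene",
    "Methyl ethyl ketone",
    "Acetaldehyde",
    "Acetonitrile",
    "Acrolein",
    "Acrylonitrile",
    "Benzene",
    "Ethylbenzene",
    "Formaldehyde",
    "Naphthalene",
    "Phenol",
    "Styrene",
    "Toluene",
    "Xylenes",
)


def _per_100k_factor(rec: AttributedOutcome, population: float) -> float:
    """Scale from (incidence × DALY/case) to DALYs per 100,000 persons/yr."""
    if rec.rate_basis == "national_count":
        return 1e5 / population
    # per-million rate: divide by 10 to express per 100,000 persons
    return 0.1


def attributed_point_estimate(
    outcomes: Sequence[AttributedOutcome], population: float = US_POPULATION
) -> float:
    """Closed-form central estimate: Σ incidence × DALY/case, per 100k/yr."""
    if population <= 0:
        raise ValidationError("population must be positive")
    return sum(
        rec.excess_incidence.central
        * rec.dalys_per_incidence.central
        * _per_100k_factor(rec, population)
        for rec in outcomes
    )


def attributed_dalys(
    outcomes: Sequence[AttributedOutcome],
    population: float = US_POPULATION,
    *,
    n: int = 10_000,
    seed: int = 42,
) -> ImpactSummary:
    """Monte Carlo attributed burden, DALYs per 100,000 persons per year.

    Per sample, each outcome's incidence and DALY factor are drawn from
    their encoded distributions and summed across outcomes.
    """
    if population <= 0:
        raise ValidationError("population must be positive")
    if n < 1:
        raise ValidationError("need at least one sample")
    outcomes = list(outcomes)
    if not outcomes:
        raise ValidationError("no attributed outcomes supplied")
    hazards = sorted({rec.hazard for rec in outcomes})
    rng = np.random.default_rng(seed)
    total = np.zeros(n)
    for rec in outcomes:
        incidence = sample_uncertain(rec.excess_incidence, rng, n)
        daly = sample_uncertain(rec.dalys_per_incidence, rng, n)
        total += incidence * daly * _per_100k_factor(rec, population)
    return ImpactSummary.from_samples("+".join(hazards), total, seed=seed)


def default_shs_increments() -> dict[str, PollutantConcentration]:
    """Synthetic concentration increments for homes with smokers (µg/m³).

    PM2.5 is elevated by the measured 16 µg/m³.  The VOC increments are
    synthetic stand-ins: smoking is taken to roughly double the in-home
    concentration, so each VOC's increment is set to its population-average
    indoor concentration; components without a tabulated concentration
    (acetonitrile, phenol) get a nominal 1 µg/m³.  Only the PM2.5 increment
    is a measured quantity.
    """
    from .core_data import load_concentrations

    conc = load_concentrations()
    increments = {"PM2.5": PollutantConcentration("PM2.5", 16.0)}
    for voc in SHS_COMPONENT_VOCS:
        base = conc[voc].mean_indoor if voc in conc else 1.0
        increments[voc] = PollutantConcentration(voc, base)
    return increments


def shs_component_scenario(
    increments: Mapping[str, PollutantConcentration],
    demo: Demographics,
    cr_entries: Sequence[CREntry],
    id_factors: Mapping[str, IDFactor],
    *,
    smoking_home_fraction: float = 0.11,
    population: float = US_POPULATION,
    n: int = 10_000,
    seed: int = 42,
) -> tuple[ImpactSummary, ImpactSummary]:
    """Component-based SHS burden from in-home concentration increments.

    PM2.5 runs through the epidemiology track (its concentration-response
    entries from ``cr_entries``); every other increment runs through the
    toxicology track and must have an entry in ``id_factors``.  Returns the
    aggregate burden ``(per_smoking_home, population_averaged)``, the latter
    being the former scaled by ``smoking_home_fraction``.
    """
    if "PM2.5" not in increments:
        raise ValidationError("SHS scenario requires a PM2.5 increment")
    if not 0.0 <= smoking_home_fraction <= 1.0:
        raise ValidationError("smoking-home fraction must lie in [0,1]")
    names = list(increments)
    seeds = spawn_seeds(seed, len(names))
    summaries: list[ImpactSummary] = []
    pm_entries = [e for e in cr_entries if e.crf.pollutant == "PM2.5"]
    for name, child_seed in zip(names, seeds):
        inc = increments[name]
        if name == "PM2.5":
            summaries.append(
                ind_impact_samples(
                    inc, pm_entries, demo, population=population, n=n, seed=child_seed
                )
            )
        else:
            if name not in id_factors:
                raise ValidationError(f"no intake-DALY factor for SHS component {name!r}")
            summaries.append(
                id_impact_samples(inc, id_factors[name], demo, n=n, seed=child_seed)
            )
    per_home_samples = np.sum([s.samples for s in summaries], axis=0)
    per_home = ImpactSummary.from_samples(
        "SHS_components_per_smoking_home", per_home_samples, seed=seed
    )
    pop_avg = ImpactSummary.from_samples(
        "SHS_components_population_average",
        per_home_samples * smoking_home_fraction,
        seed=seed,
    )
    return per_home, pop_avg
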