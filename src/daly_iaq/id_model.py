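"""Toxicology track: intake -> DALYs (noncriteria pollutants).

For pollutants without human concentration-response functions, burden is
extrapolated directly from inhaled mass via characterization factors
(DALYs per kg inhaled, separately for cancer and noncancer chronic effects):

    DALYs/person/yr = C × V × (cancer_factor × ADAF + noncancer_factor),

where C is the indoor concentration, V the volume of residential air
breathed per person per year, and ADAF the population-average cancer
age-dependent adjustment factor (early-life exposure raises carcinogenic
potency; the adjustment applies only to the cancer term).

Each factor's uncertainty is lognormal and characterized by a single
dispersion factor k = (97.5th/2.5th percentile)^0.5, so the 95% CI is
[median/k, median×k].
"""

from __future__ import annotations

import math

import numpy as np

from .core_data import (
    Demographics,
    IDFactor,
    ImpactSummary,
    PollutantConcentration,
    ValidationError,
)
from .exposure import annual_residential_volume, population_adaf
from .uncertainty import Z95

__all__ = [
    "KG_PER_UG",
    "id_dalys_point",
    "k_from_percentiles",
    "lognormal_from_median_k",
    "sample_lognormal_median_k",
    "id_impact_samples",
]

#: Mass conversion applied once to the intake term (concentrations are µg/m³,
#: factors are DALY per kg inhaled).
KG_PER_UG = 1e-9


def id_dalys_point(c: float, v: float, factor: IDFactor, adaf: float = 1.0) -> float:
    """Deterministic DALYs per person per year for one pollutant.

    ``c`` in µg/m³, ``v`` in m³/yr; linear in both and in each factor.
    """
    if c < 0:
        raise ValidationError("negative concentration")
    if v <= 0:
        raise ValidationError("annual breathing volume must be positive")
    if adaf < 1.0:
        raise ValidationError("ADAF must be >= 1")
    intake_kg = c * KG_PER_UG * v
    return intake_kg * (factor.cancer_factor * adaf + factor.noncancer_factor)


def k_from_percentiles(p975: float, p025: float) -> float:
    """Lognormal dispersion factor k = (97.5th/2.5th percentile)^0.5."""
    if p025 <= 0 or p975 < p025:
        raise ValidationError("percentiles must be positive with p975 >= p025")
    return math.sqrt(p975 / p025)


def lognormal_from_median_k(median: float, k: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) of the lognormal with the given median and k.

    The fitted distribution has 2.5th percentile median/k and 97.5th
    percentile median×k; k = 1 degenerates to a point mass.
    """
    if median <= 0:
        raise ValidationError("median must be positive")
    if k < 1.0:
        raise ValidationError("k must be >= 1")
    return math.log(median), math.log(k) / Z95


def sample_lognormal_median_k(
    median: float, k: float, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Draw ``n`` lognormal samples parameterized by median and k."""
    mu, sigma = lognormal_from_median_k(median, k)
    if sigma == 0.0:
        return np.full(n, median, dtype=float)
    return np.exp(mu + sigma * rng.standard_normal(n))


def id_impact_samples(
    conc: PollutantConcentration,
    factor: IDFactor,
    demo: Demographics,
    *,
    n: int = 10_000,
    seed: int = 42,
    adaf_weighting: str = "population",
) -> ImpactSummary:
    """Monte Carlo burden of one pollutant via the intake-DALY track.

    Cancer and noncancer factors are drawn independently from their
    median/k lognormals; the per-person result is scaled by 1e5 to DALYs per
    100,000 persons per year (V and ADAF are already population-averaged).
    """
    if n < 1:
        raise ValidationError("need at least one sample")
    if factor.pollutant != conc.pollutant:
        raise ValidationError(
            f"factor for {factor.pollutant} passed with concentration for {conc.pollutant}"
        )
    v = annual_residential_volume(demo)
    adaf = population_adaf(demo, weighting=adaf_weighting)
    rng = np.random.default_rng(seed)

    if factor.cancer_factor > 0:
        cancer = sample_lognormal_median_k(factor.cancer_factor, factor.k_cancer, rng, n)
    else:
        cancer = np.zeros(n)
    if factor.noncancer_factor > 0:
        noncancer = sample_lognormal_median_k(
            factor.noncancer_factor, factor.k_noncancer, rng, n
        )
    else:
        noncancer = np.zeros(n)

    intake_kg = conc.mean_indoor * KG_PER_UG * v
    per_person = intake_kg * (cancer * adaf + noncancer)
    return ImpactSummary.from_samples(conc.pollutant, per_person * 1e5, seed=seed)
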