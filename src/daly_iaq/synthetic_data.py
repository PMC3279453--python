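"""Synthetic inputs for the toxicology track and for end-to-end validation.

The intake-DALY characterization factors used for noncriteria pollutants come
from an external toxicology database that is not redistributed here.  This
module generates synthetic stand-ins with the same structure — cancer and
noncancer DALY-per-kg factors spanning several orders of magnitude, each with
a lognormal dispersion factor k — so that every pipeline stage is exercisable
and testable.  Nothing generated here claims per-pollutant toxicological
realism.

It also builds parameter-recovery scenarios: sets of pollutants whose
analytic expected burdens follow a prescribed dominance profile, used to
check that the Monte Carlo aggregation and dominance statistics recover known
ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_data import (
    CREntry,
    Demographics,
    IDFactor,
    PollutantConcentration,
    ValidationError,
    load_demographics,
)
from .exposure import annual_residential_volume
from .id_model import KG_PER_UG
from .uncertainty import Z95

__all__ = [
    "SyntheticScenario",
    "generate_id_factors",
    "generate_recovery_scenario",
]

#: Default span of synthetic cancer/noncancer factors (log10 DALY per kg).
#: Chosen so that, with typical indoor concentrations, per-pollutant burdens
#: spread over roughly 10^-2 to 10^2 DALYs per 100,000 persons per year.
DEFAULT_MAGNITUDE_RANGE = (-4.0, 2.0)


@dataclass(frozen=True)
class SyntheticScenario:
    """A fully specified synthetic input set with known ground truth.

    ``true_total`` is the analytic expected total burden (DALYs/100k/yr)
    implied by the generated parameters; regeneration from the same
    parameters and seed is bit-identical.
    """

    concentrations: dict[str, PollutantConcentration]
    id_factors: dict[str, IDFactor]
    crfs: tuple[CREntry, ...]
    true_total: float
    true_shares: tuple[float, ...]
    seed: int
    demographics: Demographics = field(default_factory=load_demographics)

    def __post_init__(self) -> None:
        if self.true_total < 0:
            raise ValidationError("analytic total burden cannot be negative")


def generate_id_factors(
    pollutants: Sequence[str],
    *,
    magnitude_range: tuple[float, float] = DEFAULT_MAGNITUDE_RANGE,
    k_range: tuple[float, float] = (1.5, 20.0),
    seed: int = 0,
) -> dict[str, IDFactor]:
    """Generate synthetic intake-DALY factors for a list of pollutants.

    Cancer and noncancer factors are drawn log-uniformly over
    ``magnitude_range`` (powers of ten of DALY/kg); dispersion factors k are
    drawn log-uniformly over ``k_range``.  Deterministic under ``seed``.
    """
    lo, hi = magnitude_range
    if hi < lo:
        raise ValidationError("magnitude range is inverted")
    k_lo, k_hi = k_range
    if k_lo < 1.0 or k_hi < k_lo:
        raise ValidationError("k range must satisfy 1 <= k_min <= k_max")
    rng = np.random.default_rng(seed)
    factors: dict[str, IDFactor] = {}
    for name in pollutants:
        c_mag, nc_mag = rng.uniform(lo, hi, size=2)
        if k_lo == k_hi:
            k_c = k_nc = k_lo
        else:
            k_c, k_nc = np.exp(rng.uniform(math.log(k_lo), math.log(k_hi), size=2))
        factors[name] = IDFactor(
            pollutant=name,
            cancer_factor=10.0**c_mag,
            noncancer_factor=10.0**nc_mag,
            k_cancer=float(k_c),
            k_noncancer=float(k_nc),
        )
    return factors


def generate_recovery_scenario(
    n_pollutants: int,
    dominance_profile: Sequence[float],
    seed: int = 0,
    *,
    k: float = 1.0,
    total_burden: float = 100.0,
    demo: Demographics | None = None,
) -> SyntheticScenario:
    """Build a scenario whose expected per-pollutant burdens follow a profile.

    ``dominance_profile`` assigns each pollutant's expected share of the
    total burden (must sum to 1 and have length ``n_pollutants``).  All
    pollutants get unit concentration and a noncancer-only factor whose
    lognormal *mean* burden equals share × ``total_burden`` DALYs/100k/yr
    (the median is divided by exp(σ²/2) to compensate for the lognormal
    mean/median offset), each with the same dispersion factor ``k``.
    """
    profile = np.asarray(dominance_profile, dtype=float)
    if profile.size != n_pollutants:
        raise ValidationError("profile length must equal n_pollutants")
    if np.any(profile < 0) or abs(profile.sum() - 1.0) > 1e-9:
        raise ValidationError("dominance profile must be nonnegative and sum to 1")
    if k < 1.0:
        raise ValidationError("k must be >= 1")
    if total_burden < 0:
        raise ValidationError("total burden must be nonnegative")
    demo = demo if demo is not None else load_demographics()
    v = annual_residential_volume(demo)

    sigma = math.log(k) / Z95
    mean_over_median = math.exp(0.5 * sigma**2)

    concentrations: dict[str, PollutantConcentration] = {}
    id_factors: dict[str, IDFactor] = {}
    for i, share in enumerate(profile):
        name = f"synthetic_{i}"
        concentrations[name] = PollutantConcentration(name, 1.0)
        # burden per 100k for unit concentration: 1e-9 kg/ug * v * factor * 1e5
        target_mean = share * total_burden
        median = target_mean / (KG_PER_UG * v * 1e5 * mean_over_median)
        id_factors[name] = IDFactor(
            pollutant=name,
            cancer_factor=0.0,
            noncancer_factor=median,
            k_cancer=1.0,
            k_noncancer=k,
        )
    return SyntheticScenario(
        concentrations=concentrations,
        id_factors=id_factors,
        crfs=(),
        true_total=float(total_burden),
        true_shares=tuple(float(s) for s in profile),
        seed=int(seed),
        demographics=demo,
    )
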