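"""Domain types and packaged input tables for residential indoor-air burden modelling.

The package estimates chronic health burden, in disability-adjusted life-years
(DALYs) lost per 100,000 persons per year, from inhalation of air pollutants in
U.S. residences.  This module holds the shared value types — uncertain
quantities, concentration-response (C-R) parameters, demographic bins,
toxicology-derived intake-DALY factors — and loaders for the machine-readable
copies of the published input tables shipped under ``daly_iaq/data``:

``concentrations``
    Population-average indoor concentrations (µg/m³) for 69 nonbiological
    pollutants.
``cr_functions``
    C-R slope β (with 95% CI), baseline annual prevalence y0, and DALYs lost
    per disease incidence for the criteria pollutants (PM2.5, ozone, NO2, SO2,
    CO).
``demographics``
    Three-bin residential occupancy table: population fraction, cancer
    age-dependent adjustment factor (ADAF), fraction of day at home, and air
    intake (m³/day).
``attributed_outcomes``
    Literature-attributed excess incidences for secondhand smoke (SHS), radon,
    and acute CO poisoning, with DALYs lost per case.
``stroke_strata``
    DALYs lost per nonfatal-stroke incidence split by number of complications.

Validation is strict: a hand-edited fixture that violates an invariant raises
``ValidationError`` at load time rather than propagating bad numbers downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "UncertainValue",
    "AgeGroup",
    "Demographics",
    "PollutantConcentration",
    "CRFunction",
    "DALYPerIncidence",
    "CREntry",
    "IDFactor",
    "AttributedOutcome",
    "ImpactSummary",
    "US_POPULATION",
    "CRITERIA_POLLUTANTS",
    "FIXTURE_TABLES",
    "load_fixture_table",
    "load_concentrations",
    "load_cr_functions",
    "load_demographics",
    "load_attributed_outcomes",
    "load_stroke_strata",
    "load_id_factors",
    "write_id_factors",
    "write_table",
]

logger = logging.getLogger(__name__)

#: Default U.S. population used to convert national counts to per-100,000 rates.
US_POPULATION: float = 3.0e8

#: Pollutants with human epidemiology supporting the intake-incidence-DALY track.
CRITERIA_POLLUTANTS: frozenset[str] = frozenset({"PM2.5", "Ozone", "NO2", "SO2", "CO"})


class ValidationError(ValueError):
    """Raised when a record violates a domain invariant."""


# ---------------------------------------------------------------------------
# Value types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UncertainValue:
    """A central estimate with an optional 95% confidence interval.

    ``distribution`` names the family used when the value is sampled:
    ``"lognormal"`` (DALY factors and asymmetric incidence CIs),
    ``"normal"`` (C-R slopes, truncated at zero when sampled), or
    ``"point"`` (no uncertainty).
    """

    central: float
    ci_low: float | None = None
    ci_high: float | None = None
    distribution: str = "point"

    def __post_init__(self) -> None:
        if self.distribution not in ("lognormal", "normal", "point"):
            raise ValidationError(f"unknown distribution tag {self.distribution!r}")
        if not math.isfinite(self.central):
            raise ValidationError("central value must be finite")
        has_ci = self.ci_low is not None or self.ci_high is not None
        if has_ci and (self.ci_low is None or self.ci_high is None):
            raise ValidationError("confidence interval needs both endpoints")
        if has_ci and self.ci_low > self.ci_high:
            raise ValidationError(
                f"inverted CI ({self.ci_low}, {self.ci_high}) for central {self.central}"
            )
        if self.distribution == "lognormal":
            bounds = (self.central,) if not has_ci else (self.central, self.ci_low, self.ci_high)
            if any(b <= 0 for b in bounds):
                raise ValidationError("lognormal values must be strictly positive")
        if has_ci and not (self.ci_low <= self.central <= self.ci_high):
            # Stored as printed; downstream samplers use the central as the
            # location parameter and record the inconsistency once.
            logger.warning(
                "central value %g lies outside its CI (%g, %g); stored as printed",
                self.central,
                self.ci_low,
                self.ci_high,
            )

    @property
    def has_ci(self) -> bool:
        return self.ci_low is not None and self.ci_high is not None

    @property
    def is_degenerate(self) -> bool:
        """True when sampling would return the central value with certainty."""
        return not self.has_ci or self.ci_low == self.ci_high

    @classmethod
    def point(cls, value: float) -> "UncertainValue":
        return cls(central=value, distribution="point")


@dataclass(frozen=True)
class AgeGroup:
    """One demographic bin of the residential occupancy table."""

    label: str
    population_fraction: float
    adaf: float
    time_at_home: float
    intake_rate: float  # m3/day

    def __post_init__(self) -> None:
        if not 0.0 <= self.population_fraction <= 1.0:
            raise ValidationError(f"{self.label}: population fraction outside [0,1]")
        if not 0.0 <= self.time_at_home <= 1.0:
            raise ValidationError(f"{self.label}: time at home outside [0,1]")
        if self.adaf < 1.0:
            raise ValidationError(f"{self.label}: ADAF must be >= 1")
        if self.intake_rate <= 0.0:
            raise ValidationError(f"{self.label}: intake rate must be positive")


@dataclass(frozen=True)
class Demographics:
    """Ordered collection of age groups; fractions must sum to 1 (±0.01)."""

    groups: tuple[AgeGroup, ...]

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValidationError("demographics table is empty")
        total = sum(g.population_fraction for g in self.groups)
        if abs(total - 1.0) > 0.01:
            raise ValidationError(f"population fractions sum to {total}, not 1")

    def __iter__(self):
        return iter(self.groups)

    def __len__(self) -> int:
        return len(self.groups)


@dataclass(frozen=True)
class PollutantConcentration:
    """Population-average indoor concentration of one pollutant (µg/m³)."""

    pollutant: str
    mean_indoor: float

    def __post_init__(self) -> None:
        if self.mean_indoor < 0:
            raise ValidationError(f"{self.pollutant}: negative concentration")


@dataclass(frozen=True)
class CRFunction:
    """Concentration-response parameters for one pollutant-outcome pair.

    ``beta`` is the slope on the exposure-concentration increment (per µg/m³,
    matching the concentration table's units); ``y0`` the baseline annual
    prevalence of the outcome.  ``form`` selects the exponential response or
    its first-order linearization (used where the published functional form is
    symptom-based and carries no baseline prevalence; ``y0`` is then ``None``).
    """

    pollutant: str
    outcome: str
    beta: UncertainValue
    y0: float | None
    form: str = "exponential"

    def __post_init__(self) -> None:
        if self.form not in ("exponential", "linearized"):
            raise ValidationError(f"unknown C-R form {self.form!r}")
        if self.beta.central < 0:
            raise ValidationError(f"{self.pollutant}/{self.outcome}: negative beta")
        if self.y0 is not None and not 0.0 <= self.y0 <= 1.0:
            raise ValidationError(f"{self.pollutant}/{self.outcome}: y0 outside [0,1]")


@dataclass(frozen=True)
class DALYPerIncidence:
    """DALYs lost per case of one disease outcome."""

    outcome: str
    value: UncertainValue

    def __post_init__(self) -> None:
        if self.value.central <= 0:
            raise ValidationError(f"{self.outcome}: DALY factor must be positive")


@dataclass(frozen=True)
class CREntry:
    """A C-R function paired with its DALY-per-incidence factor.

    ``daly`` is ``None`` for the nonfatal-stroke outcome, whose burden is
    computed from the complication strata instead of a single factor.
    """

    crf: CRFunction
    daly: DALYPerIncidence | None


@dataclass(frozen=True)
class IDFactor:
    """Toxicology-derived DALYs per kg of pollutant inhaled.

    Cancer and noncancer potencies carry separate lognormal uncertainty
    factors ``k`` = (97.5th/2.5th percentile)^0.5, so the 95% CI of each
    factor is [central/k, central*k].
    """

    pollutant: str
    cancer_factor: float  # DALY per kg inhaled
    noncancer_factor: float  # DALY per kg inhaled
    k_cancer: float = 1.0
    k_noncancer: float = 1.0

    def __post_init__(self) -> None:
        if self.cancer_factor < 0 or self.noncancer_factor < 0:
            raise ValidationError(f"{self.pollutant}: negative DALY factor")
        if self.k_cancer < 1.0 or self.k_noncancer < 1.0:
            raise ValidationError(f"{self.pollutant}: uncertainty factor k must be >= 1")


@dataclass(frozen=True)
class AttributedOutcome:
    """Literature-attributed excess incidence of one outcome for one hazard.

    ``rate_basis`` is ``national_count`` (cases/year for the whole U.S.,
    converted to per-100k with the population constant) or
    ``per_million_rate`` (deaths per million persons per year, rescaled
    directly).
    """

    hazard: str
    outcome: str
    excess_incidence: UncertainValue
    dalys_per_incidence: UncertainValue
    rate_basis: str = "national_count"

    def __post_init__(self) -> None:
        if self.rate_basis not in ("national_count", "per_million_rate"):
            raise ValidationError(f"unknown rate basis {self.rate_basis!r}")
        if self.excess_incidence.central < 0:
            raise ValidationError(f"{self.hazard}/{self.outcome}: negative incidence")


@dataclass(frozen=True)
class ImpactSummary:
    """Monte Carlo result for one pollutant or hazard.

    ``samples`` holds DALYs lost per 100,000 persons per year; ``median`` and
    the CI bounds are the 50th, 2.5th and 97.5th empirical percentiles.
    """

    pollutant_or_hazard: str
    samples: np.ndarray
    median: float
    ci_low: float
    ci_high: float
    n_samples: int
    seed: int
    notes: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.samples.size != self.n_samples:
            raise ValidationError("n_samples does not match sample vector length")
        if np.any(self.samples < 0):
            raise ValidationError("negative DALY samples")
        if not self.ci_low <= self.median <= self.ci_high:
            raise ValidationError("summary percentiles out of order")

    @classmethod
    def from_samples(
        cls,
        name: str,
        samples: np.ndarray,
        seed: int,
        notes: Iterable[str] = (),
    ) -> "ImpactSummary":
        samples = np.asarray(samples, dtype=float)
        median, lo, hi = (
            float(np.percentile(samples, q)) for q in (50.0, 2.5, 97.5)
        )
        return cls(
            pollutant_or_hazard=name,
            samples=samples,
            median=median,
            ci_low=lo,
            ci_high=hi,
            n_samples=int(samples.size),
            seed=int(seed),
            notes=tuple(notes),
        )

    def scaled(self, factor: float) -> "ImpactSummary":
        """Return a copy with every sample (hence every percentile) scaled."""
        if factor < 0:
            raise ValidationError("scale factor must be nonnegative")
        return ImpactSummary.from_samples(
            self.pollutant_or_hazard, self.samples * factor, self.seed, self.notes
        )


# ---------------------------------------------------------------------------
# Fixture IO
# ---------------------------------------------------------------------------

FIXTURE_TABLES = (
    "concentrations",
    "cr_functions",
    "demographics",
    "attributed_outcomes",
    "stroke_strata",
)


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("daly_iaq").joinpath("data", f"{name}.csv")))


def _read_csv(source: str | Path) -> pd.DataFrame:
    return pd.read_csv(source, dtype={0: str})


def _opt(value) -> float | None:
    return None if pd.isna(value) else float(value)


def _uncertain(central, lo, hi, distribution_with_ci: str) -> UncertainValue:
    """Build an UncertainValue, degrading to a point when the CI is absent."""
    lo, hi = _opt(lo), _opt(hi)
    if lo is None and hi is None:
        return UncertainValue(central=float(central), distribution="point")
    return UncertainValue(
        central=float(central), ci_low=lo, ci_high=hi, distribution=distribution_with_ci
    )


def load_concentrations(source: str | Path | None = None) -> dict[str, PollutantConcentration]:
    """Load the indoor-concentration table, keyed by pollutant name."""
    df = _read_csv(source or _fixture_path("concentrations"))
    records = {}
    for row in df.itertuples(index=False):
        rec = PollutantConcentration(
            pollutant=str(row.pollutant), mean_indoor=float(row.concentration_ug_m3)
        )
        if rec.pollutant in records:
            raise ValidationError(f"duplicate pollutant {rec.pollutant!r}")
        records[rec.pollutant] = rec
    return records


def load_demographics(source: str | Path | None = None) -> Demographics:
    df = _read_csv(source or _fixture_path("demographics"))
    groups = tuple(
        AgeGroup(
            label=str(row.label),
            population_fraction=float(row.population_fraction),
            adaf=float(row.adaf),
            time_at_home=float(row.time_at_home),
            intake_rate=float(row.intake_m3_day),
        )
        for row in df.itertuples(index=False)
    )
    return Demographics(groups=groups)


def load_cr_functions(source: str | Path | None = None) -> list[CREntry]:
    df = _read_csv(source or _fixture_path("cr_functions"))
    entries = []
    for row in df.itertuples(index=False):
        crf = CRFunction(
            pollutant=str(row.pollutant),
            outcome=str(row.outcome),
            beta=UncertainValue(
                central=float(row.beta),
                ci_low=float(row.beta_lo),
                ci_high=float(row.beta_hi),
                distribution="normal",
            ),
            y0=_opt(row.y0),
            form=str(row.form),
        )
        daly = None
        if _opt(row.daly) is not None:
            daly = DALYPerIncidence(
                outcome=crf.outcome,
                value=_uncertain(row.daly, row.daly_lo, row.daly_hi, "lognormal"),
            )
        entries.append(CREntry(crf=crf, daly=daly))
    return entries


def load_stroke_strata(source: str | Path | None = None) -> list[DALYPerIncidence]:
    df = _read_csv(source or _fixture_path("stroke_strata"))
    return [
        DALYPerIncidence(
            outcome=str(row.stratum),
            value=_uncertain(row.daly, row.daly_lo, row.daly_hi, "lognormal"),
        )
        for row in df.itertuples(index=False)
    ]


def load_attributed_outcomes(source: str | Path | None = None) -> list[AttributedOutcome]:
    df = _read_csv(source or _fixture_path("attributed_outcomes"))
    return [
        AttributedOutcome(
            hazard=str(row.hazard),
            outcome=str(row.outcome),
            excess_incidence=_uncertain(
                row.incidence, row.incidence_lo, row.incidence_hi, "lognormal"
            ),
            dalys_per_incidence=_uncertain(
                row.daly_per_case, row.daly_lo, row.daly_hi, "lognormal"
            ),
            rate_basis=str(row.rate_basis),
        )
        for row in df.itertuples(index=False)
    ]


def load_id_factors(source: str | Path) -> dict[str, IDFactor]:
    """Load intake-DALY factors from CSV (no packaged fixture: the published
    factor database is external; see :mod:`daly_iaq.synthetic_data`)."""
    df = _read_csv(source)
    factors = {}
    for row in df.itertuples(index=False):
        rec = IDFactor(
            pollutant=str(row.pollutant),
            cancer_factor=float(row.cancer_daly_per_kg),
            noncancer_factor=float(row.noncancer_daly_per_kg),
            k_cancer=float(row.k_cancer),
            k_noncancer=float(row.k_noncancer),
        )
        factors[rec.pollutant] = rec
    return factors


def write_id_factors(factors: Mapping[str, IDFactor], path: str | Path) -> None:
    pd.DataFrame(
        {
            "pollutant": [f.pollutant for f in factors.values()],
            "cancer_daly_per_kg": [f.cancer_factor for f in factors.values()],
            "k_cancer": [f.k_cancer for f in factors.values()],
            "noncancer_daly_per_kg": [f.noncancer_factor for f in factors.values()],
            "k_noncancer": [f.k_noncancer for f in factors.values()],
        }
    ).to_csv(path, index=False)


_LOADERS = {
    "concentrations": load_concentrations,
    "cr_functions": load_cr_functions,
    "demographics": load_demographics,
    "attributed_outcomes": load_attributed_outcomes,
    "stroke_strata": load_stroke_strata,
}


def load_fixture_table(name: str, source: str | Path | None = None):
    """Load one of the packaged input tables by name.

    ``name`` must be one of :data:`FIXTURE_TABLES`; passing ``source`` reads a
    user-supplied CSV with the same schema instead of the packaged copy.
    """
    try:
        loader = _LOADERS[name]
    except KeyError:
        raise KeyError(f"unknown table {name!r}; expected one of {FIXTURE_TABLES}") from None
    return loader(source)


# ---------------------------------------------------------------------------
# Writers (schema-preserving round trip)
# ---------------------------------------------------------------------------


def _frame_concentrations(records: Mapping[str, PollutantConcentration]) -> pd.DataFrame:
    return pd.DataFrame(
        {"pollutant": list(records), "concentration_ug_m3": [r.mean_indoor for r in records.values()]}
    )


def _frame_demographics(demo: Demographics) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label": [g.label for g in demo],
            "population_fraction": [g.population_fraction for g in demo],
            "adaf": [g.adaf for g in demo],
            "time_at_home": [g.time_at_home for g in demo],
            "intake_m3_day": [g.intake_rate for g in demo],
        }
    )


def _frame_cr(entries: Sequence[CREntry]) -> pd.DataFrame:
    rows = []
    for e in entries:
        d = e.daly.value if e.daly is not None else None
        rows.append(
            {
                "pollutant": e.crf.pollutant,
                "outcome": e.crf.outcome,
                "beta": e.crf.beta.central,
                "beta_lo": e.crf.beta.ci_low,
                "beta_hi": e.crf.beta.ci_high,
                "y0": e.crf.y0,
                "form": e.crf.form,
                "daly": d.central if d else None,
                "daly_lo": d.ci_low if d else None,
                "daly_hi": d.ci_high if d else None,
            }
        )
    return pd.DataFrame(rows)


def _frame_strata(strata: Sequence[DALYPerIncidence]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "stratum": [s.outcome for s in strata],
            "daly": [s.value.central for s in strata],
            "daly_lo": [s.value.ci_low for s in strata],
            "daly_hi": [s.value.ci_high for s in strata],
        }
    )


def _frame_attributed(records: Sequence[AttributedOutcome]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "hazard": [r.hazard for r in records],
            "outcome": [r.outcome for r in records],
            "incidence": [r.excess_incidence.central for r in records],
            "incidence_lo": [r.excess_incidence.ci_low for r in records],
            "incidence_hi": [r.excess_incidence.ci_high for r in records],
            "daly_per_case": [r.dalys_per_incidence.central for r in records],
            "daly_lo": [r.dalys_per_incidence.ci_low for r in records],
            "daly_hi": [r.dalys_per_incidence.ci_high for r in records],
            "rate_basis": [r.rate_basis for r in records],
        }
    )


_FRAMERS = {
    "concentrations": _frame_concentrations,
    "cr_functions": _frame_cr,
    "demographics": _frame_demographics,
    "attributed_outcomes": _frame_attributed,
    "stroke_strata": _frame_strata,
}


def write_table(name: str, records, path: str | Path) -> None:
    """Write records back to CSV in the fixture schema (lossless round trip)."""
    try:
        framer = _FRAMERS[name]
    except KeyError:
        raise KeyError(f"unknown table {name!r}; expected one of {FIXTURE_TABLES}") from None
    framer(records).to_csv(path, index=False)
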