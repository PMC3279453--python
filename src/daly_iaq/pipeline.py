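"""End-to-end orchestration and report writing.

``run_full_pipeline`` wires the modules together: the occupancy-adjusted
exposure increment feeds the epidemiology track for criteria pollutants and
the toxicology track for everything else, per-pollutant Monte Carlo streams
are aggregated into a joint total with a dominance decomposition, and the
result is compared against independent literature totals as a plausibility
check.  Ozone is the one pollutant eligible for both tracks; the
epidemiology result enters the total (smaller interspecies uncertainty) and
the toxicology result is reported alongside for comparison.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import synthetic_data
from .core_data import (
    CRITERIA_POLLUTANTS,
    ImpactSummary,
    US_POPULATION,
    ValidationError,
    load_cr_functions,
    load_concentrations,
    load_demographics,
    load_id_factors,
)
from .id_model import id_impact_samples
from .ind_model import ind_impact_samples
from .uncertainty import AggregateResult, aggregate, dominant_share, spawn_seeds

__all__ = ["RunConfig", "ReferenceConstants", "REFERENCES", "run_full_pipeline", "write_report"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReferenceConstants:
    """Independent population-wide burden totals used as plausibility anchors
    (DALYs per 100,000 persons per year)."""

    who_total: float = 7_700.0  # all noncommunicable, nonpsychiatric U.S. disease
    mckenna_iaq_linked: float = 3_000.0  # top-20 diseases with an indoor-air connection
    ezzati_tobacco: float = 1_700.0  # first- plus secondhand tobacco smoke


REFERENCES = ReferenceConstants()


@dataclass
class RunConfig:
    """Configuration for a pipeline run; flat JSON-serializable key scheme."""

    population: float = US_POPULATION
    samples: int = 10_000
    seed: int = 42
    occupancy_override: float | None = None
    concentrations_path: str | None = None
    cr_functions_path: str | None = None
    demographics_path: str | None = None
    id_factors_path: str | None = None
    out_dir: str | None = None
    dominance_subset: tuple[str, ...] = ("PM2.5", "Acrolein", "Formaldehyde")
    dominance_share_threshold: float = 0.8

    def __post_init__(self) -> None:
        if self.samples < 1:
            raise ValidationError("samples must be >= 1")
        if self.population <= 0:
            raise ValidationError("population must be positive")

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class PipelineResult:
    """Aggregate burden plus per-track bookkeeping."""

    aggregate: AggregateResult
    ozone_id: ImpactSummary | None
    subset_share: float
    config: RunConfig
    input_checksums: dict[str, str]


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_full_pipeline(config: RunConfig) -> PipelineResult:
    """Run both burden tracks over the full pollutant table and aggregate.

    Criteria pollutants with concentration-response entries run through the
    epidemiology track; all other pollutants need an intake-DALY factor
    (user CSV via ``id_factors_path``, else synthetic stand-ins generated
    from the run seed).  A non-ozone pollutant appearing in both tracks is
    counted once (epidemiology) and logged as a warning.
    """
    concentrations = load_concentrations(config.concentrations_path)
    cr_entries = load_cr_functions(config.cr_functions_path)
    demo = load_demographics(config.demographics_path)

    checksums = {}
    for label, path in (
        ("concentrations", config.concentrations_path),
        ("cr_functions", config.cr_functions_path),
        ("demographics", config.demographics_path),
        ("id_factors", config.id_factors_path),
    ):
        if path is not None:
            checksums[label] = _checksum(path)

    ind_pollutants = sorted({e.crf.pollutant for e in cr_entries} & set(concentrations))
    id_pollutants = sorted(set(concentrations) - set(ind_pollutants))
    # ozone runs through both tracks; other overlaps would double count
    for p in set(ind_pollutants) - CRITERIA_POLLUTANTS:
        logger.warning("pollutant %s in both tracks; counting epidemiology track only", p)

    if config.id_factors_path is not None:
        id_factors = load_id_factors(config.id_factors_path)
    else:
        id_factors = synthetic_data.generate_id_factors(
            id_pollutants + ["Ozone"], seed=config.seed
        )
        logger.info("no intake-DALY factor table supplied; using synthetic stand-ins")

    missing = [p for p in id_pollutants if p not in id_factors]
    if missing:
        raise ValidationError(f"no intake-DALY factors for: {missing[:5]}...")

    names = ind_pollutants + id_pollutants
    seeds = spawn_seeds(config.seed, len(names) + 1)
    summaries: list[ImpactSummary] = []
    for name, child_seed in zip(ind_pollutants, seeds):
        entries = [e for e in cr_entries if e.crf.pollutant == name]
        summaries.append(
            ind_impact_samples(
                concentrations[name],
                entries,
                demo,
                population=config.population,
                n=config.samples,
                seed=child_seed,
                occupancy=config.occupancy_override,
            )
        )
    for name, child_seed in zip(id_pollutants, seeds[len(ind_pollutants) : -1]):
        summaries.append(
            id_impact_samples(
                concentrations[name], id_factors[name], demo, n=config.samples, seed=child_seed
            )
        )

    ozone_id = None
    if "Ozone" in concentrations and "Ozone" in id_factors:
        ozone_id = id_impact_samples(
            concentrations["Ozone"], id_factors["Ozone"], demo,
            n=config.samples, seed=seeds[-1],
        )
        ozone_id = ImpactSummary.from_samples(
            "Ozone (intake-DALY track)", ozone_id.samples, ozone_id.seed,
            notes=("comparison only; epidemiology-track ozone enters the total",),
        )

    agg = aggregate(summaries, seed=config.seed)
    subset = [p for p in config.dominance_subset if p in names]
    subset_share = (
        dominant_share(summaries, subset, config.dominance_share_threshold) if subset else 0.0
    )
    return PipelineResult(
        aggregate=agg,
        ozone_id=ozone_id,
        subset_share=subset_share,
        config=config,
        input_checksums=checksums,
    )


def write_report(
    result: PipelineResult,
    out_dir: str | Path,
    refs: ReferenceConstants = REFERENCES,
) -> dict[str, Path]:
    """Write the per-pollutant CSV (ranked by median burden) and a JSON report.

    The JSON carries full provenance (config echo, seed, sample count, input
    checksums), the dominance table, ratios of the estimated total to the
    independent literature totals, and a plausibility flag raised when the
    upper CI bound of the total exceeds the all-disease reference.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    agg = result.aggregate

    ranked = sorted(agg.per_pollutant, key=lambda s: s.median, reverse=True)
    csv_path = out_dir / "per_pollutant.csv"
    pd.DataFrame(
        {
            "pollutant": [s.pollutant_or_hazard for s in ranked],
            "median_daly_per_100k_yr": [s.median for s in ranked],
            "ci_low": [s.ci_low for s in ranked],
            "ci_high": [s.ci_high for s in ranked],
        }
    ).to_csv(csv_path, index=False)

    total = agg.total
    report = {
        "units": "DALY/100k/yr",
        "config": result.config.to_dict(),
        "n_samples": total.n_samples,
        "seed": result.config.seed,
        "input_checksums": result.input_checksums,
        "total": {"median": total.median, "ci_low": total.ci_low, "ci_high": total.ci_high},
        "dominance": agg.dominance,
        "subset_share": {
            "subset": list(result.config.dominance_subset),
            "share_threshold": result.config.dominance_share_threshold,
            "fraction_of_samples": result.subset_share,
        },
        "ozone_intake_daly_track": (
            None
            if result.ozone_id is None
            else {
                "median": result.ozone_id.median,
                "ci_low": result.ozone_id.ci_low,
                "ci_high": result.ozone_id.ci_high,
            }
        ),
        "reference_comparison": {
            "who_all_noncommunicable": refs.who_total,
            "iaq_linked_top20": refs.mckenna_iaq_linked,
            "tobacco_total": refs.ezzati_tobacco,
            "total_over_who": total.median / refs.who_total,
            "total_over_iaq_linked": total.median / refs.mckenna_iaq_linked,
            "upper_ci_implausible": bool(total.ci_high > refs.who_total),
        },
    }
    json_path = out_dir / "report.json"
    json_path.write_text(json.dumps(report, indent=2))
    return {"csv": csv_path, "json": json_path}
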