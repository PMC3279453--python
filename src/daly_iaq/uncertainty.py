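"""Shared Monte Carlo engine: distribution fitting, sampling, aggregation.

Uncertain inputs are published as a central estimate with a 95% CI.  Slope
coefficients are sampled from a normal distribution fitted to the CI and
truncated at zero; DALY factors and incidence counts are sampled from a
lognormal with the printed central value as the median and the log-scale
standard deviation fitted to the CI half-width.  Aggregation across
pollutants works on aligned sample vectors (one independent stream per
pollutant, all spawned from one seed), so the total burden distribution and
the dominance decomposition — which pollutant is the largest contributor in
each Monte Carlo draw — come from the same joint sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_data import ImpactSummary, UncertainValue, ValidationError

__all__ = [
    "Z95",
    "sigma_ln_from_ci",
    "sample_uncertain",
    "summarize",
    "AggregateResult",
    "aggregate",
    "dominant_share",
    "spawn_seeds",
]

#: Two-sided 95% normal quantile used throughout to map CIs to scale parameters.
Z95 = 1.959963984540054


def sigma_ln_from_ci(ci_low: float, ci_high: float) -> float:
    """Log-scale standard deviation of a lognormal with the given 95% CI ratio."""
    if ci_low <= 0 or ci_high < ci_low:
        raise ValidationError("lognormal CI endpoints must be positive and ordered")
    return math.log(ci_high / ci_low) / (2.0 * Z95)


def sample_uncertain(uv: UncertainValue, rng: np.random.Generator, n: int) -> np.ndarray:
    """Draw ``n`` samples from the distribution encoded by an UncertainValue.

    - ``point`` or a degenerate CI: the central value, repeated.
    - ``normal``: mean = central, σ = CI width / (2·1.96), truncated at 0.
    - ``lognormal``: median = central, σ_ln = ln(hi/lo) / (2·1.96).
    """
    if n < 1:
        raise ValidationError("need at least one sample")
    if uv.is_degenerate or uv.distribution == "point":
        return np.full(n, uv.central, dtype=float)
    if uv.distribution == "normal":
        sigma = (uv.ci_high - uv.ci_low) / (2.0 * Z95)
        a = (0.0 - uv.central) / sigma  # truncate at zero: slopes are nonnegative
        return stats.truncnorm.rvs(
            a, np.inf, loc=uv.central, scale=sigma, size=n, random_state=rng
        )
    if uv.distribution == "lognormal":
        sigma = sigma_ln_from_ci(uv.ci_low, uv.ci_high)
        return uv.central * np.exp(sigma * rng.standard_normal(n))
    raise ValidationError(f"cannot sample distribution {uv.distribution!r}")


def summarize(samples: np.ndarray) -> tuple[float, float, float]:
    """Empirical (median, 2.5th, 97.5th) percentiles with linear interpolation."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValidationError("cannot summarize an empty sample vector")
    median, lo, hi = np.percentile(samples, [50.0, 2.5, 97.5])
    return float(median), float(lo), float(hi)


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1, dtype=np.uint32)[0] % (2**31)) for s in ss.spawn(n)]


@dataclass(frozen=True)
class AggregateResult:
    """Joint Monte Carlo result across pollutants.

    ``dominance`` maps each pollutant to the fraction of samples in which it
    is the single largest contributor (ties broken by input order);
    ``topk_share`` optionally records, for a named subset, the fraction of
    samples in which the subset exceeds a threshold share of the total.
    """

    total: ImpactSummary
    per_pollutant: tuple[ImpactSummary, ...]
    dominance: dict[str, float]
    topk_share: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {s.n_samples for s in self.per_pollutant}
        if len(lengths) > 1:
            raise ValidationError("misaligned sample vectors")
        if sum(self.dominance.values()) > 1.0 + 1e-9:
            raise ValidationError("dominance fractions exceed 1")


def aggregate(per_pollutant: list[ImpactSummary], seed: int = 0) -> AggregateResult:
    """Element-wise total and dominance decomposition of aligned summaries."""
    if not per_pollutant:
        raise ValidationError("nothing to aggregate")
    lengths = {s.n_samples for s in per_pollutant}
    if len(lengths) > 1:
        raise ValidationError(f"misaligned sample vectors: lengths {sorted(lengths)}")
    matrix = np.vstack([s.samples for s in per_pollutant])  # pollutants x samples
    totals = matrix.sum(axis=0)
    # argmax returns the first maximal row: ties go to the first-listed pollutant
    winners = np.argmax(matrix, axis=0)
    n = matrix.shape[1]
    dominance = {
        s.pollutant_or_hazard: float(np.count_nonzero(winners == i)) / n
        for i, s in enumerate(per_pollutant)
    }
    total = ImpactSummary.from_samples("total", totals, seed=seed)
    return AggregateResult(
        total=total, per_pollutant=tuple(per_pollutant), dominance=dominance
    )


def dominant_share(
    per_pollutant: list[ImpactSummary],
    subset: list[str],
    share_threshold: float,
) -> float:
    """Fraction of samples in which ``subset`` contributes more than
    ``share_threshold`` of the total burden."""
    if not subset:
        raise ValidationError("subset must be nonempty")
    if not 0.0 < share_threshold <= 1.0:
        raise ValidationError("share threshold must lie in (0,1]")
    names = [s.pollutant_or_hazard for s in per_pollutant]
    unknown = set(subset) - set(names)
    if unknown:
        raise ValidationError(f"unknown pollutants in subset: {sorted(unknown)}")
    matrix = np.vstack([s.samples for s in per_pollutant])
    totals = matrix.sum(axis=0)
    idx = [names.index(p) for p in subset]
    subset_sum = matrix[idx].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(totals > 0, subset_sum / totals, 0.0)
    return float(np.count_nonzero(share > share_threshold)) / totals.size
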