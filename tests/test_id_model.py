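"""Toxicology (intake-DALY) track."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from daly_iaq.core_data import IDFactor, PollutantConcentration, ValidationError
from daly_iaq.id_model import (
    id_dalys_point,
    id_impact_samples,
    k_from_percentiles,
    lognormal_from_median_k,
    sample_lognormal_median_k,
)
from daly_iaq.ind_model import ind_impact_samples
from daly_iaq.exposure import annual_residential_volume, population_adaf


class TestPointValue:
    def test_unit_conversion(self):
        factor = IDFactor("x", cancer_factor=0.0, noncancer_factor=1.0)
        # 1 ug/m3 * 3680 m3/yr = 3.68 mg = 3.68e-6 kg inhaled
        assert id_dalys_point(1.0, 3680.0, factor) == pytest.approx(3.68e-6)

    def test_zero_concentration(self):
        factor = IDFactor("x", 5.0, 3.0, 2.0, 2.0)
        assert id_dalys_point(0.0, 3680.0, factor, adaf=1.65) == 0.0

    def test_adaf_scales_only_cancer_term(self):
        cancer_only = IDFactor("x", cancer_factor=1.0, noncancer_factor=0.0)
        base = id_dalys_point(1.0, 1000.0, cancer_only, adaf=1.0)
        assert id_dalys_point(1.0, 1000.0, cancer_only, adaf=1.65) == pytest.approx(
            1.65 * base
        )
        noncancer_only = IDFactor("x", cancer_factor=0.0, noncancer_factor=1.0)
        nc = id_dalys_point(1.0, 1000.0, noncancer_only, adaf=1.0)
        assert id_dalys_point(1.0, 1000.0, noncancer_only, adaf=1.65) == pytest.approx(nc)

    @given(scale=st.floats(0.1, 10.0))
    def test_linear_in_concentration_and_volume(self, scale):
        factor = IDFactor("x", 2.0, 3.0)
        base = id_dalys_point(1.0, 1000.0, factor)
        assert id_dalys_point(scale, 1000.0, factor) == pytest.approx(scale * base)
        assert id_dalys_point(1.0, scale * 1000.0, factor) == pytest.approx(scale * base)

    def test_invalid_inputs_rejected(self):
        factor = IDFactor("x", 1.0, 1.0)
        with pytest.raises(ValidationError):
            id_dalys_point(-1.0, 1000.0, factor)
        with pytest.raises(ValidationError):
            id_dalys_point(1.0, 0.0, factor)
        with pytest.raises(ValidationError):
            id_dalys_point(1.0, 1000.0, factor, adaf=0.5)


class TestDispersionFactor:
    def test_reference_value_from_radon_interval(self):
        assert k_from_percentiles(58_000, 5_600) == pytest.approx(3.218, abs=0.005)

    def test_equal_percentiles_give_unit_k(self):
        assert k_from_percentiles(7.0, 7.0) == 1.0

    def test_square_root_of_ratio(self):
        assert k_from_percentiles(100.0, 1.0) == pytest.approx(10.0)

    def test_invalid_percentiles_rejected(self):
        with pytest.raises(ValidationError):
            k_from_percentiles(1.0, 2.0)
        with pytest.raises(ValidationError):
            k_from_percentiles(1.0, 0.0)

    def test_unit_k_is_degenerate(self):
        mu, sigma = lognormal_from_median_k(10.0, 1.0)
        assert sigma == 0.0 and math.exp(mu) == pytest.approx(10.0)

    def test_fitted_distribution_hits_percentiles(self):
        mu, sigma = lognormal_from_median_k(10.0, 10.0)
        dist = stats.lognorm(s=sigma, scale=math.exp(mu))
        assert dist.ppf(0.025) == pytest.approx(1.0, rel=1e-9)
        assert dist.ppf(0.975) == pytest.approx(100.0, rel=1e-9)

    @given(median=st.floats(0.01, 1e4), k=st.floats(1.001, 50.0))
    def test_round_trip_k(self, median, k):
        mu, sigma = lognormal_from_median_k(median, k)
        dist = stats.lognorm(s=sigma, scale=math.exp(mu))
        assert k_from_percentiles(dist.ppf(0.975), dist.ppf(0.025)) == pytest.approx(
            k, rel=1e-9
        )


class TestIdImpactSamples:
    def test_degenerate_k_gives_point_mass(self, demographics):
        conc = PollutantConcentration("x", 5.0)
        factor = IDFactor("x", cancer_factor=2.0, noncancer_factor=1.0)
        s = id_impact_samples(conc, factor, demographics, n=50, seed=0)
        v = annual_residential_volume(demographics)
        adaf = population_adaf(demographics)
        expected = 5.0 * 1e-9 * v * (2.0 * adaf + 1.0) * 1e5
        assert np.all(s.samples == s.samples[0])
        assert s.median == pytest.approx(expected, rel=1e-12)

    def test_reproducible_under_seed(self, demographics):
        conc = PollutantConcentration("x", 5.0)
        factor = IDFactor("x", 2.0, 1.0, 5.0, 3.0)
        a = id_impact_samples(conc, factor, demographics, n=1000, seed=9)
        b = id_impact_samples(conc, factor, demographics, n=1000, seed=9)
        assert np.array_equal(a.samples, b.samples)

    def test_sample_median_matches_analytic_median(self, demographics):
        # single lognormal factor: the analytic median of the burden is the
        # point value at the median factor
        conc = PollutantConcentration("x", 5.0)
        factor = IDFactor("x", 0.0, 2.0, 1.0, 8.0)
        n = 40_000
        s = id_impact_samples(conc, factor, demographics, n=n, seed=13)
        v = annual_residential_volume(demographics)
        analytic = 5.0 * 1e-9 * v * 2.0 * 1e5
        sigma = math.log(8.0) / 1.959963984540054
        # standard error of a lognormal sample median
        se = analytic * 1.2533 * sigma / math.sqrt(n)
        assert abs(s.median - analytic) < 3 * se

    def test_median_of_sum_bracketed_by_scaled_medians(self, demographics):
        # comparable cancer and noncancer factors: the median burden lies
        # between the point value at medians/k and at medians*k
        conc = PollutantConcentration("x", 1.0)
        factor = IDFactor("x", 3.0, 2.0, 4.0, 4.0)
        s = id_impact_samples(conc, factor, demographics, n=20_000, seed=21)
        v = annual_residential_volume(demographics)
        adaf = population_adaf(demographics)
        lower = 1e-9 * v * (3.0 / 4.0 * adaf + 2.0 / 4.0) * 1e5
        upper = 1e-9 * v * (3.0 * 4.0 * adaf + 2.0 * 4.0) * 1e5
        assert lower < s.median < upper

    def test_ozone_dual_track_intervals_overlap(
        self, demographics, concentrations, cr_entries
    ):
        """Ozone run through both tracks yields overlapping 95% CIs.

        The toxicology factor here is a synthetic stand-in calibrated to the
        reported scale of the intake-DALY ozone estimate (median 2.3,
        CI 0.2-26 => k ~ 11.4)."""
        entries = [e for e in cr_entries if e.crf.pollutant == "Ozone"]
        ind = ind_impact_samples(
            concentrations["Ozone"], entries, demographics, n=5000, seed=2
        )
        v = annual_residential_volume(demographics)
        median_factor = 2.3 / (17.2 * 1e-9 * v * 1e5)
        factor = IDFactor("Ozone", 0.0, median_factor, 1.0, k_from_percentiles(26, 0.2))
        idr = id_impact_samples(concentrations["Ozone"], factor, demographics, n=5000, seed=2)
        assert max(ind.ci_low, idr.ci_low) < min(ind.ci_high, idr.ci_high)
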