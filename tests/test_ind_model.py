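"""Epidemiology (intake-incidence-DALY) track."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from daly_iaq.core_data import (
    CREntry,
    CRFunction,
    DALYPerIncidence,
    PollutantConcentration,
    UncertainValue,
    ValidationError,
)
from daly_iaq.ind_model import (
    cr_incidence,
    cr_incidence_linearized,
    ind_impact_samples,
    split_stroke,
)


def make_crf(pollutant="X", outcome="o", beta=0.005, y0=7.4e-3, form="exponential"):
    return CRFunction(
        pollutant=pollutant,
        outcome=outcome,
        beta=UncertainValue(beta, beta, beta, "normal"),
        y0=y0,
        form=form,
    )


class TestCRIncidence:
    def test_exponential_reference_value(self):
        # direct evaluation: -y0 (e^{-b dC} - 1) pop
        crf = make_crf(y0=7.4e-3)
        assert cr_incidence(crf, 0.0058, 11.13, 1e5) == pytest.approx(46.26, abs=0.05)

    def test_zero_increment_zero_incidence(self):
        assert cr_incidence(make_crf(), 0.01, 0.0, 1e6) == 0.0

    def test_saturates_at_baseline_prevalence(self):
        crf = make_crf(y0=7.4e-3)
        assert cr_incidence(crf, 10.0, 1e6, 1e5) == pytest.approx(7.4e-3 * 1e5)

    def test_linearized_reference_value(self):
        crf = make_crf(y0=9.5e-3)
        assert cr_incidence_linearized(crf, 0.004, 9.17, 1e5) == pytest.approx(34.85, abs=0.05)

    def test_linearized_zero_increment(self):
        assert cr_incidence_linearized(make_crf(), 0.004, 0.0, 1e5) == 0.0

    def test_small_signal_agreement_with_series_expansion(self):
        # for b*dC -> 0, 1 - e^{-x} = x - x^2/2 + ...; the two forms agree
        crf = make_crf(y0=5e-3)
        beta, delta_c = 1e-3, 1e-3  # x = 1e-6
        exp_form = cr_incidence(crf, beta, delta_c, 1e6)
        lin_form = cr_incidence_linearized(crf, beta, delta_c, 1e6)
        assert abs(exp_form - lin_form) / lin_form < 1e-6

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValidationError):
            cr_incidence(make_crf(), -0.01, 1.0, 1e5)
        with pytest.raises(ValidationError):
            cr_incidence(make_crf(), 0.01, -1.0, 1e5)
        with pytest.raises(ValidationError):
            cr_incidence(make_crf(), 0.01, 1.0, 0.0)

    @given(
        beta=st.floats(0.0, 0.2),
        dc1=st.floats(0.0, 50.0),
        dc2=st.floats(0.0, 50.0),
    )
    def test_monotone_in_concentration_and_bounded_by_linear(self, beta, dc1, dc2):
        crf = make_crf(y0=1e-2)
        lo, hi = sorted((dc1, dc2))
        assert cr_incidence(crf, beta, lo, 1e5) <= cr_incidence(crf, beta, hi, 1e5) + 1e-9
        # concavity of 1-exp(-x): exponential form never exceeds its tangent
        assert (
            cr_incidence(crf, beta, hi, 1e5)
            <= cr_incidence_linearized(crf, beta, hi, 1e5) + 1e-9
        )

    def test_population_doubling_doubles_incidence(self):
        crf = make_crf()
        one = cr_incidence(crf, 0.01, 5.0, 1e5)
        assert cr_incidence(crf, 0.01, 5.0, 2e5) == pytest.approx(2 * one)


class TestSplitStroke:
    def test_equal_weights_reference(self):
        total = split_stroke(3.0, (1 / 3, 1 / 3, 1 / 3), (9.5, 11.7, 13.1))
        assert total == pytest.approx(34.3, abs=0.05)

    def test_degenerate_weight_selects_stratum(self, stroke_strata):
        assert split_stroke(2.0, (1, 0, 0), stroke_strata) == pytest.approx(2 * 9.5)

    def test_zero_incidence(self):
        assert split_stroke(0.0, (0.5, 0.25, 0.25), (9.5, 11.7, 13.1)) == 0.0

    def test_bad_weights_rejected(self):
        with pytest.raises(ValidationError, match="sum"):
            split_stroke(1.0, (0.5, 0.5, 0.5), (9.5, 11.7, 13.1))


def degenerate_entry(pollutant, beta, y0, daly):
    crf = CRFunction(
        pollutant=pollutant,
        outcome="outcome",
        beta=UncertainValue(beta, beta, beta, "normal"),
        y0=y0,
    )
    return CREntry(crf=crf, daly=DALYPerIncidence("outcome", UncertainValue.point(daly)))


class TestIndImpactSamples:
    def test_degenerate_uncertainty_equals_deterministic_chain(self, demographics):
        # all CIs collapsed: every sample equals the closed-form value
        conc = PollutantConcentration("SO2", 2.9)
        entry = degenerate_entry("SO2", 0.002, 8.0e-3, 4e-4)
        summary = ind_impact_samples(
            conc, [entry], demographics, population=3e8, n=100, seed=1
        )
        delta_c = 0.7032 * 2.9
        expected = (
            -8.0e-3 * (math.exp(-0.002 * delta_c) - 1.0) * 3e8 * 4e-4 / 3e8 * 1e5
        )
        assert summary.median == pytest.approx(expected, rel=1e-12)
        assert np.all(summary.samples == summary.samples[0])

    def test_reproducible_under_seed(self, demographics, concentrations, cr_entries):
        pm_entries = [e for e in cr_entries if e.crf.pollutant == "PM2.5"]
        kwargs = dict(population=3e8, n=500, seed=7)
        a = ind_impact_samples(concentrations["PM2.5"], pm_entries, demographics, **kwargs)
        b = ind_impact_samples(concentrations["PM2.5"], pm_entries, demographics, **kwargs)
        assert np.array_equal(a.samples, b.samples)

    def test_single_sample(self, demographics, concentrations, cr_entries):
        entries = [e for e in cr_entries if e.crf.pollutant == "SO2"]
        s = ind_impact_samples(concentrations["SO2"], entries, demographics, n=1, seed=3)
        assert s.n_samples == 1 and s.median == s.ci_low == s.ci_high

    def test_ozone_fixture_interval_brackets_published_median(
        self, demographics, concentrations, cr_entries
    ):
        # published epidemiology-track estimate for ozone: 6.7 (0.3, 160);
        # the slope units are an open assumption, so only a loose interval
        # check is made
        entries = [e for e in cr_entries if e.crf.pollutant == "Ozone"]
        s = ind_impact_samples(
            concentrations["Ozone"], entries, demographics, n=10_000, seed=11
        )
        assert s.ci_low < 6.7 < s.ci_high

    def test_mismatched_pollutant_rejected(self, demographics, cr_entries):
        entries = [e for e in cr_entries if e.crf.pollutant == "SO2"]
        with pytest.raises(ValidationError, match="SO2"):
            ind_impact_samples(
                PollutantConcentration("Ozone", 17.2), entries, demographics, n=10
            )

    def test_stroke_entries_use_strata(self, demographics, concentrations, cr_entries):
        stroke_only = [
            e
            for e in cr_entries
            if e.crf.pollutant == "PM2.5" and e.crf.outcome == "nonfatal_stroke"
        ]
        s = ind_impact_samples(
            concentrations["PM2.5"], stroke_only, demographics, n=200, seed=5
        )
        assert s.median > 0
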