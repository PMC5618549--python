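"""The occupancy model, its finite-sampling bias, and the correction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicesat import (
    MultiplicitySpectrum,
    add_virtual_events,
    calibrate_virtual_count,
    expected_observed,
    predict_curve,
    unique_underestimation_fraction,
    unobserved_probability_unique,
)

TOY = MultiplicitySpectrum(n=2, z={1: 2, 2: 1})


@st.composite
def integer_spectra(draw, max_n=60):
    n = draw(st.integers(min_value=2, max_value=max_n))
    z = draw(
        st.dictionaries(
            st.integers(min_value=1, max_value=n),
            st.integers(min_value=1, max_value=10**5),
            min_size=1,
            max_size=6,
        )
    )
    return MultiplicitySpectrum(n=n, z=z)


class TestExpectedObserved:
    def test_hand_calculations(self):
        assert expected_observed(TOY, 1) == pytest.approx(2.0)
        assert expected_observed(TOY, 2) == pytest.approx(2.5)

    def test_large_batch_limit_is_total_mass(self):
        s = add_virtual_events(TOY, 0.3, 10.0)
        assert expected_observed(s, 5000) == pytest.approx(13.0, rel=1e-6)

    def test_nu_zero_rejected(self):
        with pytest.raises(ValueError):
            expected_observed(TOY, 0)

    @settings(max_examples=60, deadline=None)
    @given(integer_spectra())
    def test_monotone_in_batch_size(self, spectrum):
        nus = sorted({1, 2, 5, spectrum.n})
        values = [expected_observed(spectrum, nu) for nu in nus]
        assert all(a <= b + 1e-9 for a, b in zip(values, values[1:]))
        if any(j < spectrum.n for j in spectrum.z):
            assert values[0] < values[-1]

    @settings(max_examples=60, deadline=None)
    @given(integer_spectra())
    def test_single_sample_identity(self, spectrum):
        # At nu=1 the expectation is the prior mean times the site count.
        expect = sum(c * j / spectrum.n for j, c in spectrum.z.items())
        assert expected_observed(spectrum, 1) == pytest.approx(expect, rel=1e-12)

    def test_monte_carlo_oracle_small_spectrum(self):
        # Generative simulation: each site present independently per sample.
        s = MultiplicitySpectrum(n=4, z={1: 10, 2: 5, 3: 3, 4: 2})
        rng = np.random.default_rng(42)
        p = np.repeat([1 / 4, 2 / 4, 3 / 4, 1.0], [10, 5, 3, 2])
        for nu in (1, 2, 4, 6):
            hits = rng.binomial(nu, p, size=(20_000, p.size)) >= 1
            union = hits.sum(axis=1)
            se = union.std(ddof=1) / math.sqrt(union.size)
            assert abs(expected_observed(s, nu) - union.mean()) <= 3 * se


class TestUniqueEventBias:
    def test_degenerate_single_sample(self):
        assert unobserved_probability_unique(1) == 0.0

    def test_limit_is_inverse_e(self):
        assert unobserved_probability_unique(math.inf) == pytest.approx(math.exp(-1))

    def test_n54_within_one_percent_of_limit(self):
        v = unobserved_probability_unique(54)
        assert v == pytest.approx((53 / 54) ** 54)
        assert abs(v - math.exp(-1)) / math.exp(-1) < 0.01

    def test_monotone_increasing_in_n(self):
        vals = [unobserved_probability_unique(n) for n in range(1, 200)]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert all(v < math.exp(-1) for v in vals)

    def test_underestimation_fraction_values(self):
        assert unique_underestimation_fraction(2) == pytest.approx(0.25)
        assert unique_underestimation_fraction(math.inf) == pytest.approx(0.368, abs=5e-4)


class TestVirtualEvents:
    def test_zero_mass_changes_nothing(self):
        s = add_virtual_events(TOY, 0.24, 0.0)
        for nu in (1, 2, 10):
            assert expected_observed(s, nu) == expected_observed(TOY, nu)

    def test_add_then_remove_restores_predictions(self):
        s = add_virtual_events(TOY, 0.24, 1e6).without_virtual()
        for nu in (1, 2, 10):
            assert expected_observed(s, nu) == expected_observed(TOY, nu)

    def test_virtual_term_contribution(self):
        mu_v, m_v, nu = 0.24, 7.75e6, 10
        s = MultiplicitySpectrum(n=54, z={54: 5})
        extra = expected_observed(add_virtual_events(s, mu_v, m_v), nu)
        assert extra - expected_observed(s, nu) == pytest.approx(
            m_v * (1 - (1 - mu_v / 54) ** nu), rel=1e-9
        )

    @pytest.mark.parametrize("mu_v", [0.0, 1.0, -0.2, 1.5])
    def test_multiplicity_outside_unit_interval_rejected(self, mu_v):
        with pytest.raises(ValueError):
            add_virtual_events(TOY, mu_v, 1.0)


class TestCalibration:
    def test_hand_calculation(self):
        m_v = calibrate_virtual_count(TOY, mu_v=0.5)
        assert m_v == pytest.approx(0.5 / 0.4375)
        corrected = add_virtual_events(TOY, 0.5, m_v)
        assert expected_observed(corrected, 2) == pytest.approx(3.0, rel=1e-12)

    def test_no_bias_no_correction(self):
        s = MultiplicitySpectrum(n=5, z={5: 100})
        assert calibrate_virtual_count(s, 0.24) == 0.0

    @settings(max_examples=80, deadline=None)
    @given(integer_spectra(), st.floats(min_value=0.05, max_value=0.95))
    def test_corrected_full_batch_prediction_is_exact(self, spectrum, mu_v):
        m_v = calibrate_virtual_count(spectrum, mu_v)
        corrected = add_virtual_events(spectrum, mu_v, m_v)
        assert expected_observed(corrected, spectrum.n) == pytest.approx(
            spectrum.total_sites(), rel=1e-9
        )


class TestPredictCurve:
    def test_raw_deficit_identity(self):
        n = TOY.n
        curve = predict_curve(TOY, [n], corrected=False)
        deficit = sum(c * (1 - j / n) ** n for j, c in TOY.z.items() if j < n)
        assert TOY.total_sites() - curve.expected[-1] == pytest.approx(deficit)
        assert curve.expected[-1] < TOY.total_sites()  # underestimation bias

    def test_corrected_curve_hits_total_at_n(self):
        curve = predict_curve(TOY, [1, 2], corrected=True, mu_v=0.5)
        assert curve.expected[-1] == pytest.approx(TOY.total_sites())
        assert curve.model_tag == "corrected"

    def test_raw_equals_corrected_without_low_multiplicity_mass(self):
        s = MultiplicitySpectrum(n=3, z={3: 7})
        raw = predict_curve(s, [1, 2, 3], corrected=False)
        cor = predict_curve(s, [1, 2, 3], corrected=True)
        np.testing.assert_allclose(raw.expected, cor.expected)

    def test_extrapolation_flagged(self):
        curve = predict_curve(TOY, [1, 2, 3, 10], corrected=False)
        assert list(curve.extrapolated) == [False, False, True, True]
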