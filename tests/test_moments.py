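"""Moment operator accuracy and the moment-based bed characterization chain."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fiberchrom.errors import DataError, DomainError, EstimationError
from fiberchrom.moments import (
    PeakMoments,
    accessible_fraction,
    baseline_correct,
    correct_extra_column,
    dax_from_moments,
    fit_dispersivity,
    peak_moments,
    porosity_from_voidages,
    voidages_from_isec,
)


def _rect(t0=10.0, t1=20.0, n=20001, t_end=40.0):
    t = np.linspace(0.0, t_end, n)
    y = ((t >= t0) & (t <= t1)).astype(float)
    return t, y


class TestPeakMoments:
    def test_rectangular_pulse_closed_form(self):
        t, y = _rect()
        m = peak_moments(t, y, threshold_frac=0.0)
        assert m.mu == pytest.approx(15.0, rel=1e-6)
        assert m.sigma2 == pytest.approx(100.0 / 12.0, rel=1e-3)

    def test_gaussian_peak_moments(self):
        t = np.linspace(0.0, 100.0, 40001)
        t0, s = 40.0, 3.0
        y = np.exp(-0.5 * ((t - t0) / s) ** 2)
        m = peak_moments(t, y, threshold_frac=0.0)
        assert m.mu == pytest.approx(t0, rel=1e-6)
        assert m.sigma2 == pytest.approx(s**2, rel=1e-6)

    def test_emg_peak_closed_form_moments(self):
        # exponentially-modified Gaussian: mu = t0 + tau, sigma2 = s^2 + tau^2
        t = np.linspace(0.0, 400.0, 80001)
        t0, s, tau = 60.0, 2.5, 8.0
        gauss = np.exp(-0.5 * ((t - t0) / s) ** 2)
        dt = t[1] - t[0]
        kern = np.exp(-t / tau)
        y = np.convolve(gauss, kern)[: t.size] * dt / tau
        m = peak_moments(t, y, threshold_frac=0.0)
        assert m.mu == pytest.approx(t0 + tau, rel=1e-4)
        assert m.sigma2 == pytest.approx(s**2 + tau**2, rel=1e-3)

    @given(shift=st.floats(1.0, 50.0))
    @settings(max_examples=25, deadline=None)
    def test_translation_adds_to_mu_leaves_sigma2(self, shift):
        t = np.linspace(0.0, 200.0, 8001)
        y = np.exp(-0.5 * ((t - 30.0) / 2.0) ** 2)
        m0 = peak_moments(t, y, threshold_frac=0.0)
        m1 = peak_moments(t + shift, y, threshold_frac=0.0)
        assert m1.mu - m0.mu == pytest.approx(shift, rel=1e-9)
        assert m1.sigma2 == pytest.approx(m0.sigma2, rel=1e-9)

    def test_convolution_moment_additivity(self):
        """Variance additivity under convolution justifies the series
        subtraction of extra-column moments."""
        t = np.linspace(0.0, 300.0, 60001)
        dt = t[1] - t[0]
        a = np.exp(-0.5 * ((t - 30.0) / 2.0) ** 2)
        b = np.exp(-((t - 5.0) ** 2) / (2 * 4.0)) * (t > 0)
        conv = np.convolve(a, b)[: t.size] * dt
        ma = peak_moments(t, a, threshold_frac=0.0)
        mb = peak_moments(t, b, threshold_frac=0.0)
        mc = peak_moments(t, conv, threshold_frac=0.0)
        assert mc.mu == pytest.approx(ma.mu + mb.mu, rel=1e-6)
        assert mc.sigma2 == pytest.approx(ma.sigma2 + mb.sigma2, rel=1e-4)

    def test_all_zero_signal_rejected(self):
        t = np.linspace(0, 10, 100)
        with pytest.raises(DomainError):
            peak_moments(t, np.zeros_like(t))

    def test_baseline_correction_removes_linear_drift(self):
        t = np.linspace(0.0, 100.0, 10001)
        peak = np.exp(-0.5 * ((t - 50.0) / 2.0) ** 2)
        drift = 0.05 + 0.001 * t
        y = baseline_correct(t, peak + drift, (0.0, 10.0), (90.0, 100.0))
        m = peak_moments(t, y)
        assert m.mu == pytest.approx(50.0, abs=0.05)


class TestExtraColumnCorrection:
    def test_hand_arithmetic(self):
        obs = PeakMoments(60.0, 25.0, 1.0)
        hplc = PeakMoments(10.0, 4.0, 1.0)
        out = correct_extra_column(obs, hplc)
        assert (out.mu, out.sigma2) == (50.0, 21.0)

    def test_zero_system_is_identity(self):
        obs = PeakMoments(60.0, 25.0, 1.0)
        out = correct_extra_column(obs, PeakMoments(0.0, 0.0, 1.0))
        assert (out.mu, out.sigma2) == (obs.mu, obs.sigma2)
        assert correct_extra_column(obs, None) is obs

    def test_equal_moments_boundary_accepted(self):
        obs = PeakMoments(10.0, 4.0, 1.0)
        out = correct_extra_column(obs, obs)
        assert (out.mu, out.sigma2) == (0.0, 0.0)

    def test_narrower_than_system_rejected(self):
        with pytest.raises(DataError):
            correct_extra_column(PeakMoments(10.0, 4.0, 1.0), PeakMoments(12.0, 1.0, 1.0))


class TestAccessibleFraction:
    def test_hand_arithmetic(self):
        # F = 1 mL/min, mu = 1.2 min = 72 s, V = 2.36 mL
        assert accessible_fraction(72.0, 1.0, 2.36) == pytest.approx(1.2 / 2.36)

    def test_full_access_is_one(self):
        V, F = 2.36, 3.0
        mu = V / (F / 60.0)
        assert accessible_fraction(mu, F, V) == pytest.approx(1.0)

    def test_above_hold_up_rejected(self):
        with pytest.raises(DataError):
            accessible_fraction(72.0 * 1.2, 1.0, 1.2)


class TestPorosity:
    def test_reference_bed_value(self):
        assert porosity_from_voidages(0.76, 0.54) == pytest.approx(0.478, abs=5e-4)

    def test_degenerate_limits(self):
        assert porosity_from_voidages(0.5, 0.5) == 0.0
        assert porosity_from_voidages(1.0, 0.3) == pytest.approx(1.0)

    def test_ordering_violation_rejected(self):
        with pytest.raises(DomainError):
            porosity_from_voidages(0.5, 0.6)


class TestDaxAndDispersivity:
    def test_hand_arithmetic(self):
        assert dax_from_moments(2.0, 0.1, 3.0) == pytest.approx(2 * 0.001 / 6.0)

    def test_linearity_in_sigma2(self):
        assert dax_from_moments(4.0, 0.1, 3.0) == pytest.approx(
            2 * dax_from_moments(2.0, 0.1, 3.0)
        )

    def test_exact_line_recovers_reference_dispersivity(self):
        v = np.array([0.02, 0.05, 0.1, 0.2])
        alpha, report = fit_dispersivity(zip(v, 0.051 * v))
        assert alpha == pytest.approx(0.051, rel=1e-12)
        assert report["r2"] == pytest.approx(1.0)

    def test_zero_dispersion_gives_zero_alpha(self):
        v = np.array([0.05, 0.1])
        alpha, _ = fit_dispersivity(zip(v, np.zeros_like(v)))
        assert alpha == 0.0

    def test_noisy_line_monte_carlo(self):
        rng = np.random.default_rng(7)
        v = np.linspace(0.02, 0.2, 10)
        dax = 0.051 * v * (1 + 0.05 * rng.standard_normal(v.size))
        alpha, _ = fit_dispersivity(zip(v, dax))
        assert alpha == pytest.approx(0.051, rel=0.10)

    def test_single_point_rejected(self):
        with pytest.raises(EstimationError):
            fit_dispersivity([(0.1, 0.005)])


class TestISEC:
    def test_plateau_round_trip(self, truth_clean):
        from fiberchrom import gen_isec_curve

        df = gen_isec_curve(truth_clean, seed=0)
        eps_T, eps_b = voidages_from_isec(df["r_h_nm"], df["epsilon"])
        assert eps_T == pytest.approx(0.76, abs=1e-12)
        assert eps_b == pytest.approx(0.54, abs=1e-12)
        assert porosity_from_voidages(eps_T, eps_b) == pytest.approx(0.478, abs=5e-4)

    def test_grid_must_span_both_plateaus(self):
        with pytest.raises(DataError):
            voidages_from_isec([2.0, 3.0, 4.0], [0.7, 0.65, 0.6])
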