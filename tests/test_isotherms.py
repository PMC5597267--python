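"""Langmuir evaluation, salt dependence, and the batch-fitting workflow."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fiberchrom.errors import (
    ConfigurationError,
    DomainError,
    EstimationError,
    RangeError,
)
from fiberchrom.isotherms import (
    BatchAdsorptionDataset,
    CompositeMeasurement,
    LangmuirParams,
    SaltDependence,
    STANDARD_ASSAYS,
    eval_langmuir,
    eval_salt_dependence,
    fit_langmuir,
    fit_salt_dependence,
    invert_composite,
)


class TestEvalLangmuir:
    def test_zero_input_gives_zero_binding(self):
        params = [LangmuirParams(50.0, 2.0), LangmuirParams(30.0, 1.0)]
        assert eval_langmuir(params, [0.0, 0.0]) == pytest.approx([0.0, 0.0])

    def test_single_component_hand_value(self):
        # q = 50*2*0.5 / (1 + 2*0.5) = 25
        q = eval_langmuir([LangmuirParams(50.0, 2.0)], [0.5])
        assert q[0] == pytest.approx(25.0)

    def test_two_identical_components_sum_like_one_at_double_conc(self):
        p = LangmuirParams(40.0, 3.0)
        q_pair = eval_langmuir([p, p], [0.7, 0.7]).sum()
        q_single = eval_langmuir([p], [1.4])[0]
        assert q_pair == pytest.approx(q_single, rel=1e-12)

    def test_matches_textbook_single_component_formula_on_grid(self):
        qmax, K = 37.0, 4.2
        for c in np.linspace(0.0, 10.0, 50):
            expected = K * qmax * c / (1.0 + K * c)
            assert eval_langmuir([LangmuirParams(qmax, K)], [c])[0] == pytest.approx(
                expected, rel=1e-12, abs=1e-15
            )

    def test_negative_concentration_rejected(self):
        with pytest.raises(DomainError):
            eval_langmuir([LangmuirParams(50.0, 2.0)], [-0.1])

    @given(
        c=st.lists(st.floats(0.0, 50.0), min_size=1, max_size=4),
        qmax=st.floats(1.0, 200.0),
        k=st.lists(st.floats(0.01, 20.0), min_size=4, max_size=4),
    )
    @settings(max_examples=60, deadline=None)
    def test_fractional_coverage_bounded_below_one(self, c, qmax, k):
        """With equal q_max, total fractional coverage stays below 1."""
        n = len(c)
        params = [LangmuirParams(qmax, k[i]) for i in range(n)]
        q = eval_langmuir(params, c)
        assert (q / qmax).sum() < 1.0
        assert np.all(q >= 0.0) and np.all(q < qmax)

    @given(
        c=st.lists(st.floats(0.01, 10.0), min_size=2, max_size=2),
        k=st.lists(st.floats(0.05, 5.0), min_size=2, max_size=2),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_own_concentration_antitone_in_competitor(self, c, k):
        params = [LangmuirParams(50.0, k[0]), LangmuirParams(50.0, k[1])]
        h = 1e-6
        q0 = eval_langmuir(params, c)
        q_up_own = eval_langmuir(params, [c[0] + h, c[1]])
        q_up_other = eval_langmuir(params, [c[0], c[1] + h])
        assert q_up_own[0] >= q0[0]
        assert q_up_other[0] <= q0[0]


class TestSaltDependence:
    def test_zero_salt_identity(self):
        sd = SaltDependence(a1=-0.1, a2=60.0, b1=10.0, b2=0.02)
        p = eval_salt_dependence(sd, 0.0)
        assert (p.q_max, p.K_eq) == (60.0, 10.0)

    def test_degenerate_decay_constant_keq(self):
        sd = SaltDependence(a1=0.0, a2=60.0, b1=7.0, b2=0.0)
        for c in (0.0, 50.0, 400.0):
            assert eval_salt_dependence(sd, c).K_eq == 7.0

    def test_hand_evaluated_point(self):
        sd = SaltDependence(a1=-0.1, a2=60.0, b1=10.0, b2=0.02)
        p = eval_salt_dependence(sd, 100.0)
        assert p.q_max == pytest.approx(50.0)
        assert p.K_eq == pytest.approx(10.0 * math.exp(-2.0), rel=1e-12)

    def test_negative_qmax_names_salt_level(self):
        sd = SaltDependence(a1=-1.0, a2=60.0, b1=10.0, b2=0.02)
        with pytest.raises(RangeError, match="100"):
            eval_salt_dependence(sd, 100.0)
        with pytest.raises(RangeError):
            sd.validate_range(500.0)


class TestFitLangmuir:
    def test_noise_free_round_trip(self):
        qmax, K = 40.0, 5.0
        c = np.array([0.05, 0.1, 0.5, 1.0, 2.0, 5.0])
        q = K * qmax * c / (1 + K * c)
        params, r2, binding = fit_langmuir(c, q)
        assert binding
        assert params.q_max == pytest.approx(qmax, rel=1e-3)
        assert params.K_eq == pytest.approx(K, rel=1e-3)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_noisy_monte_carlo_recovery(self):
        qmax, K = 40.0, 5.0
        c = np.array([0.05, 0.1, 0.5, 1.0, 2.0, 5.0])
        q_true = K * qmax * c / (1 + K * c)
        rng = np.random.default_rng(42)
        est = []
        for _ in range(5):
            q = q_true * (1 + 0.02 * rng.standard_normal(c.size))
            params, _, _ = fit_langmuir(c, q)
            est.append([params.q_max, params.K_eq])
        mean = np.mean(est, axis=0)
        assert mean[0] == pytest.approx(qmax, rel=0.10)
        assert mean[1] == pytest.approx(K, rel=0.10)

    def test_all_zero_flagged_non_binding(self):
        params, _, binding = fit_langmuir([0.1, 0.5, 1.0], [0.0, 0.0, 0.0])
        assert not binding
        assert params.K_eq == 0.0

    def test_underdetermined_inputs_rejected(self):
        with pytest.raises(EstimationError):
            fit_langmuir([0.1, 0.5], [1.0, 2.0])
        with pytest.raises(EstimationError):
            fit_langmuir([1.0, 1.0, 1.0], [1.0, 1.1, 0.9])


class TestFitSaltDependence:
    def test_exact_round_trip(self):
        sd = SaltDependence(a1=-0.1, a2=65.0, b1=5.0, b2=0.025)
        fits = [(c, eval_salt_dependence(sd, c)) for c in (20.0, 60.0, 100.0, 140.0)]
        out, r2s = fit_salt_dependence(fits)
        assert out.a1 == pytest.approx(sd.a1, rel=1e-9)
        assert out.a2 == pytest.approx(sd.a2, rel=1e-9)
        assert out.b1 == pytest.approx(sd.b1, rel=1e-9)
        assert out.b2 == pytest.approx(sd.b2, rel=1e-9)
        assert r2s["r2_qmax"] == pytest.approx(1.0)

    def test_log_linear_decay_rate_recovery(self):
        b1, b2 = 3.0, 0.05
        fits = [
            (c, LangmuirParams(50.0, b1 * math.exp(-b2 * c)))
            for c in (20.0, 60.0, 100.0, 140.0)
        ]
        out, _ = fit_salt_dependence(fits)
        assert out.b2 == pytest.approx(b2, abs=1e-6)

    def test_flat_keq_yields_zero_decay(self):
        fits = [(c, LangmuirParams(50.0, 2.0)) for c in (20.0, 60.0, 100.0)]
        out, _ = fit_salt_dependence(fits)
        assert out.b2 == pytest.approx(0.0, abs=1e-12)

    def test_too_few_levels_rejected(self):
        fits = [(20.0, LangmuirParams(50.0, 2.0)), (60.0, LangmuirParams(45.0, 1.0))]
        with pytest.raises(EstimationError):
            fit_salt_dependence(fits)


class TestBatchDataset:
    def test_fit_component_end_to_end_noise_free(self):
        sd = SaltDependence(a1=-0.1, a2=65.0, b1=5.0, b2=0.025)
        rows = []
        for c_mod in (20.0, 60.0, 100.0, 140.0):
            p = eval_salt_dependence(sd, c_mod)
            for c in (0.25, 0.5, 1.0, 2.0, 5.0):
                rows.append(
                    {
                        "component": "mAb",
                        "c_eq_mg_ml": c,
                        "q_mg_ml": p.K_eq * p.q_max * c / (1 + p.K_eq * c),
                        "salt_mM": c_mod,
                    }
                )
        ds = BatchAdsorptionDataset(rows)
        out, report = ds.fit_component("mAb")
        assert out.a1 == pytest.approx(sd.a1, rel=1e-3)
        assert out.b2 == pytest.approx(sd.b2, rel=1e-3)
        assert report["r2_qmax"] > 0.999

    def test_per_gram_conversion(self):
        rows = [
            {"component": "x", "c_eq_mg_ml": c, "q_mg_ml": 10.0, "salt_mM": 20.0}
            for c in (0.5, 1.0, 2.0)
        ]
        ds = BatchAdsorptionDataset(rows, q_per_gram=True, packing_density=0.35)
        assert np.allclose(ds.frame["q_mg_ml"], 3.5)

    def test_missing_columns_rejected(self):
        with pytest.raises(ConfigurationError, match="salt_mM"):
            BatchAdsorptionDataset([{"component": "x", "c_eq_mg_ml": 1, "q_mg_ml": 1}])


class TestInvertComposite:
    def _measurements(self, mono, agg, low):
        return [
            CompositeMeasurement("total-mAb", mono + agg, STANDARD_ASSAYS["total-mAb"]),
            CompositeMeasurement("monomer", mono, STANDARD_ASSAYS["monomer"]),
            CompositeMeasurement("aggregate", agg, STANDARD_ASSAYS["aggregate"]),
            CompositeMeasurement("lowMW", low, STANDARD_ASSAYS["lowMW"]),
        ]

    def test_exact_recovery(self):
        conc, report = invert_composite(self._measurements(2.0, 0.2, 1.0))
        assert conc["monomer"] == pytest.approx(2.0)
        assert conc["aggregate"] == pytest.approx(0.2)
        assert conc["lowMW"] == pytest.approx(1.0)
        assert report["consistent"]

    def test_inconsistency_reported(self):
        ms = [
            CompositeMeasurement("total-mAb", 2.4, STANDARD_ASSAYS["total-mAb"]),
            CompositeMeasurement("monomer", 2.0, STANDARD_ASSAYS["monomer"]),
            CompositeMeasurement("aggregate", 0.2, STANDARD_ASSAYS["aggregate"]),
            CompositeMeasurement("lowMW", 0.5, STANDARD_ASSAYS["lowMW"]),
        ]
        _, report = invert_composite(ms, tolerance=0.1)
        assert report["total_mab_inconsistency"] == pytest.approx(0.2)
        assert not report["consistent"]

    def test_zero_in_zero_out(self):
        conc, _ = invert_composite(self._measurements(0.0, 0.0, 0.0))
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in conc.values())

    def test_rank_deficiency_rejected(self):
        ms = [
            CompositeMeasurement("total-mAb", 2.2, STANDARD_ASSAYS["total-mAb"]),
            CompositeMeasurement("monomer", 2.0, STANDARD_ASSAYS["monomer"]),
        ]
        with pytest.raises(ConfigurationError):
            invert_composite(ms)
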