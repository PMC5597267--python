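"""Column model physics: hold-up, dispersion, retention, conservation."""

import numpy as np
import pytest

from fiberchrom.errors import ConfigurationError
from fiberchrom.isotherms import LangmuirParams, SaltDependence
from fiberchrom.moments import dax_from_moments, peak_moments
from fiberchrom.solver import (
    FlowProgram,
    Segment,
    SolverSettings,
    _fwhm,
    assemble_system,
    sensitivity_scan,
    simulate,
)
from fiberchrom.types import Component

from conftest import inlet_moments

MAB_BINDING = SaltDependence(a1=-0.10, a2=65.0, b1=5.0, b2=0.025)


class TestTracerTransport:
    def test_zero_inlet_zero_state_stays_zero(self, bed, fast_settings):
        prog = FlowProgram(
            (Segment(30.0, 3.0, {"salt": 0.0, "x": 0.0}),)
        )
        system = assemble_system(bed, [Component("x", 1e-9)], {"x": 1.0}, prog,
                                 settings=fast_settings)
        res = simulate(system)
        assert np.allclose(res.column_outlet.signal("x"), 0.0, atol=1e-12)

    def test_fully_accessing_tracer_first_moment_is_total_holdup(
        self, bed, acetone_tracer_run
    ):
        """Fast-exchange non-binding tracer: centroid at V*eps_T/F."""
        system, res = acetone_tracer_run
        m = peak_moments(res.column_outlet.time_s, res.column_outlet.signal("acetone"))
        mu_col = m.mu - inlet_moments(system, "acetone").mu
        expected = bed.V_ml * bed.eps_T / (3.0 / 60.0)
        assert mu_col == pytest.approx(expected, rel=0.01)

    def test_excluded_tracer_recovers_dispersivity(self, bed, fast_settings):
        """Moment analysis of a stagnant-phase-excluded tracer returns the
        configured D_ax = alpha * v."""
        prog = FlowProgram.tracer_pulse(species="dex", F_ml_min=3.0)
        system = assemble_system(bed, [Component("dex", 1e-11)], {"dex": 0.0}, prog,
                                 settings=fast_settings)
        res = simulate(system)
        m = peak_moments(res.column_outlet.time_s, res.column_outlet.signal("dex"))
        m_in = inlet_moments(system, "dex")
        v = bed.interstitial_velocity(3.0)
        # interstitial hold-up only
        assert m.mu - m_in.mu == pytest.approx(bed.V_ml * bed.eps_b / 0.05, rel=0.01)
        dax = dax_from_moments(m.sigma2 - m_in.sigma2, v, bed.L_m)
        assert dax == pytest.approx(bed.alpha_m * v, rel=0.05)

    def test_salt_step_breakthrough_monotone_with_total_holdup_centroid(
        self, bed, fast_settings
    ):
        prog = FlowProgram.salt_step(F_ml_min=3.0, salt_from_mM=20.0, salt_to_mM=500.0)
        system = assemble_system(bed, [], {}, prog, settings=fast_settings)
        res = simulate(system)
        t = res.column_outlet.time_s
        y = res.column_outlet.signal("salt")
        assert np.all(np.diff(y) > -1e-6 * y.max())  # monotone S-curve
        # centroid of the derivative sits one total hold-up after the step
        dy = np.gradient(y, t)
        m = peak_moments(t, np.clip(dy, 0, None), threshold_frac=0.0)
        t_step = system._bounds[1]
        assert m.mu - t_step == pytest.approx(bed.V_ml * bed.eps_T / 0.05, rel=0.02)


class TestRetention:
    def test_linear_isotherm_centroid_closed_form(self, bed, fast_settings):
        """Equilibrium-dispersive limit: t_R = (L/v)(1 + ((1-eb)/eb)(ep + (1-ep)K))."""
        K_slope = 2.0  # K_eq * q_max at vanishing load
        comp = Component("p", 4e-11, binding=LangmuirParams(q_max=40.0, K_eq=0.05))
        prog = FlowProgram.tracer_pulse(species="p", F_ml_min=3.0,
                                        concentration=1e-4, chase_cv=5.0)
        system = assemble_system(bed, [comp], {"p": 50.0}, prog, settings=fast_settings)
        res = simulate(system)
        m = peak_moments(res.column_outlet.time_s, res.column_outlet.signal("p"))
        v = bed.interstitial_velocity(3.0)
        eb, ep = bed.eps_b, bed.eps_p
        t_pred = (bed.L_m / v) * (1 + (1 - eb) / eb * (ep + (1 - ep) * K_slope))
        assert m.mu - inlet_moments(system, "p").mu == pytest.approx(t_pred, rel=0.01)

    def test_peak_position_independent_of_load_in_linear_regime(self, bed, fast_settings):
        mus = []
        for conc in (1e-5, 1e-4):
            comp = Component("p", 4e-11, binding=LangmuirParams(q_max=40.0, K_eq=0.05))
            prog = FlowProgram.tracer_pulse(species="p", F_ml_min=3.0,
                                            concentration=conc, chase_cv=5.0)
            system = assemble_system(bed, [comp], {"p": 50.0}, prog,
                                     settings=fast_settings)
            res = simulate(system)
            mus.append(
                peak_moments(res.column_outlet.time_s,
                             res.column_outlet.signal("p")).mu
            )
        assert mus[0] == pytest.approx(mus[1], rel=1e-3)

    def test_high_salt_limit_elutes_unretained(self, bed, fast_settings):
        """With a steep K decay and high salt, the protein runs through."""
        sd = SaltDependence(a1=0.0, a2=65.0, b1=5.0, b2=5.0)
        comp = Component("m", 4e-11, binding=sd)
        prog = FlowProgram.tracer_pulse(species="m", F_ml_min=3.0,
                                        salt_mM=500.0, chase_cv=4.0)
        system = assemble_system(bed, [comp], {"m": 0.129}, prog,
                                 settings=fast_settings)
        res = simulate(system)
        m = peak_moments(res.column_outlet.time_s, res.column_outlet.signal("m"))
        unretained = bed.V_ml * bed.eps_T / 0.05
        assert m.mu - inlet_moments(system, "m").mu == pytest.approx(unretained, rel=0.02)


@pytest.fixture(scope="module")
def mab_system(bed, fast_settings):
    comp = Component("mAb", 4.00e-11, binding=MAB_BINDING)
    prog = FlowProgram.bind_wash_elute(load={"mAb": 4.0}, gradient_cv=7.5)
    return assemble_system(bed, [comp], {}, prog, settings=fast_settings)


class TestGradientElution:
    def test_mass_balance_closes(self, mab_system):
        res = simulate(mab_system)
        mb = res.mass_balance.set_index("species")
        assert mb.loc["mAb", "closure"] == pytest.approx(1.0, abs=1e-3)
        assert mb.loc["mAb", "fed_mg"] == pytest.approx(0.4, rel=1e-9)  # 100 µL * 4 mg/mL

    def test_longer_gradient_broadens_and_lowers_peak(self, bed, fast_settings):
        comp = Component("mAb", 4.00e-11, binding=MAB_BINDING)
        widths, heights = [], []
        for cv in (5.0, 10.0):
            prog = FlowProgram.bind_wash_elute(load={"mAb": 4.0}, gradient_cv=cv)
            system = assemble_system(bed, [comp], {}, prog, settings=fast_settings)
            res = simulate(system)
            t, y = res.column_outlet.time_s, res.column_outlet.signal("mAb")
            widths.append(_fwhm(t, y))
            heights.append(y.max())
        assert widths[1] > widths[0]
        assert heights[1] < heights[0]

    def test_grid_convergence_of_retention_and_width(self, bed):
        comp = Component("mAb", 4.00e-11, binding=MAB_BINDING)
        prog = FlowProgram.bind_wash_elute(load={"mAb": 4.0}, gradient_cv=7.5)
        out = {}
        for n in (100, 200):
            system = assemble_system(bed, [comp], {}, prog,
                                     settings=SolverSettings(n_cells=n))
            res = simulate(system)
            t, y = res.column_outlet.time_s, res.column_outlet.signal("mAb")
            out[n] = (peak_moments(t, y).mu, _fwhm(t, y))
        assert abs(out[200][0] - out[100][0]) / out[200][0] < 1e-3
        assert abs(out[200][1] - out[100][1]) / out[200][1] < 0.01

    def test_scan_over_current_value_reproduces_simulate(self, mab_system):
        res_direct = simulate(mab_system)
        current = float(mab_system.k_eff_A[mab_system.species.index("mAb")])
        results, summary = sensitivity_scan(mab_system, "k_eff_A", [current])
        np.testing.assert_allclose(
            results[0].column_outlet.signal("mAb"),
            res_direct.column_outlet.signal("mAb"),
            rtol=1e-9, atol=1e-12,
        )
        assert len(summary) == 1

    def test_lower_keffA_broadens_peak(self, mab_system):
        _, summary = sensitivity_scan(mab_system, "k_eff_A", [1.0, 0.065])
        w = summary["fwhm_s"].to_numpy()
        assert w[1] > 1.5 * w[0]

    def test_empty_scan_rejected(self, mab_system):
        with pytest.raises(ConfigurationError):
            sensitivity_scan(mab_system, "k_eff_A", [])

    def test_unknown_parameter_rejected(self, mab_system):
        with pytest.raises(ConfigurationError):
            sensitivity_scan(mab_system, "zeta_potential", [1.0])


class TestAssembly:
    def test_program_referencing_unknown_component_rejected(self, bed):
        prog = FlowProgram.tracer_pulse(species="ghost", F_ml_min=3.0)
        with pytest.raises(ConfigurationError, match="ghost"):
            assemble_system(bed, [], {}, prog)

    def test_binding_salt_rejected(self, bed):
        salt = Component("salt", 1.99e-9, binding=LangmuirParams(10.0, 1.0))
        prog = FlowProgram.salt_step()
        with pytest.raises(ConfigurationError, match="non-binding"):
            assemble_system(bed, [salt], {}, prog)

    def test_negative_qmax_over_program_salt_range_rejected(self, bed):
        sd = SaltDependence(a1=-1.0, a2=65.0, b1=5.0, b2=0.02)  # negative past 65 mM
        comp = Component("m", 4e-11, binding=sd)
        prog = FlowProgram.bind_wash_elute(load={"m": 1.0}, salt_high_mM=500.0)
        with pytest.raises(Exception, match="500"):
            assemble_system(bed, [comp], {}, prog)
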