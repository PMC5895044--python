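"""Forward-model and fitter tests: oracles, round trips, invariances."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from frrphys import frr_model as fm
from frrphys import synthetic


def make_params(fo=350.0, fmax=1000.0, sigma=450.0, rho=0.35,
                tau1=2500.0, tau2=450.0, amp1=0.35):
    return fm.PSIIFitResult(fo=fo, fm=fmax, sigma_psii=sigma, rho=rho,
                            tau1=tau1, tau2=tau2, amp1=amp1, amp2=1 - amp1)


class TestProtocol:
    def test_defaults_follow_single_turnover_configuration(self, protocol):
        assert protocol.n_induction_flashlets == 40
        assert protocol.flashlet_spacing == pytest.approx(128.0 / 40)
        assert protocol.relaxation_times.size == 4000
        assert protocol.actinic_levels[0] == 0.0

    @pytest.mark.parametrize("kwargs", [
        {"n_induction_flashlets": 0},
        {"flashlet_duration": -1.0},
        {"n_induction_flashlets": 200},   # train does not fit in the window
    ])
    def test_invalid_protocols_rejected(self, kwargs):
        with pytest.raises(ValueError):
            fm.FlashletProtocol(**kwargs)


class TestClosureModel:
    def test_fluorescence_map_endpoints(self):
        assert fm.fluorescence_from_closure(0.0, 200.0, 500.0, 0.4) == 200.0
        assert fm.fluorescence_from_closure(1.0, 200.0, 500.0, 0.4) == 500.0

    def test_zero_connectivity_is_saturating_exponential(self):
        dose = np.linspace(0, 5e-3, 50)
        c = fm.closure_fraction(dose, sigma=450.0, rho=0.0)
        np.testing.assert_allclose(c, 1 - np.exp(-450.0 * dose), rtol=1e-12)

    @pytest.mark.parametrize("rho", [0.1, 0.35, 0.7])
    def test_closure_matches_ode_integration(self, rho):
        """Closed-form Lambert-W closure equals a fine numerical integral."""
        sigma = 500.0
        doses = np.linspace(1e-4, 1e-2, 20)

        def rhs(s, c):
            return sigma * (1 - c) / (1 - rho * c)

        sol = solve_ivp(rhs, (0, doses[-1]), [0.0], t_eval=doses,
                        rtol=1e-10, atol=1e-12)
        ours = fm.closure_fraction(doses, sigma, rho)
        np.testing.assert_allclose(ours, sol.y[0], rtol=1e-3 * 1e-1)

    def test_saturating_dose_flags_trace(self, protocol):
        hot = fm.FlashletProtocol(excitation_intensity=10.0)
        trace = fm.simulate_transient(make_params(), hot)
        assert "dose_saturates" in trace.warnings


class TestInductionFit:
    @pytest.mark.parametrize("sigma,rho", [(450.0, 0.35), (700.0, 0.1),
                                           (300.0, 0.6)])
    def test_noiseless_round_trip(self, protocol, sigma, rho):
        truth = make_params(sigma=sigma, rho=rho)
        trace = fm.simulate_transient(truth, protocol)
        fit = fm.fit_induction(trace, protocol)
        assert fit.fo == pytest.approx(truth.fo, rel=1e-6)
        assert fit.fm == pytest.approx(truth.fm, rel=1e-6)
        assert fit.sigma_psii == pytest.approx(sigma, rel=1e-5)
        assert fit.rho == pytest.approx(rho, abs=1e-5)

    def test_zero_connectivity_matches_exponential_oracle(self, protocol):
        """On a rho=0 trace the fitted sigma equals the log-linear slope."""
        truth = make_params(sigma=500.0, rho=0.0)
        trace = fm.simulate_transient(truth, protocol)
        _, f = trace.select("induction")
        k = np.arange(1, f.size + 1)
        y = np.log(1 - (f - truth.fo) / (truth.fm - truth.fo))
        sigma_oracle = -np.polyfit(k, y, 1)[0] / protocol.flashlet_dose
        fit = fm.fit_induction(trace, protocol)
        assert fit.rho == pytest.approx(0.0, abs=1e-4)
        assert fit.sigma_psii == pytest.approx(sigma_oracle, rel=5e-3)

    def test_no_rise_is_flagged_failure(self, protocol):
        flat = fm.FluorescenceTrace(
            time_us=protocol.induction_times,
            fluorescence=np.full(40, 300.0),
            phase=np.full(40, "induction", dtype=object))
        with pytest.raises(fm.FitError):
            fm.fit_induction(flat, protocol)

    @pytest.mark.parametrize("scale", [0.01, 3.7])
    def test_scale_invariance(self, protocol, scale):
        """Rescaling fluorescence rescales Fo/Fm but not sigma, rho, tau."""
        truth = make_params()
        trace = fm.simulate_transient(truth, protocol)
        scaled = fm.FluorescenceTrace(time_us=trace.time_us,
                                      fluorescence=trace.fluorescence * scale,
                                      phase=trace.phase)
        base = fm.fit_transient(trace, protocol)
        other = fm.fit_transient(scaled, protocol)
        assert other.fo == pytest.approx(base.fo * scale, rel=1e-6)
        assert other.fm == pytest.approx(base.fm * scale, rel=1e-6)
        assert other.sigma_psii == pytest.approx(base.sigma_psii, rel=1e-6)
        assert other.rho == pytest.approx(base.rho, abs=1e-6)
        assert other.tau1 == pytest.approx(base.tau1, rel=1e-5)


class TestRelaxationFit:
    def test_noiseless_round_trip(self, protocol):
        truth = make_params()
        trace = fm.simulate_transient(truth, protocol)
        fit = fm.fit_transient(trace, protocol)
        assert fit.tau1 == pytest.approx(truth.tau1, rel=1e-4)
        assert fit.tau2 == pytest.approx(truth.tau2, rel=1e-4)
        assert fit.amp1 == pytest.approx(truth.amp1, abs=1e-5)

    def test_single_lifetime_truth_degrades_with_flag(self, protocol):
        truth = make_params(amp1=1.0, tau1=2000.0, tau2=400.0)
        trace = fm.simulate_transient(truth, protocol)
        fit = fm.fit_transient(trace, protocol)
        assert "single_exponential" in fit.flags
        assert fit.amp1 == 1.0
        assert fit.tau1 == pytest.approx(2000.0, rel=1e-4)

    def test_lifetimes_ordered_slow_first(self, protocol):
        truth = make_params()
        fit = fm.fit_transient(fm.simulate_transient(truth, protocol), protocol)
        assert fit.tau1 > fit.tau2


class TestWeightedTau:
    def test_hand_weighted_mean(self):
        fit = make_params(tau1=800.0, tau2=400.0, amp1=0.5)
        assert fm.weighted_tau(fit) == pytest.approx(600.0)

    def test_pure_slow_component(self):
        assert fm.weighted_tau(make_params(tau1=900.0, amp1=1.0)) == 900.0

    def test_equal_lifetimes_amplitude_independent(self):
        a = fm.weighted_tau(make_params(tau1=500.0001, tau2=500.0, amp1=0.2))
        b = fm.weighted_tau(make_params(tau1=500.0001, tau2=500.0, amp1=0.9))
        assert a == pytest.approx(b, rel=1e-6)


class TestLightCurve:
    def test_dark_level_recovers_dark_state(self, protocol, tp_replete):
        fits = fm.run_light_curve(tp_replete, protocol)
        dark = fits[0.0]["main"]
        assert dark.fo == pytest.approx(tp_replete.fo, rel=1e-6)
        assert dark.fm == pytest.approx(tp_replete.fm, rel=1e-6)

    def test_steady_state_bounded_by_fo_and_fm_prime(self, tp_replete):
        for level in (8.0, 85.0, 600.0):
            truth = synthetic.light_response(tp_replete, level)
            assert tp_replete.fo <= truth.fs <= truth.fm_prime

    def test_low_actinic_sigma_reflects_quenching_state(self, scenarios):
        """sigma' at 8 vs 21 umol differs exactly as the NPQ state dictates."""
        st = scenarios["Ot"].phase("late_stationary")   # strong NPQ induction
        s8 = synthetic.light_response(st, 8.0).sigma_prime
        s21 = synthetic.light_response(st, 21.0).sigma_prime
        assert s8 > s21                                  # more quenching at 21
        quiet = scenarios["Ot"].phase("replete")         # no NPQ: no difference
        q8 = synthetic.light_response(quiet, 8.0).sigma_prime
        q21 = synthetic.light_response(quiet, 21.0).sigma_prime
        assert q8 == pytest.approx(q21, rel=1e-12)
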