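"""Derived-parameter tests: hand-computed oracles and partition properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from frrphys import photoparams as pp
from frrphys import pipeline, synthetic


def make_state(fo=200.0, fm=500.0, fs=270.0, fm_prime=450.0,
               fm_prime_1s=500.0, fo_prime_1s=100.0,
               sigma_prime=500.0, sigma_prime_1s=400.0, rho_prime=0.3,
               irradiance=85.0, **kw):
    return pp.FluorescenceState(
        fo=fo, fm=fm, fs=fs, fm_prime=fm_prime,
        fm_prime_1s=fm_prime_1s, fo_prime_1s=fo_prime_1s,
        sigma_prime=sigma_prime, sigma_prime_1s=sigma_prime_1s,
        rho_prime=rho_prime, growth_irradiance=irradiance, **kw)


class TestScalarDerivations:
    def test_fv_fm_hand_value(self):
        assert pp.fv_fm(make_state(fo=200, fm=500)) == pytest.approx(0.60)

    def test_fv_fm_limits(self):
        assert pp.fv_fm(make_state(fo=499.9999, fm=500)) == pytest.approx(0, abs=1e-6)
        assert pp.fv_fm(make_state(fo=1e-9, fm=500)) == pytest.approx(1, abs=1e-9)
        with pytest.raises(ValueError):
            pp.fv_fm(make_state(fo=500, fm=500))

    def test_fo_prime_hand_value(self):
        state = make_state(fo_prime_1s=100, fm_prime_1s=500, fm_prime=450)
        value, flags = pp.fo_prime(state)
        assert value == pytest.approx(90.0)
        assert flags == []

    def test_fo_prime_without_relaxation_equals_fo_prime_1s(self):
        state = make_state(fo_prime_1s=120, fm_prime_1s=450, fm_prime=450)
        value, _ = pp.fo_prime(state)
        assert value == pytest.approx(120.0)

    def test_fo_prime_unrelaxed_quenching_flagged(self):
        state = make_state(fm_prime_1s=400, fm_prime=450)
        value, flags = pp.fo_prime(state)
        assert "quenching_not_relaxed" in flags
        assert value == pytest.approx(100 * 450 / 400)

    def test_qp_hand_and_endpoints(self):
        state = make_state(fm_prime=450, fs=270, fo_prime_1s=100,
                           fm_prime_1s=500)
        value, flags = pp.qp(state, fo_p=90.0)
        assert value == pytest.approx(0.5)
        assert pp.qp(make_state(fs=90), fo_p=90.0)[0] == pytest.approx(1.0)
        assert pp.qp(make_state(fs=450), fo_p=90.0)[0] == pytest.approx(0.0)

    def test_qp_out_of_range_clipped_and_flagged(self):
        value, flags = pp.qp(make_state(fs=80), fo_p=90.0)
        assert value == 1.0 and "qp_clipped" in flags
        with pytest.raises(ValueError):
            pp.qp(make_state(fm_prime=90), fo_p=90.0)

    def test_etr_unit_conversion_hand_value(self):
        """sigma'=500 A^2, I=85 umol m-2 s-1, qP=0.5 -> ~128 e- PSII^-1 s^-1."""
        state = make_state(sigma_prime=500, irradiance=85)
        assert pp.etr(state, 0.5) == pytest.approx(128.0, rel=1e-3)
        assert pp.etr(state, 0.0) == 0.0

    def test_etr_linear_in_irradiance(self):
        lo = pp.etr(make_state(irradiance=85), 0.5)
        hi = pp.etr(make_state(irradiance=170), 0.5)
        assert hi == pytest.approx(2 * lo)

    def test_psii_active_hand_value_and_dilution_invariance(self):
        state = make_state(fo_prime_1s=120, sigma_prime_1s=400)
        vol, cell = pp.psii_active(state, cell_density=1e5)
        assert vol == pytest.approx(0.30)
        # dilution scales Fo'_1s and density together: per-cell quota invariant
        diluted = make_state(fo_prime_1s=60, sigma_prime_1s=400)
        _, cell2 = pp.psii_active(diluted, cell_density=5e4)
        assert cell2 == pytest.approx(cell)

    def test_yields_hand_value(self):
        phi_psii, phi_no, phi_npq, flags = pp.yields(
            make_state(fm=500, fm_prime=400, fs=240))
        assert phi_psii == pytest.approx(0.40)
        assert phi_no == pytest.approx(0.48)
        assert phi_npq == pytest.approx(0.12)
        assert flags == []

    def test_yields_no_quenching_case(self):
        """Fm'=Fm and Fs=Fo: Phi_PSII = Fv/Fm, Phi_NO = Fo/Fm, Phi_NPQ = 0."""
        phi_psii, phi_no, phi_npq, _ = pp.yields(
            make_state(fo=200, fm=500, fm_prime=500, fs=200))
        assert phi_psii == pytest.approx(0.6)
        assert phi_no == pytest.approx(0.4)
        assert phi_npq == pytest.approx(0.0, abs=1e-12)

    def test_yields_flag_out_of_range_without_clipping(self):
        # inconsistent Fm' > Fm makes Phi_NPQ negative; reported as computed
        phi_psii, phi_no, phi_npq, flags = pp.yields(
            make_state(fm=400, fm_prime=500, fs=200))
        assert phi_npq < 0
        assert "phi_npq_out_of_range" in flags


class TestPartitionProperties:
    @given(fm=st.floats(100, 1000), q=st.floats(0.01, 1.0),
           c=st.floats(0.0, 1.0))
    @settings(max_examples=60, deadline=None)
    def test_partition_closure_everywhere(self, fm, q, c):
        """Phi_PSII + Phi_NO + Phi_NPQ = 1 for any consistent state."""
        fm_prime = fm * q
        fs = fm_prime * (0.2 + 0.8 * c)
        phi = pp.yields(make_state(fo=fs * 0.5, fm=fm, fm_prime=fm_prime, fs=fs))
        assert phi[0] + phi[1] + phi[2] == pytest.approx(1.0, abs=1e-12)

    def test_increasing_fs_moves_yields_monotonically(self):
        qs, psis, nos = [], [], []
        for fs in (100.0, 200.0, 300.0, 400.0):
            state = make_state(fs=fs)
            qs.append(pp.qp(state, fo_p=90.0)[0])
            phi = pp.yields(state)
            psis.append(phi[0])
            nos.append(phi[1])
        assert np.all(np.diff(qs) < 0)
        assert np.all(np.diff(psis) < 0)
        assert np.all(np.diff(nos) > 0)


class TestErrorPropagation:
    def test_zero_fit_se_returns_replicate_se(self):
        se, flags = pp.propagate_se(lambda a, b: a / b, {"a": 2.0, "b": 4.0},
                                    fit_ses=None, replicate_se=0.7)
        assert se == pytest.approx(0.7)
        assert "no_fit_se" in flags

    def test_delta_method_matches_monte_carlo_for_ratio(self):
        """SE of a/b via the delta method vs simulation, CV 5% inputs."""
        rng = np.random.default_rng(42)
        a, b, cv = 10.0, 4.0, 0.05
        draws = rng.normal(a, a * cv, 200_000) / rng.normal(b, b * cv, 200_000)
        mc = draws.std()
        se, _ = pp.propagate_se(lambda a, b: a / b, {"a": a, "b": b},
                                {"a": a * cv, "b": b * cv})
        assert se == pytest.approx(mc, rel=0.05)

    def test_sources_combine_in_quadrature(self):
        se, _ = pp.propagate_se(lambda x: x, {"x": 1.0}, {"x": 3.0},
                                replicate_se=4.0)
        assert se == pytest.approx(5.0)


class TestAgainstScenarioTruth:
    @pytest.mark.parametrize("preset", synthetic.PRESET_NAMES)
    def test_noiseless_pipeline_equals_analytic_truth(self, scenarios,
                                                      protocol, preset):
        """Fit-then-derive on noiseless traces reproduces the analytic values."""
        scn = scenarios[preset]
        for phase in ("replete", "late_stationary"):
            state = scn.phase(phase)
            fitted = pipeline.derive_fluorescence_state(state, protocol)
            truth = synthetic.true_fluorescence_state(state)
            got = pp.derive(fitted, cell_density=state.cell_density)
            want = pp.derive(truth, cell_density=state.cell_density)
            for attr in ("fv_fm", "fo_prime", "qp", "etr", "psii_active",
                         "phi_psii", "phi_no", "phi_npq", "sigma_prime"):
                assert getattr(got, attr) == pytest.approx(
                    getattr(want, attr), rel=1e-4), (preset, phase, attr)
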