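"""Forward model and inverse estimators of the efflux-kinetics module."""

import numpy as np
import pytest
from scipy.optimize import brentq

from pgpkit.kinetics import (
    AssayConditions,
    FluorescenceTrace,
    KineticsError,
    TransportParams,
    analyze_trace,
    concentrations_from_trace,
    estimate_active_efflux,
    estimate_initial_influx,
    inhibition_ratio,
    simulate_concentrations,
    simulate_uptake,
)
from pgpkit.synthetic import UptakeSpec, gen_uptake_trace

from conftest import K_ACT_RHO_GRID, K_PLUS_RHO_GRID, params_for, plateau_trace

GRID = np.arange(0.0, 2001.0)


class TestForwardModel:
    def test_no_permeation_means_flat_trace(self, conditions, rho):
        params = params_for(0.0, 4.8e-3, rho)
        trace = simulate_uptake(params, conditions, GRID, permeabilization_time=None)
        assert np.allclose(trace.intensities, trace.intensities[0], atol=1e-9)
        conc = simulate_concentrations(params, conditions, GRID)
        assert np.allclose(conc[:, 2], 0.0, atol=1e-6)

    @pytest.mark.parametrize("kpr,kar", [(1.6e-3, 0.0), (1.6e-3, 4.8e-3), (2.7e-3, 1.6e-3)])
    def test_mass_conservation(self, conditions, rho, kpr, kar):
        conc = simulate_concentrations(
            params_for(kpr, kar, rho), conditions, GRID, permeabilization_time=1600.0
        )
        total = conc.sum(axis=1)
        assert np.all(np.abs(total - conditions.total_drug) <= 1e-6 * conditions.total_drug)

    def test_monotone_decline_to_steady_state(self, conditions, rho):
        trace = simulate_uptake(
            params_for(2.2e-3, 3.2e-3, rho), conditions, GRID, permeabilization_time=1600.0
        )
        pre = trace.intensities[trace.times <= 1600.0]
        assert np.all(np.diff(pre) <= 1e-9)

    def test_steady_state_matches_rootfinding_oracle(self, conditions):
        # independent oracle: solve the stationarity equations of the
        # three-pool model directly (pump balance + binding equilibrium +
        # mass balance), then compare with the integrated trajectory.
        rho = conditions.cell_density
        phi = conditions.cytosol_fraction
        ct = conditions.total_drug
        params = TransportParams(
            k_plus=2e-3 / rho, k_act=4e-3 / rho, k_on=1e-4, k_off=1e-3, b_max=600.0
        )
        kp, ka = 2e-3, 4e-3

        def resid(cc):
            c_e = cc * (kp + ka) / kp  # kp (C_e - cc) = ka cc
            c_n = params.k_on * cc * params.b_max / (params.k_off + params.k_on * cc)
            return c_e + phi * cc + c_n - ct

        cc = brentq(resid, 0.0, ct, xtol=1e-12)
        c_n_expected = params.k_on * cc * params.b_max / (params.k_off + params.k_on * cc)

        grid = np.arange(0.0, 20001.0, 10.0)  # slow binding: run well past 1600 s
        conc = simulate_concentrations(params, conditions, grid)
        assert conc[-1, 2] == pytest.approx(c_n_expected, rel=1e-4)

    def test_permeabilization_releases_more_drug_to_dna(self, conditions, rho):
        conc = simulate_concentrations(
            params_for(1.6e-3, 4.8e-3, rho), conditions, GRID, permeabilization_time=1600.0
        )
        c_n_ss = conc[GRID == 1600.0, 2][0]
        assert conc[-1, 2] > c_n_ss  # pump gone: nuclear pool grows

    def test_invalid_inputs_raise(self, conditions, rho):
        with pytest.raises(KineticsError):
            simulate_concentrations(params_for(1.6e-3, 0, rho), conditions, [0.0, 0.0, 1.0])
        with pytest.raises(KineticsError):
            TransportParams(k_plus=float("nan"), k_act=0.0)
        with pytest.raises(KineticsError):
            TransportParams(k_plus=-1e-12, k_act=0.0)


class TestConcentrationsFromTrace:
    def test_printed_formula(self, conditions):
        est = concentrations_from_trace(plateau_trace(100.0, 70.0), conditions)
        assert est.C_n == pytest.approx(300.0)

    def test_no_quenching_means_nothing_bound(self, conditions):
        est = concentrations_from_trace(plateau_trace(100.0, 100.0), conditions)
        assert est.C_n == pytest.approx(0.0)

    def test_full_quenching_after_triton(self):
        # FN at background level: everything intercalated
        cond = AssayConditions(background_intensity=5.0)
        est = concentrations_from_trace(
            plateau_trace(100.0, 70.0, 0.0, background=5.0), cond
        )
        assert est.FN == pytest.approx(0.0)
        assert est.C_N == pytest.approx(cond.total_drug)

    def test_background_subtraction(self):
        cond = AssayConditions(background_intensity=10.0)
        trace = plateau_trace(100.0, 70.0, background=10.0)
        est = concentrations_from_trace(trace, cond)
        assert est.F0 == pytest.approx(100.0)
        assert est.C_n == pytest.approx(300.0)

    def test_missing_markers_are_named(self, conditions):
        trace = plateau_trace(100.0, 70.0)
        del trace.events["steady_state_window"]
        with pytest.raises(KineticsError, match="steady_state_window"):
            concentrations_from_trace(trace, conditions)

    def test_clamping_warns(self, conditions):
        # Fn above F0 pushes C_n negative
        trace = plateau_trace(100.0, 120.0)
        with pytest.warns(UserWarning, match="clamped"):
            est = concentrations_from_trace(trace, conditions)
        assert est.C_n == 0.0


class TestInitialInflux:
    def test_flat_trace_returns_zero_with_warning(self, conditions):
        trace = plateau_trace(100.0, 100.0)
        with pytest.warns(UserWarning, match="flat"):
            v_plus, k_plus = estimate_initial_influx(trace, conditions)
        assert v_plus == 0.0 and k_plus == 0.0

    def test_noise_free_recovery_within_2pct(self, conditions, rho):
        params = params_for(1.6e-3, 4.8e-3, rho)
        trace, _ = gen_uptake_trace(UptakeSpec(params=params, noise_sd=0.0))
        _, k_plus = estimate_initial_influx(trace, conditions)
        assert k_plus == pytest.approx(params.k_plus, rel=0.02)

    def test_noisy_recovery_within_10pct(self, conditions, rho):
        params = params_for(1.6e-3, 4.8e-3, rho)
        trace, _ = gen_uptake_trace(UptakeSpec(seed=7, params=params, noise_sd=0.5))
        _, k_plus = estimate_initial_influx(trace, conditions)
        assert k_plus == pytest.approx(params.k_plus, rel=0.10)

    def test_window_shorter_than_subwindow(self, conditions):
        with pytest.raises(KineticsError):
            estimate_initial_influx(plateau_trace(100, 70), conditions, window=5.0)


class TestActiveEfflux:
    def test_linear_isotherm_closure(self, conditions):
        est = concentrations_from_trace(plateau_trace(100.0, 70.0, 40.0), conditions)
        assert (est.C_n, est.C_N) == (pytest.approx(300.0), pytest.approx(600.0))
        full = estimate_active_efflux(est, conditions, k_plus=1e-12)
        assert full.C_i == pytest.approx(300.0 * 400.0 / 600.0)  # 200 nM
        assert full.C_e_ss == pytest.approx(700.0)

    def test_no_pump_means_equilibrated_free_drug(self, conditions, rho):
        # without active efflux the free pools equalize; probe the closure on
        # a record long enough to actually reach steady state
        params = params_for(1.6e-3, 0.0, rho)
        trace, _ = gen_uptake_trace(
            UptakeSpec(params=params, noise_sd=0.0, t_end=6000.0, t_perm=5000.0)
        )
        est = analyze_trace(trace, conditions)
        assert est.C_i == pytest.approx(est.C_e_ss, rel=0.03)
        assert abs(est.V_a) < 0.02 * est.V_plus

    def test_recovery_monotone_in_pump_strength(self, conditions, rho):
        estimates = []
        for kar in (1e-3, 2e-3, 4e-3, 8e-3):
            params = params_for(2e-3, kar, rho)
            trace, _ = gen_uptake_trace(UptakeSpec(params=params, noise_sd=0.0))
            est = analyze_trace(trace, conditions)
            assert est.k_a == pytest.approx(params.k_act, rel=0.10)
            estimates.append(est.k_a)
        assert np.all(np.diff(estimates) > 0)

    def test_missing_permeabilization_is_an_error(self, conditions):
        est = concentrations_from_trace(plateau_trace(100.0, 70.0), conditions)
        with pytest.raises(KineticsError, match="C_n and C_N"):
            estimate_active_efflux(est, conditions, k_plus=1e-12)


class TestInhibitionRatio:
    def test_anchors(self):
        assert inhibition_ratio(0.0, 2.9e-9).ratio == 0.0
        assert inhibition_ratio(2.9e-9, 2.9e-9).ratio == 1.0

    def test_printed_coefficients(self):
        # k_a at 50 ug/mL inhibitor vs control
        assert inhibition_ratio(1.06e-9, 2.9e-9).ratio == pytest.approx(0.366, abs=5e-4)

    def test_invalid_control(self):
        with pytest.raises(KineticsError):
            inhibition_ratio(1.0e-9, 0.0)

    @pytest.mark.parametrize("scale", [0.5, 3.0])
    def test_ratio_is_intensity_scale_invariant(self, conditions, rho, scale):
        cond_scaled = conditions
        traces = {}
        for label, kar in (("control", 4.8e-3), ("inhibited", 1.6e-3)):
            trace, _ = gen_uptake_trace(
                UptakeSpec(params=params_for(2.2e-3, kar, rho), noise_sd=0.0)
            )
            traces[label] = trace
        r_ref = (
            analyze_trace(traces["inhibited"], conditions).k_a
            / analyze_trace(traces["control"], conditions).k_a
        )
        scaled = {
            k: FluorescenceTrace(t.times, t.intensities * scale, dict(t.events))
            for k, t in traces.items()
        }
        r_scaled = (
            analyze_trace(scaled["inhibited"], cond_scaled).k_a
            / analyze_trace(scaled["control"], cond_scaled).k_a
        )
        assert r_scaled == pytest.approx(r_ref, rel=1e-6)


def test_full_pipeline_round_trip_grid(conditions, rho):
    """Noise-free round trip: both coefficients within 10% across the grid."""
    for kpr in K_PLUS_RHO_GRID:
        for kar in K_ACT_RHO_GRID:
            params = params_for(kpr, kar, rho)
            trace, _ = gen_uptake_trace(UptakeSpec(params=params, noise_sd=0.0))
            est = analyze_trace(trace, conditions)
            assert est.k_plus == pytest.approx(params.k_plus, rel=0.10)
            assert est.k_a == pytest.approx(params.k_act, rel=0.10)
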