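"""Measurement-chain tests: IV extraction, subtraction, conductance,
Boltzmann fitting (incl. a brute-force grid-search oracle), capacitance,
Ba2+ decomposition, classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rodmg import (CellRecord, Condition, GVCurve, SteadyStateIV, SweepSet,
                   VoltageProtocol, ba_decomposition, boltzmann,
                   capacitance_from_transient, classify_cell,
                   conductance_from_iv, fit_boltzmann, normalize_gmax,
                   simulate_cap_test, simulate_vclamp, steady_state_iv,
                   subtract_conditions)
from rodmg.ephys import _initial_guess

from conftest import make_cell


def flat_sweepset(value_pa, step_mv=-120.0, step_ms=2000.0):
    protocol = VoltageProtocol(step_mvs=(step_mv,), step_ms=step_ms,
                               pre_ms=0.0, post_ms=0.0, filter_hz=None)
    t = protocol.time_ms()
    return SweepSet("t", Condition("highK"), protocol, t,
                    np.full((1, t.size), float(value_pa)))


class TestSteadyStateIV:
    def test_mean_of_constant_trace(self):
        iv = steady_state_iv(flat_sweepset(-50.0), 200.0)
        assert iv.currents[0] == -50.0

    def test_zero_traces_give_zero_iv(self):
        iv = steady_state_iv(flat_sweepset(0.0), 200.0)
        assert np.all(iv.currents == 0.0)

    def test_exponential_trace_matches_analytic_integral(self):
        """I(t) = -100 (1 - e^{-t/200 ms}); the mean over the last 200 ms of a
        2000 ms step has the closed form -100 + 100*(tau/W)(e^-9 - e^-10)."""
        protocol = VoltageProtocol(step_mvs=(-120.0,), step_ms=2000.0,
                                   pre_ms=0.0, post_ms=0.0, filter_hz=None)
        t = protocol.time_ms()
        trace = -100.0 * (1.0 - np.exp(-t / 200.0))
        sw = SweepSet("t", Condition("highK"), protocol, t, trace[None, :])
        iv = steady_state_iv(sw, 200.0)
        expected = -100.0 + 100.0 * (200.0 / 200.0) * (math.exp(-9) - math.exp(-10))
        assert iv.currents[0] == pytest.approx(expected, abs=1e-3)

    def test_window_longer_than_step_rejected(self):
        with pytest.raises(ValueError, match="window_ms"):
            steady_state_iv(flat_sweepset(-50.0, step_ms=100.0), 200.0)


class TestSubtractConditions:
    def test_identical_inputs_cancel(self):
        iv = SteadyStateIV([-60, -120], [-10.0, -100.0], 200.0, "highK")
        out = subtract_conditions(iv, iv)
        assert np.all(out.currents == 0.0)

    def test_arithmetic(self):
        a = SteadyStateIV([-120.0], [-120.0], 200.0, "highK")
        b = SteadyStateIV([-120.0], [-20.0], 200.0, "highK_Cs")
        assert subtract_conditions(a, b).currents[0] == -100.0

    def test_mismatched_grids_rejected(self):
        a = SteadyStateIV([-60.0, -120.0], [0.0, 0.0], 200.0, "highK")
        b = SteadyStateIV([-60.0, -100.0], [0.0, 0.0], 200.0, "highK_Cs")
        with pytest.raises(ValueError, match="grids"):
            subtract_conditions(a, b)

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(-500, 500), min_size=1, max_size=6),
           st.floats(0.1, 10))
    def test_antisymmetry_and_scaling(self, currents, k):
        """a-b = -(b-a), and subtraction distributes over scaling both inputs."""
        v = np.arange(len(currents), dtype=float) - 130.0
        a = SteadyStateIV(v, currents, 200.0, "a")
        b = SteadyStateIV(v, np.arange(len(currents), dtype=float), 200.0, "b")
        ab = subtract_conditions(a, b).currents
        ba = subtract_conditions(b, a).currents
        assert np.allclose(ab, -ba)
        ka = SteadyStateIV(v, k * a.currents, 200.0, "a")
        kb = SteadyStateIV(v, k * b.currents, 200.0, "b")
        assert np.allclose(subtract_conditions(ka, kb).currents, k * ab, rtol=1e-9)


class TestConductance:
    def test_zero_current_gives_zero_conductance(self):
        iv = SteadyStateIV([-60.0, -120.0], [0.0, 0.0], 200.0, "d")
        gv = conductance_from_iv(iv, -30.0)
        assert np.all(gv.g_hyp == 0.0)

    def test_driving_force_arithmetic(self):
        iv = SteadyStateIV([-120.0], [-90.0], 200.0, "d")
        assert conductance_from_iv(iv, -30.0).g_hyp[0] == pytest.approx(1.0)

    def test_zero_driving_force_rejected(self):
        iv = SteadyStateIV([-30.0, -120.0], [0.0, -90.0], 200.0, "d")
        with pytest.raises(ValueError, match="driving force"):
            conductance_from_iv(iv, -30.0)

    def test_reversal_mismatch_scales_by_driving_force_ratio(self):
        """With the analysis reversal fixed at -30 mV but a true reversal of
        -20 mV, G(V) = g_max * m_inf(V) * (V + 20)/(V + 30) (closed form)."""
        cell = make_cell(g_hcn=1.0, e_rev=-20.0, leak=0.0)
        protocol = VoltageProtocol(filter_hz=None)
        a = steady_state_iv(simulate_vclamp(cell, protocol, Condition("highK"), 0.0))
        b = steady_state_iv(simulate_vclamp(cell, protocol, Condition("highK_Cs"), 0.0))
        gv = conductance_from_iv(subtract_conditions(a, b), -30.0)
        for v, g in zip(gv.voltages, gv.g_hyp):
            m = 1.0 / (1.0 + np.exp(-(v + 90.0) / -8.0))
            expected = 1.0 * m * (v + 20.0) / (v + 30.0)
            assert g == pytest.approx(expected, rel=5e-3)


def grid_search_boltzmann(v, g):
    """Brute-force fitter: exhaustive grid over (g_max, v_half, slope)."""
    g_maxs = np.linspace(0.5 * g.max(), 1.5 * g.max(), 41)
    v_halfs = np.arange(-130.0, -50.0, 0.5)
    slopes = np.arange(-20.0, -2.0, 0.25)
    best, best_ss = None, np.inf
    for gm in g_maxs:
        pred = gm / (1.0 + np.exp(-(v[None, None, :] - v_halfs[:, None, None])
                                  / slopes[None, :, None]))
        ss = ((pred - g) ** 2).sum(axis=-1)
        i, j = np.unravel_index(np.argmin(ss), ss.shape)
        if ss[i, j] < best_ss:
            best_ss = ss[i, j]
            best = (gm, v_halfs[i], slopes[j])
    return best, best_ss


class TestBoltzmannFit:
    GRID = np.array([-40.0, -60.0, -80.0, -100.0, -120.0])

    def test_exact_recovery_on_model_data(self):
        g = boltzmann(self.GRID, 1.0, -90.0, -8.0)
        fit = fit_boltzmann(GVCurve(self.GRID, g))
        assert fit.converged
        assert fit.g_max == pytest.approx(1.0, rel=1e-6)
        assert fit.v_half == pytest.approx(-90.0, rel=1e-6)
        assert fit.slope == pytest.approx(-8.0, rel=1e-6)

    def test_midpoint_identity(self):
        g = boltzmann(self.GRID, 2.0, -85.0, -10.0) + 0.01 * np.cos(self.GRID)
        fit = fit_boltzmann(GVCurve(self.GRID, g))
        assert boltzmann(fit.v_half, fit.g_max, fit.v_half, fit.slope) \
            == pytest.approx(fit.g_max / 2.0)

    def test_invariant_to_voltage_ordering(self):
        rng = np.random.default_rng(3)
        g = boltzmann(self.GRID, 1.0, -90.0, -8.0) + rng.normal(0, 0.02, 5)
        f1 = fit_boltzmann(GVCurve(self.GRID, g))
        perm = [3, 0, 4, 1, 2]
        f2 = fit_boltzmann(GVCurve(self.GRID[perm], g[perm]))
        assert f1.g_max == pytest.approx(f2.g_max, rel=1e-9)
        assert f1.v_half == pytest.approx(f2.v_half, rel=1e-9)

    def test_all_zero_conductance_degenerate(self):
        fit = fit_boltzmann(GVCurve(self.GRID, np.zeros(5)))
        assert fit.g_max == 0.0 and fit.converged
        assert fit.v_half is None and fit.slope is None

    def test_fewer_than_three_points_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            fit_boltzmann(GVCurve(np.array([-60.0, -120.0]), np.array([0.1, 0.9])))

    def test_initial_guess_tie_breaks_hyperpolarized(self):
        # two points equidistant from half-max: pick the more negative voltage
        v = np.array([-120.0, -90.0, -80.0, -40.0])
        g = np.array([1.0, 0.5, 0.5, 0.0])
        g0, v0, s0 = _initial_guess(v, g)
        assert v0 == -90.0 and g0 == 1.0 and s0 == -8.0

    def test_evaluator_bounded_and_monotone(self):
        fit = fit_boltzmann(GVCurve(self.GRID, boltzmann(self.GRID, 1.0, -90.0, -8.0)))
        vv = np.linspace(-140, 0, 300)
        gg = fit(vv)
        assert np.all((gg >= 0) & (gg <= fit.g_max))
        assert np.all(np.diff(gg) <= 1e-12)  # slope < 0: decreasing in V

    def test_noisy_recovery_vs_grid_search_oracle(self):
        """Seeded noisy replicates: the least-squares fit must do at least as
        well as an exhaustive grid search on the same data, and its median
        parameter errors stay within the grid-established tolerances."""
        rng = np.random.default_rng(11)
        true = (1.0, -90.0, -8.0)
        clean = boltzmann(self.GRID, *true)
        driving = self.GRID + 30.0
        lm_err, grid_err = [], []
        for _ in range(40):
            noise_pa = rng.normal(0, 2.0 / math.sqrt(200), size=5)
            g = clean + noise_pa / driving
            fit = fit_boltzmann(GVCurve(self.GRID, g))
            (gm, vh, sl), ss_grid = grid_search_boltzmann(self.GRID, g)
            assert fit.residual_ss <= ss_grid + 1e-12
            lm_err.append([abs(fit.g_max - 1), abs(fit.v_half + 90), abs(fit.slope + 8)])
            grid_err.append([abs(gm - 1), abs(vh + 90), abs(sl + 8)])
        lm_med = np.median(lm_err, axis=0)
        grid_med = np.median(grid_err, axis=0)
        resolution = np.array([0.025, 0.5, 0.25])  # grid step sizes
        assert np.all(lm_med <= grid_med + resolution)


class TestCapacitance:
    def test_known_area_identity(self):
        """A transient of area 100 fC over a 20 mV step is a 5 pF cell."""
        protocol = VoltageProtocol(step_mvs=(-20.0,), step_ms=25.0, pre_ms=5.0,
                                   post_ms=5.0, sample_rate_hz=50_000.0,
                                   filter_hz=None)
        t = protocol.time_ms()
        tau = 0.3
        trace = np.zeros_like(t)
        on = t >= 5.0
        trace[on] = (100.0 / tau) * np.exp(-(t[on] - 5.0) / tau)
        est = capacitance_from_transient(
            SweepSet("t", Condition("highK"), protocol, t, trace[None, :]))
        assert est.cm_pf == pytest.approx(5.0, rel=5e-3)
        assert est.cm_pf == est.delta_q_fc / est.delta_v_mv
        assert est.settled

    @pytest.mark.parametrize("cm,rs", [(3.0, 50.0), (5.0, 65.0), (7.0, 80.0)])
    def test_noiseless_round_trip_within_1pct(self, cm, rs):
        cell = make_cell(cm=cm, rs=rs)
        est = capacitance_from_transient(simulate_cap_test(cell, noise_sd_pa=0.0))
        assert est.cm_pf == pytest.approx(cm, rel=0.01)

    def test_flat_zero_trace_flags_unsettled(self):
        protocol = VoltageProtocol(step_mvs=(-20.0,), step_ms=25.0, pre_ms=5.0,
                                   post_ms=5.0, sample_rate_hz=50_000.0,
                                   filter_hz=None)
        t = protocol.time_ms()
        est = capacitance_from_transient(
            SweepSet("t", Condition("highK"), protocol, t, np.zeros((1, t.size))))
        assert est.delta_q_fc == 0.0 and est.cm_pf == 0.0
        assert not est.settled

    def test_unsettled_transient_flagged(self):
        """A transient slower than the step leaves no plateau for the baseline."""
        cell = make_cell(cm=5.0, rs=60.0)
        sw = simulate_cap_test(cell, dur_ms=25.0, noise_sd_pa=0.0)
        # stretch the decay 40x by resampling time: emulate tau ~ 12 ms
        slow = make_cell(cm=5.0, rs=2400.0)
        sw_slow = simulate_cap_test(slow, dur_ms=25.0, noise_sd_pa=0.0)
        assert capacitance_from_transient(sw).settled
        assert not capacitance_from_transient(sw_slow).settled

    def test_normalize_gmax(self):
        from rodmg.model import BoltzmannFit, CapacitanceEstimate
        fit = BoltzmannFit(1.0, -90.0, -8.0, 0.0, True, 5)
        cm = CapacitanceEstimate(100.0, 20.0, 5.0)
        assert normalize_gmax(fit, cm) == pytest.approx(0.2)
        fit0 = BoltzmannFit(0.0, None, None, 0.0, True, 5)
        assert normalize_gmax(fit0, cm) == 0.0
        with pytest.raises(ValueError):
            normalize_gmax(fit, CapacitanceEstimate(0.0, 20.0, 0.0))


class TestBaDecomposition:
    def grids(self, i_k, i_ba, i_ba_cs):
        v = np.array([-120.0])
        mk = lambda i, c: SteadyStateIV(v, [i], 200.0, c)
        return mk(i_k, "highK"), mk(i_ba, "highK_Ba"), mk(i_ba_cs, "highK_Ba_Cs")

    def test_even_split(self):
        d = ba_decomposition(*self.grids(-200.0, -100.0, 0.0), at_mv=-120.0)
        assert d.ba_fraction == pytest.approx(0.5)
        assert d.i_kir_pa == -100.0 and d.i_h_pa == -100.0

    def test_pure_hcn_cell_has_zero_ba_fraction(self, hcn_cell, protocol):
        ivs = [steady_state_iv(simulate_vclamp(hcn_cell, protocol, Condition(c), 0.0))
               for c in ("highK", "highK_Ba", "highK_Ba_Cs")]
        d = ba_decomposition(*ivs)
        assert d.ba_fraction == pytest.approx(0.0, abs=1e-9)

    def test_decomposition_closure(self, hybrid_cell, protocol):
        """i_kir + i_h + I(Ba+Cs) reconstructs the control current exactly."""
        ivs = {c: steady_state_iv(simulate_vclamp(hybrid_cell, protocol, Condition(c), 0.0))
               for c in ("highK", "highK_Ba", "highK_Ba_Cs")}
        d = ba_decomposition(ivs["highK"], ivs["highK_Ba"], ivs["highK_Ba_Cs"])
        i_k_at = ivs["highK"].currents[np.argmin(ivs["highK"].voltages)]
        i_rest = ivs["highK_Ba_Cs"].currents[np.argmin(ivs["highK_Ba_Cs"].voltages)]
        assert d.i_kir_pa + d.i_h_pa + i_rest == pytest.approx(float(i_k_at), rel=1e-12)

    def test_below_noise_floor_indeterminate(self):
        d = ba_decomposition(*self.grids(-0.3, -0.1, 0.0), at_mv=-120.0)
        assert d.indeterminate and d.ba_fraction is None

    def test_outward_component_indeterminate(self):
        d = ba_decomposition(*self.grids(-50.0, -80.0, 0.0), at_mv=-120.0)
        assert d.indeterminate

    def test_mismatched_grids_rejected(self):
        v1 = SteadyStateIV([-120.0], [-100.0], 200.0, "k")
        v2 = SteadyStateIV([-100.0], [-50.0], 200.0, "ba")
        with pytest.raises(ValueError, match="grid"):
            ba_decomposition(v1, v2, v1)


class TestClassification:
    def record(self, g_norm, ba=None):
        return CellRecord("c", 8, "1x", g_norm=g_norm, ba_fraction=ba)

    def test_zero_conductance_is_mg_like(self):
        assert classify_cell(self.record(0.0)) == "mg_like"

    def test_high_conductance_no_kir_is_rod_like(self):
        assert classify_cell(self.record(0.2, ba=0.0)) == "rod_like"

    def test_kir_share_in_band_is_hybrid(self):
        assert classify_cell(self.record(0.2, ba=0.6)) == "hybrid"

    def test_missing_inputs_unclassified(self):
        assert classify_cell(CellRecord("c", 8, "1x")) == "unclassified"

    def test_invariant_to_uniform_rescaling(self, protocol):
        """Scaling all conductances and the capacitance together (a bigger
        cell) leaves g_norm, ba_fraction, and hence the label unchanged."""
        from rodmg.study import analyze_cell
        for k in (1.0, 3.0):
            cell = make_cell(g_hcn=0.25 * k, g_kir=1.0 * k, leak=0.2 * k, cm=2.0 * k)
            sweeps = {c: simulate_vclamp(cell, protocol, Condition(c), 0.0)
                      for c in ("highK", "highK_Cs", "highK_Ba", "highK_Ba_Cs")}
            cap = simulate_cap_test(cell, noise_sd_pa=0.0)
            rec = analyze_cell(sweeps, cap)
            if k == 1.0:
                base = (rec.label, rec.g_norm, rec.ba_fraction)
        assert rec.label == base[0]
        assert rec.g_norm == pytest.approx(base[1], rel=0.02)
        assert rec.ba_fraction == pytest.approx(base[2], rel=0.02)


class TestEndToEndIdentity:
    def test_noiseless_chain_recovers_generative_parameters(self):
        """simulate -> IV -> Cs-subtract -> G(V) -> fit recovers (g_max, v_half,
        slope) to <= 0.5% for tau <= 100 ms (true reversal = analysis reversal)."""
        cell = make_cell(g_hcn=1.3, g_kir=0.0, v_half=-92.0, slope=-7.0,
                         tau_ms=100.0)
        protocol = VoltageProtocol(step_mvs=(-40.0, -60.0, -80.0, -100.0, -120.0))
        a = steady_state_iv(simulate_vclamp(cell, protocol, Condition("highK"), 0.0))
        b = steady_state_iv(simulate_vclamp(cell, protocol, Condition("highK_Cs"), 0.0))
        fit = fit_boltzmann(conductance_from_iv(subtract_conditions(a, b), -30.0))
        assert fit.g_max == pytest.approx(1.3, rel=5e-3)
        assert fit.v_half == pytest.approx(-92.0, rel=5e-3)
        assert fit.slope == pytest.approx(-7.0, rel=5e-3)
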