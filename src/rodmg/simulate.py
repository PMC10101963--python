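"""Synthetic voltage-clamp recordings from parameterized model cells.

The simulator reproduces the acquisition chain of a perforated-patch
experiment on cultured rod precursors: 2 s hyperpolarizing steps from a
-40 mV holding potential, a capacitive transient shaped by series
resistance, an ohmic leak, an instantaneous Ba2+-blockable inward
rectifier (Kir), a first-order HCN gate with Boltzmann steady state,
additive Gaussian recording noise, and an optional second-order low-pass
filter emulating the amplifier's 300 Hz output filter.

All currents follow the physiological sign convention: inward current is
negative.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from scipy import signal

from .model import CellModel, Condition, GatedChannel, SweepSet, VoltageProtocol

__all__ = [
    "nernst_mv",
    "simulate_vclamp",
    "simulate_cap_test",
    "hcn_steady_current",
    "kir_steady_current",
    "leak_current",
]

# Gas-constant voltage RT/F at ~22 C, in mV.
_RT_OVER_F_MV = 25.4


def nernst_mv(c_out: float, c_in: float, z: int = 1, rt_over_f_mv: float = _RT_OVER_F_MV) -> float:
    """Nernst equilibrium potential in mV for an ion at the given activities."""
    if c_out <= 0 or c_in <= 0:
        raise ValueError("concentrations must be positive")
    return rt_over_f_mv / z * math.log(c_out / c_in)


def leak_current(cell: CellModel, v) -> np.ndarray:
    """Ohmic leak current (pA) at voltage(s) v."""
    return cell.leak_conductance * (np.asarray(v, dtype=float) - cell.leak_reversal)


def kir_steady_current(cell: CellModel, v, condition: Condition) -> np.ndarray:
    """Instantaneous inward-rectifier current (pA), blocker-scaled."""
    scale = cell.kir.unblocked_fraction(condition.blockers)
    v = np.asarray(v, dtype=float)
    return scale * cell.kir.g_max * cell.kir.m_inf(v) * (v - cell.kir.e_rev)


def hcn_steady_current(cell: CellModel, v, condition: Condition) -> np.ndarray:
    """Steady-state HCN current (pA), blocker-scaled."""
    scale = cell.hcn.unblocked_fraction(condition.blockers)
    v = np.asarray(v, dtype=float)
    return scale * cell.hcn.g_max * cell.hcn.m_inf(v) * (v - cell.hcn.e_rev)


def _hcn_gate_trace(channel: GatedChannel, t_ms: np.ndarray, protocol: VoltageProtocol,
                    step_mv: float) -> np.ndarray:
    """First-order gate m(t): relaxes exponentially toward m_inf of the local voltage."""
    m_hold = float(channel.m_inf(protocol.holding_mv))
    m_step = float(channel.m_inf(step_mv))
    tau = channel.tau_ms
    t0 = protocol.pre_ms
    t1 = protocol.pre_ms + protocol.step_ms

    m = np.full_like(t_ms, m_hold)
    on = (t_ms >= t0) & (t_ms < t1)
    m[on] = m_step + (m_hold - m_step) * np.exp(-(t_ms[on] - t0) / tau)
    off = t_ms >= t1
    if np.any(off):
        m_end = m_step + (m_hold - m_step) * math.exp(-(t1 - t0) / tau)
        m[off] = m_hold + (m_end - m_hold) * np.exp(-(t_ms[off] - t1) / tau)
    return m


def _voltage_trace(t_ms: np.ndarray, protocol: VoltageProtocol, step_mv: float) -> np.ndarray:
    v = np.full_like(t_ms, protocol.holding_mv)
    on = (t_ms >= protocol.pre_ms) & (t_ms < protocol.pre_ms + protocol.step_ms)
    v[on] = step_mv
    return v


def _capacitive_transient(cell: CellModel, t_ms: np.ndarray, protocol: VoltageProtocol,
                          step_mv: float) -> np.ndarray:
    """Single-exponential charging transients at the step edges.

    Peak amplitude dV/Rs (mV/MOhm = nA, hence the factor 1000 to pA);
    decay tau = Rs * Cm (MOhm * pF = us, hence / 1000 to ms).
    """
    dv = step_mv - protocol.holding_mv
    amp_pa = 1000.0 * dv / cell.rs_mohm
    tau_ms = cell.rs_mohm * cell.cm_pf / 1000.0
    out = np.zeros_like(t_ms)
    t0 = protocol.pre_ms
    t1 = protocol.pre_ms + protocol.step_ms
    on = t_ms >= t0
    out[on] += amp_pa * np.exp(-(t_ms[on] - t0) / tau_ms)
    off = t_ms >= t1
    out[off] += -amp_pa * np.exp(-(t_ms[off] - t1) / tau_ms)
    return out


def _deterministic_sweep(cell: CellModel, protocol: VoltageProtocol, condition: Condition,
                         step_mv: float, t_ms: np.ndarray) -> np.ndarray:
    v = _voltage_trace(t_ms, protocol, step_mv)
    i = _capacitive_transient(cell, t_ms, protocol, step_mv)
    i += leak_current(cell, v)
    i += kir_steady_current(cell, v, condition)
    hcn_scale = cell.hcn.unblocked_fraction(condition.blockers)
    if hcn_scale > 0 and cell.hcn.g_max > 0:
        m = _hcn_gate_trace(cell.hcn, t_ms, protocol, step_mv)
        i += hcn_scale * cell.hcn.g_max * m * (v - cell.hcn.e_rev)
    return i


def _lowpass(currents: np.ndarray, sample_rate_hz: float, cutoff_hz: float) -> np.ndarray:
    """Causal 2nd-order Butterworth low-pass, initialized at the first sample
    to avoid a spurious filter start-up transient."""
    sos = signal.butter(2, cutoff_hz, fs=sample_rate_hz, output="sos")
    zi = signal.sosfilt_zi(sos)
    out = np.empty_like(currents)
    for k in range(currents.shape[0]):
        out[k], _ = signal.sosfilt(sos, currents[k], zi=zi * currents[k, 0])
    return out


def simulate_vclamp(cell: CellModel, protocol: VoltageProtocol, condition: Condition,
                    noise_sd_pa: float = 2.0, seed: Optional[int] = None) -> SweepSet:
    """Simulate one pharmacological condition's full sweep set.

    Each sweep is the sum of a capacitive transient, ohmic leak,
    instantaneous Kir, first-order-gated HCN, and white Gaussian noise,
    optionally low-pass filtered per ``protocol.filter_hz``.  Identical
    seeds give bit-identical output.
    """
    if noise_sd_pa < 0 or not math.isfinite(noise_sd_pa):
        raise ValueError("noise_sd_pa must be finite and >= 0")
    t_ms = protocol.time_ms()
    currents = np.vstack([
        _deterministic_sweep(cell, protocol, condition, v, t_ms)
        for v in protocol.step_mvs
    ])
    if noise_sd_pa > 0:
        rng = np.random.default_rng(seed)
        currents = currents + rng.normal(0.0, noise_sd_pa, size=currents.shape)
    if protocol.filter_hz is not None:
        currents = _lowpass(currents, protocol.sample_rate_hz, protocol.filter_hz)
    return SweepSet(cell_id=cell.cell_id, condition=condition, protocol=protocol,
                    time_ms=t_ms, currents_pa=currents, seed=seed)


def simulate_cap_test(cell: CellModel, dv_mv: float = 20.0, dur_ms: float = 25.0,
                      noise_sd_pa: float = 2.0, seed: Optional[int] = None,
                      sample_rate_hz: float = 50_000.0, n_repeats: int = 16) -> SweepSet:
    """Simulate a capacitance-test step (default +20 mV for 25 ms from -40 mV).

    The transient is sampled wideband (no 300 Hz output filter, fast
    sampling) as capacitance tests are in practice, and ``n_repeats``
    noisy realizations are averaged into the stored trace.  The integral
    of the transient above the post-transient plateau equals Cm * dV.
    """
    if dur_ms <= 0:
        raise ValueError("dur_ms must be > 0")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    protocol = VoltageProtocol(
        holding_mv=-40.0,
        step_mvs=(-40.0 + dv_mv,),
        step_ms=dur_ms,
        pre_ms=5.0,
        post_ms=5.0,
        sample_rate_hz=sample_rate_hz,
        filter_hz=None,
    )
    condition = Condition("highK")
    t_ms = protocol.time_ms()
    clean = _deterministic_sweep(cell, protocol, condition, protocol.step_mvs[0], t_ms)
    if noise_sd_pa > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sd_pa, size=(n_repeats, clean.size)).mean(axis=0)
        trace = clean + noise
    else:
        trace = clean
    return SweepSet(cell_id=cell.cell_id, condition=condition, protocol=protocol,
                    time_ms=t_ms, currents_pa=trace[None, :], seed=seed)
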