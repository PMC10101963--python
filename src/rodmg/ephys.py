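"""Measurement chain from raw voltage-clamp sweeps to cell classification.

Steps, in the order a recording is processed:

1. ``steady_state_iv`` — late-current I/V (mean of the final window of each
   2 s step).
2. ``subtract_conditions`` — pharmacological isolation, e.g. I_HYP as
   (high-K control) minus (high-K + Cs).
3. ``conductance_from_iv`` — G(V) = I / (V - E_HYP) with the analysis
   reversal fixed at -30 mV by convention.
4. ``fit_boltzmann`` — G(V) = G_MAX / (1 + exp(-(V - V_0.5)/S)) by
   least squares; S is the signed inverse slope factor (negative for
   hyperpolarization-activated conductances).
5. ``capacitance_from_transient`` — Cm = dQ/dV by charge integration of the
   capacitance-test transient.
6. ``normalize_gmax`` — G_MAX / Cm, removing cell-size differences.
7. ``ba_decomposition`` — split I_HYP into a Ba2+-sensitive (Kir) and a
   residual Cs-sensitive (HCN) component.
8. ``classify_cell`` — rod-like / MG-like / hybrid call from the
   normalized conductance and the Ba2+-sensitive share.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .model import (BoltzmannFit, CapacitanceEstimate, CellRecord, GVCurve,
                    SteadyStateIV, SweepSet, boltzmann)

__all__ = [
    "steady_state_iv",
    "subtract_conditions",
    "conductance_from_iv",
    "fit_boltzmann",
    "capacitance_from_transient",
    "normalize_gmax",
    "BaDecomposition",
    "ba_decomposition",
    "classify_cell",
    "DEFAULT_E_HYP_MV",
    "DEFAULT_G_NORM_FLOOR",
    "DEFAULT_HYBRID_BAND",
]

DEFAULT_E_HYP_MV = -30.0
#: Below this Cs-sensitive normalized conductance (nS/pF) a cell is called
#: MG-like ("lacking I_HYP").  Roughly a tenth of a typical rod-track value.
DEFAULT_G_NORM_FLOOR = 0.02
#: Ba2+-sensitive share of I_HYP that marks a hybrid cell.
DEFAULT_HYBRID_BAND = (0.15, 1.0)


def steady_state_iv(sweeps: SweepSet, window_ms: float = 200.0) -> SteadyStateIV:
    """Mean current over the final ``window_ms`` of the step, per voltage."""
    protocol = sweeps.protocol
    if window_ms <= 0:
        raise ValueError("window_ms must be > 0")
    if window_ms > protocol.step_ms:
        raise ValueError(
            f"window_ms ({window_ms}) exceeds the step duration ({protocol.step_ms})"
        )
    sl = protocol.step_slice()
    n_window = max(1, int(round(window_ms / protocol.dt_ms)))
    window = sweeps.currents_pa[:, sl.stop - n_window: sl.stop]
    return SteadyStateIV(
        voltages=np.array(protocol.step_mvs, dtype=float),
        currents=window.mean(axis=1),
        window_ms=window_ms,
        condition=sweeps.condition.name,
    )


def subtract_conditions(iv_a: SteadyStateIV, iv_b: SteadyStateIV) -> SteadyStateIV:
    """Element-wise iv_a - iv_b on identical voltage grids (no interpolation)."""
    if iv_a.voltages.shape != iv_b.voltages.shape or np.any(iv_a.voltages != iv_b.voltages):
        raise ValueError("voltage grids differ; refusing to interpolate")
    return SteadyStateIV(
        voltages=iv_a.voltages.copy(),
        currents=iv_a.currents - iv_b.currents,
        window_ms=iv_a.window_ms,
        condition=f"{iv_a.condition}-{iv_b.condition}",
    )


def conductance_from_iv(iv: SteadyStateIV, e_hyp_mv: float = DEFAULT_E_HYP_MV) -> GVCurve:
    """Chord conductance G = I / (V - E_HYP), pA/mV reported as nS."""
    driving = iv.voltages - e_hyp_mv
    if np.any(driving == 0):
        raise ValueError(
            f"zero driving force: a command voltage equals E_HYP = {e_hyp_mv} mV"
        )
    return GVCurve(voltages=iv.voltages.copy(), g_hyp=iv.currents / driving,
                   e_hyp=e_hyp_mv)


def _initial_guess(v: np.ndarray, g: np.ndarray) -> tuple[float, float, float]:
    """g_max0 = max G; v_half0 = voltage nearest half-max (ties toward the
    more hyperpolarized point); slope0 = -8 mV."""
    g_max0 = float(g.max())
    half = g_max0 / 2.0
    dist = np.abs(g - half)
    # v sorted ascending; ties resolved toward the most negative voltage
    v_half0 = float(v[int(np.argmin(dist))])
    return g_max0, v_half0, -8.0


def fit_boltzmann(gv: GVCurve) -> BoltzmannFit:
    """Least-squares Boltzmann fit of a G-V curve.

    Local least squares (trust-region reflective, g_max bounded at 0) from
    the documented deterministic initialization; invariant to the input
    voltage ordering.  All-zero conductance returns a degenerate fit with
    g_max = 0 and v_half / slope marked missing.
    """
    order = np.argsort(gv.voltages)
    v = gv.voltages[order]
    g = gv.g_hyp[order]
    n = len(v)
    if len(np.unique(v)) < 3:
        raise ValueError(f"need >= 3 distinct voltages, got {len(np.unique(v))}")
    if np.allclose(g, 0.0):
        fit = BoltzmannFit(g_max=0.0, v_half=None, slope=None, residual_ss=0.0,
                           converged=True, n_points=n)
        gv.fit = fit
        return fit

    p0 = _initial_guess(v, g)

    def residuals(p):
        return boltzmann(v, *p) - g

    sol = least_squares(residuals, p0, bounds=([0.0, -np.inf, -np.inf],
                                               [np.inf, np.inf, np.inf]),
                        method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
    g_max, v_half, slope = (float(x) for x in sol.x)
    fit = BoltzmannFit(g_max=g_max, v_half=v_half, slope=slope,
                       residual_ss=float(np.sum(sol.fun ** 2)),
                       converged=bool(sol.success), n_points=n)
    gv.fit = fit
    return fit


def capacitance_from_transient(cap_sweeps: SweepSet,
                               baseline_ms: float = 5.0) -> CapacitanceEstimate:
    """Cm = dQ/dV from charge integration of the capacitance-test transient.

    Baseline is the mean of the final ``baseline_ms`` of the step; dQ is the
    trapezoidal integral of (current - baseline) over the step (pA * ms =
    fC, and fC/mV = pF).  Estimates are averaged across repeat traces.  The
    ``settled`` flag is cleared when no transient is detectable or the
    plateau still drifts (baseline window overlapping the transient).
    """
    protocol = cap_sweeps.protocol
    dv = protocol.step_mvs[0] - protocol.holding_mv
    if dv == 0:
        raise ValueError("capacitance test requires a nonzero voltage step")
    sl = protocol.step_slice()
    dt = protocol.dt_ms
    n_base = max(2, int(round(baseline_ms / dt)))

    dqs = []
    settled = True
    for trace in cap_sweeps.currents_pa:
        step = trace[sl]
        baseline = step[-n_base:].mean()
        amp = np.abs(step - baseline).max()
        if amp < 1.0:  # pA; no detectable transient
            settled = False
        elif len(step) >= 2 * n_base:
            prev = step[-2 * n_base: -n_base].mean()
            if abs(prev - baseline) > 0.02 * amp + 0.5:
                settled = False  # plateau still drifting under the baseline window
        dq = float(np.trapezoid(step - baseline, dx=dt))
        dqs.append(dq)
    delta_q = float(np.mean(dqs))
    return CapacitanceEstimate(delta_q_fc=delta_q, delta_v_mv=float(dv),
                               cm_pf=delta_q / float(dv), settled=settled)


def normalize_gmax(fit: BoltzmannFit, cm: CapacitanceEstimate) -> float:
    """Capacitance-normalized maximal conductance G_MAX / Cm (nS/pF)."""
    if cm.cm_pf <= 0:
        raise ValueError(f"cm_pf must be positive, got {cm.cm_pf}")
    return fit.g_max / cm.cm_pf


@dataclass
class BaDecomposition:
    """Ba2+-sensitive (Kir) vs residual Cs-sensitive (HCN) split of I_HYP."""

    i_kir_pa: float
    i_h_pa: float
    ba_fraction: Optional[float]
    indeterminate: bool = False
    reason: str = ""


def ba_decomposition(iv_k: SteadyStateIV, iv_ba: SteadyStateIV,
                     iv_ba_cs: SteadyStateIV, at_mv: Optional[float] = None,
                     noise_floor_pa: float = 1.0) -> BaDecomposition:
    """Decompose the hyperpolarization-activated current at one voltage.

    i_kir = I(control) - I(+Ba) is the Ba2+-sensitive component;
    i_h = I(+Ba) - I(+Ba+Cs) is the residual Cs-sensitive (HCN) component.
    ba_fraction = i_kir / (i_kir + i_h), clamped to [0, 1], defined only
    when both components have the inward (negative) sign; components
    smaller than ``noise_floor_pa`` are treated as absent.  Defaults to the
    most hyperpolarized common voltage, where both components are largest.
    """
    for other in (iv_ba, iv_ba_cs):
        if iv_k.voltages.shape != other.voltages.shape or np.any(iv_k.voltages != other.voltages):
            raise ValueError("the three IV curves must share one voltage grid")
    if at_mv is None:
        at_mv = float(iv_k.voltages.min())
    idx = np.flatnonzero(iv_k.voltages == at_mv)
    if idx.size == 0:
        raise ValueError(f"{at_mv} mV is not on the common voltage grid")
    i = int(idx[0])
    i_kir = float(iv_k.currents[i] - iv_ba.currents[i])
    i_h = float(iv_ba.currents[i] - iv_ba_cs.currents[i])

    k = i_kir if abs(i_kir) >= noise_floor_pa else 0.0
    h = i_h if abs(i_h) >= noise_floor_pa else 0.0
    total = k + h
    if abs(total) < noise_floor_pa:
        return BaDecomposition(i_kir, i_h, None, indeterminate=True,
                               reason="total blocker-sensitive current below noise floor")
    if k > 0 or h > 0:
        return BaDecomposition(i_kir, i_h, None, indeterminate=True,
                               reason="a blocker-sensitive component has the outward sign")
    frac = min(1.0, max(0.0, k / total))
    return BaDecomposition(i_kir, i_h, frac)


def classify_cell(record: CellRecord,
                  g_norm_floor: float = DEFAULT_G_NORM_FLOOR,
                  hybrid_band: tuple[float, float] = DEFAULT_HYBRID_BAND) -> str:
    """Cell-state call from the electrophysiological fingerprint.

    * ``mg_like``  — Cs-sensitive normalized conductance below
      ``g_norm_floor`` ("lacks I_HYP").
    * ``hybrid``   — Ba2+-sensitive share of I_HYP inside ``hybrid_band``.
    * ``rod_like`` — everything else with a measurable conductance.
    * ``unclassified`` — required inputs missing.

    Both thresholds are explicit configuration; the defaults are the
    package's documented choices, expressed per-capacitance so the call is
    invariant to cell size.
    """
    if record.g_norm is None or not math.isfinite(record.g_norm):
        return "unclassified"
    if record.g_norm < g_norm_floor:
        return "mg_like"
    ba = record.ba_fraction
    if ba is not None and hybrid_band[0] <= ba <= hybrid_band[1]:
        return "hybrid"
    return "rod_like"
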