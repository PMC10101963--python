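"""Domain types for the voltage-clamp simulation and analysis pipeline.

Unit conventions used throughout the package (chosen so products need no
conversion factors):

* voltage        mV
* current        pA
* conductance    nS        (nS * mV = pA)
* capacitance    pF
* resistance    MOhm       (MOhm * pF = us; divide by 1000 for ms)
* time           ms
* charge         fC        (pA * ms = fC; fC / mV = pF)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

__all__ = [
    "GatedChannel",
    "CellModel",
    "VoltageProtocol",
    "Condition",
    "CONDITION_BLOCKERS",
    "SweepSet",
    "SteadyStateIV",
    "GVCurve",
    "BoltzmannFit",
    "CapacitanceEstimate",
    "CellRecord",
    "boltzmann",
]


def boltzmann(v, g_max: float, v_half: float, slope: float):
    """Boltzmann activation curve G(V) = g_max / (1 + exp(-(V - v_half)/slope)).

    ``slope`` is the signed inverse slope factor in mV; a negative slope
    yields activation on hyperpolarization (HCN-like), a positive slope
    activation on depolarization.
    """
    v = np.asarray(v, dtype=float)
    return g_max / (1.0 + np.exp(-(v - v_half) / slope))


@dataclass(frozen=True)
class GatedChannel:
    """A voltage-gated conductance with Boltzmann steady-state activation.

    Parameters
    ----------
    g_max : float
        Maximal conductance in nS; must be >= 0.
    v_half : float
        Half-activation voltage in mV.
    slope : float
        Signed inverse slope factor in mV (negative for channels that open
        on hyperpolarization).
    e_rev : float
        Reversal potential in mV.
    tau_ms : float
        Activation time constant in ms (> 0).  Channels treated as
        instantaneous use a small tau and are flagged by the simulator.
    blocker_sensitivity : mapping
        Blocker name -> blocked fraction in [0, 1] when that blocker is
        present in the bath.
    """

    g_max: float
    v_half: float
    slope: float
    e_rev: float
    tau_ms: float = 300.0
    blocker_sensitivity: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not math.isfinite(self.g_max) or self.g_max < 0:
            raise ValueError(f"g_max must be finite and >= 0, got {self.g_max}")
        if self.tau_ms <= 0 or not math.isfinite(self.tau_ms):
            raise ValueError(f"tau_ms must be finite and > 0, got {self.tau_ms}")
        for name in ("v_half", "slope", "e_rev"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.slope == 0:
            raise ValueError("slope must be nonzero")
        for blocker, frac in self.blocker_sensitivity.items():
            if not (0.0 <= frac <= 1.0):
                raise ValueError(
                    f"blocked fraction for {blocker!r} must lie in [0, 1], got {frac}"
                )

    def m_inf(self, v) -> np.ndarray:
        """Steady-state open probability at voltage(s) ``v``."""
        v = np.asarray(v, dtype=float)
        return 1.0 / (1.0 + np.exp(-(v - self.v_half) / self.slope))

    def unblocked_fraction(self, blockers: frozenset[str]) -> float:
        """Fraction of conductance remaining with the given blockers present.

        Independent blockers combine multiplicatively.
        """
        remaining = 1.0
        for blocker in blockers:
            remaining *= 1.0 - self.blocker_sensitivity.get(blocker, 0.0)
        return remaining


@dataclass(frozen=True)
class CellModel:
    """Generative biophysical parameters of one simulated cell.

    ``hcn`` is a slowly gating, Cs-blocked, Ba-insensitive conductance;
    ``kir`` is an instantaneous inward rectifier blocked by both Ba and Cs.
    ``cm_pf`` and ``rs_mohm`` shape the capacitive transient (tau = Rs * Cm).
    """

    hcn: GatedChannel
    kir: GatedChannel
    leak_conductance: float
    leak_reversal: float
    cm_pf: float
    rs_mohm: float
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        if not (self.cm_pf > 0 and math.isfinite(self.cm_pf)):
            raise ValueError(f"cm_pf must be positive, got {self.cm_pf}")
        if not (self.rs_mohm > 0 and math.isfinite(self.rs_mohm)):
            raise ValueError(f"rs_mohm must be positive, got {self.rs_mohm}")
        if self.leak_conductance < 0:
            raise ValueError("leak_conductance must be >= 0")
        if not math.isfinite(self.leak_reversal):
            raise ValueError("leak_reversal must be finite")


@dataclass(frozen=True)
class VoltageProtocol:
    """A step protocol: hold, step to each command voltage, return to hold."""

    holding_mv: float = -40.0
    step_mvs: tuple[float, ...] = (-60.0, -80.0, -100.0, -120.0)
    step_ms: float = 2000.0
    pre_ms: float = 100.0
    post_ms: float = 100.0
    sample_rate_hz: float = 1000.0
    filter_hz: Optional[float] = 300.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "step_mvs", tuple(float(v) for v in self.step_mvs))
        if self.step_ms <= 0:
            raise ValueError("step_ms must be > 0")
        if not self.step_mvs:
            raise ValueError("step_mvs must be non-empty")
        if len(set(self.step_mvs)) != len(self.step_mvs):
            raise ValueError("step_mvs must be distinct")
        if self.filter_hz is not None and self.sample_rate_hz <= 2 * self.filter_hz:
            raise ValueError(
                "sample_rate_hz must exceed 2 * filter_hz when filtering is enabled"
            )
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sample_rate_hz

    @property
    def total_ms(self) -> float:
        return self.pre_ms + self.step_ms + self.post_ms

    def time_ms(self) -> np.ndarray:
        n = int(round(self.total_ms / self.dt_ms))
        return np.arange(n) * self.dt_ms

    def step_slice(self) -> slice:
        """Sample indices covered by the command step."""
        dt = self.dt_ms
        i0 = int(round(self.pre_ms / dt))
        i1 = int(round((self.pre_ms + self.step_ms) / dt))
        return slice(i0, i1)


#: Bath condition name -> set of blockers present.
CONDITION_BLOCKERS: dict[str, frozenset[str]] = {
    "highK": frozenset(),
    "highK_Cs": frozenset({"Cs"}),
    "highK_Ba": frozenset({"Ba"}),
    "highK_Ba_Cs": frozenset({"Ba", "Cs"}),
}


@dataclass(frozen=True)
class Condition:
    """A pharmacological bath condition (high-K saline plus optional blockers)."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in CONDITION_BLOCKERS:
            raise ValueError(
                f"unknown condition {self.name!r}; expected one of "
                f"{sorted(CONDITION_BLOCKERS)}"
            )

    @property
    def blockers(self) -> frozenset[str]:
        return CONDITION_BLOCKERS[self.name]


@dataclass
class SweepSet:
    """One condition's voltage-clamp recording for one cell.

    ``currents_pa`` has shape (n_steps, n_samples) with rows keyed 1:1 to
    ``protocol.step_mvs``.
    """

    cell_id: str
    condition: Condition
    protocol: VoltageProtocol
    time_ms: np.ndarray
    currents_pa: np.ndarray
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.currents_pa = np.atleast_2d(np.asarray(self.currents_pa, dtype=float))
        if self.currents_pa.shape != (len(self.protocol.step_mvs), len(self.time_ms)):
            raise ValueError(
                "currents_pa must have shape (n_steps, n_samples) = "
                f"({len(self.protocol.step_mvs)}, {len(self.time_ms)}), "
                f"got {self.currents_pa.shape}"
            )

    def trace(self, step_mv: float) -> np.ndarray:
        """Current trace for one command voltage."""
        for i, v in enumerate(self.protocol.step_mvs):
            if v == step_mv:
                return self.currents_pa[i]
        raise KeyError(f"no sweep at {step_mv} mV")


# ---------------------------------------------------------------------------
# Analysis-side containers


@dataclass
class SteadyStateIV:
    """Per-voltage late currents (mean over the final ``window_ms`` of a step)."""

    voltages: np.ndarray
    currents: np.ndarray
    window_ms: float
    condition: str

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.voltages.shape != self.currents.shape:
            raise ValueError("voltages and currents must have the same length")
        if self.window_ms <= 0:
            raise ValueError("window_ms must be > 0")


@dataclass
class BoltzmannFit:
    """Least-squares Boltzmann parameters of a G-V curve."""

    g_max: float
    v_half: Optional[float]
    slope: Optional[float]
    residual_ss: float
    converged: bool
    n_points: int

    def __call__(self, v) -> np.ndarray:
        if self.v_half is None or self.slope is None:
            return np.zeros_like(np.asarray(v, dtype=float))
        g = boltzmann(v, self.g_max, self.v_half, self.slope)
        return np.clip(g, 0.0, self.g_max)


@dataclass
class GVCurve:
    """Conductance-voltage points derived with a fixed analysis reversal."""

    voltages: np.ndarray
    g_hyp: np.ndarray
    e_hyp: float = -30.0
    fit: Optional[BoltzmannFit] = None

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.g_hyp = np.asarray(self.g_hyp, dtype=float)
        if np.any(self.voltages == self.e_hyp):
            raise ValueError("a voltage equals the analysis reversal (zero driving force)")
        if not np.all(np.isfinite(self.g_hyp)):
            raise ValueError("g_hyp must be finite")


@dataclass
class CapacitanceEstimate:
    """Membrane capacitance from charge integration: Cm = dQ/dV (fC/mV = pF)."""

    delta_q_fc: float
    delta_v_mv: float
    cm_pf: float
    settled: bool = True

    def __post_init__(self) -> None:
        if self.delta_v_mv == 0:
            raise ValueError("delta_v_mv must be nonzero")


@dataclass
class CellRecord:
    """One cell's derived electrophysiological fingerprint plus expression."""

    cell_id: str
    div: int
    density: str  # "1x" or "4x"
    g_norm: Optional[float] = None  # G_MAX / Cm, nS/pF
    v_half: Optional[float] = None
    slope: Optional[float] = None
    cm_pf: Optional[float] = None
    ba_fraction: Optional[float] = None
    expression: dict[str, float] = field(default_factory=dict)  # gene -> -dCt
    label: str = "unclassified"

    def __post_init__(self) -> None:
        if self.density not in {"1x", "4x"}:
            raise ValueError(f"density must be '1x' or '4x', got {self.density!r}")
        if self.ba_fraction is not None and not (0.0 <= self.ba_fraction <= 1.0):
            raise ValueError("ba_fraction must lie in [0, 1] when present")
        if self.g_norm is not None and self.g_norm < 0:
            raise ValueError("g_norm must be >= 0")
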