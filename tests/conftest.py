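import numpy as np
import pytest

from rodmg import CellModel, GatedChannel, VoltageProtocol


def make_cell(g_hcn=1.0, g_kir=0.0, v_half=-90.0, slope=-8.0, e_rev=-30.0,
              tau_ms=50.0, leak=0.2, leak_e=-40.0, cm=5.0, rs=60.0,
              kir_cs_sensitive=True, cell_id="cell") -> CellModel:
    """A rod-precursor-like model cell with configurable HCN/Kir conductances."""
    hcn = GatedChannel(g_max=g_hcn, v_half=v_half, slope=slope, e_rev=e_rev,
                       tau_ms=tau_ms, blocker_sensitivity={"Cs": 1.0})
    kir_sens = {"Ba": 1.0, "Cs": 1.0} if kir_cs_sensitive else {"Ba": 1.0}
    kir = GatedChannel(g_max=g_kir, v_half=-44.0, slope=-15.0, e_rev=-44.0,
                       tau_ms=1e-3, blocker_sensitivity=kir_sens)
    return CellModel(hcn=hcn, kir=kir, leak_conductance=leak, leak_reversal=leak_e,
                     cm_pf=cm, rs_mohm=rs, cell_id=cell_id)


@pytest.fixture
def hcn_cell() -> CellModel:
    """Pure rod-track cell: HCN + leak, no inward rectifier."""
    return make_cell()


@pytest.fixture
def hybrid_cell() -> CellModel:
    """Hybrid-track cell: attenuated HCN plus a Ba2+-blockable Kir."""
    return make_cell(g_hcn=0.25, g_kir=1.0)


@pytest.fixture
def protocol() -> VoltageProtocol:
    """The four-step hyperpolarization protocol (2 s steps from -40 mV)."""
    return VoltageProtocol()


@pytest.fixture
def unfiltered_protocol() -> VoltageProtocol:
    return VoltageProtocol(filter_hz=None)


def steady_current_oracle(cell: CellModel, v: float, blockers=frozenset()) -> float:
    """Closed-form steady-state current: leak + Kir + g_max * m_inf * (V - E)."""
    def m_inf(ch, v):
        return 1.0 / (1.0 + np.exp(-(v - ch.v_half) / ch.slope))

    def unblocked(ch):
        rem = 1.0
        for b in blockers:
            rem *= 1.0 - ch.blocker_sensitivity.get(b, 0.0)
        return rem

    i = cell.leak_conductance * (v - cell.leak_reversal)
    i += unblocked(cell.kir) * cell.kir.g_max * m_inf(cell.kir, v) * (v - cell.kir.e_rev)
    i += unblocked(cell.hcn) * cell.hcn.g_max * m_inf(cell.hcn, v) * (v - cell.hcn.e_rev)
    return float(i)
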