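"""Synthetic cohorts of model cells with matched single-cell expression.

The generator emulates the structure of the culture experiments: groups
crossed by days in vitro (DIV) and plating density (1x vs 4x), per-group
gene-expression distributions (-dCt vs Actb) with a density-driven
suppression of the immaturity genes c-Kit and Mcam, and an
expression-to-conductance coupling for Hcn1.  A configurable fraction of
low-density late-DIV cells follows a "hybrid" trajectory: they gain a
Ba2+-blockable inward-rectifier (Kir) conductance and their realized HCN
conductance decouples from (and inverts against) Hcn1 expression,
mimicking rod precursors drifting toward a Muller-glia-like state.

All randomness flows from ``CohortConfig.seed``; identical configs give
identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .model import CellModel, Condition, GatedChannel, SweepSet, VoltageProtocol
from .simulate import nernst_mv, simulate_cap_test, simulate_vclamp
from .stats import ExpressionRecord

__all__ = ["GeneModel", "CouplingConfig", "CohortConfig", "CohortCell",
           "generate_cohort", "build_cell", "CONDITIONS"]

CONDITIONS = ("highK", "highK_Cs", "highK_Ba", "highK_Ba_Cs")


class GeneModel(BaseModel):
    """Per-group -dCt distribution for one gene.

    mean(-dCt) = base_mean + div_slope * (DIV - first DIV level)
                 + density_effect_4x * [density == 4x]
    """
    model_config = ConfigDict(extra="forbid")

    base_mean: float
    sd: float = Field(ge=0)
    div_slope: float = 0.0
    density_effect_4x: float = 0.0


class CouplingConfig(BaseModel):
    """Expression-to-conductance link: realized HCN conductance scales as
    2**((-dCt - offset) * strength), with lognormal cell-to-cell noise.

    ``strength_rod`` (positive) reproduces the rod-track positive trend of
    normalized conductance with Hcn1 expression; ``strength_hybrid``
    (negative) inverts it on the hybrid track, where Kir takes over.
    """
    model_config = ConfigDict(extra="forbid")

    gene: str = "Hcn1"
    offset: float = -3.85
    base_g_ns: float = 1.0
    strength_rod: float = 0.2
    strength_hybrid: float = -0.3
    hybrid_hcn_base_g_ns: float = 0.25
    hybrid_kir_base_g_ns: float = 1.0
    lognormal_sd: float = 0.2


class CohortConfig(BaseModel):
    """Distributions and effect sizes governing synthetic cohort generation.

    Defaults reflect the study design being emulated: DIV 2-8 cultures at
    1x and 4x densities, 25/140 mM K+ across the membrane, 3-7 pF cells
    patched through 50-80 MOhm pipettes, 2 pA recording noise, and a
    5/19 hybrid-derailment probability among low-density late-DIV cells.
    """
    model_config = ConfigDict(extra="forbid")

    n_cells: int = Field(default=6, ge=1)
    density_levels: list[str] = ["1x", "4x"]
    div_levels: list[int] = [2, 4, 6, 8]
    hybrid_fraction: float = Field(default=5.0 / 19.0, ge=0.0, le=1.0)
    hybrid_min_div: int = 8
    hybrid_density: str = "1x"

    expression_model: dict[str, GeneModel] = Field(default_factory=lambda: {
        "c-Kit":  GeneModel(base_mean=-4.0, sd=1.2, density_effect_4x=-5.0),
        "Mcam":   GeneModel(base_mean=-4.5, sd=1.2, density_effect_4x=-5.0),
        "Tnfsf9": GeneModel(base_mean=-5.0, sd=1.5),
        "Rho":    GeneModel(base_mean=-8.0, sd=1.5, div_slope=0.98),
        "Hcn1":   GeneModel(base_mean=-3.85, sd=1.7),
    })
    coupling: CouplingConfig = Field(default_factory=CouplingConfig)
    actb_ct_mean: float = 20.0
    actb_ct_sd: float = Field(default=1.0, ge=0)

    # Biophysics
    hcn_v_half_mv: float = -90.0
    hcn_slope_mv: float = -8.0
    hcn_tau_ms: float = 300.0
    hcn_e_rev_mv: float = -30.0
    k_out_mm: float = 25.0
    k_in_mm: float = 140.0
    kir_slope_mv: float = -15.0
    leak_g_ns: float = 0.2
    leak_e_mv: float = -40.0
    cm_range_pf: tuple[float, float] = (3.0, 7.0)
    rs_range_mohm: tuple[float, float] = (50.0, 80.0)

    noise_sd_pa: float = Field(default=2.0, ge=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        if not self.div_levels:
            raise ValueError("div_levels must be non-empty")
        if not self.density_levels:
            raise ValueError("density_levels must be non-empty")
        bad = set(self.density_levels) - {"1x", "4x"}
        if bad:
            raise ValueError(f"unknown density levels: {sorted(bad)}")
        if self.cm_range_pf[0] <= 0 or self.cm_range_pf[1] < self.cm_range_pf[0]:
            raise ValueError("cm_range_pf must be a positive, ordered interval")
        if self.rs_range_mohm[0] <= 0 or self.rs_range_mohm[1] < self.rs_range_mohm[0]:
            raise ValueError("rs_range_mohm must be a positive, ordered interval")
        return self

    @property
    def kir_e_rev_mv(self) -> float:
        return nernst_mv(self.k_out_mm, self.k_in_mm)


@dataclass
class CohortCell:
    """One generated cell: biophysics, expression, recordings, ground truth."""

    model: CellModel
    div: int
    density: str
    expression: ExpressionRecord
    true_label: str
    sweeps: dict[str, SweepSet] = dc_field(default_factory=dict)
    cap_test: Optional[SweepSet] = None


def _draw_expression(config: CohortConfig, rng: np.random.Generator,
                     div: int, density: str, cell_id: str) -> ExpressionRecord:
    div0 = min(config.div_levels)
    ct_ref = rng.normal(config.actb_ct_mean, config.actb_ct_sd)
    ct = {"Actb": float(ct_ref)}
    for gene, gm in config.expression_model.items():
        mean = gm.base_mean + gm.div_slope * (div - div0)
        if density == "4x":
            mean += gm.density_effect_4x
        ndct = rng.normal(mean, gm.sd)
        ct[gene] = float(ct_ref - ndct)  # -dCt = -(ct_gene - ct_ref)
    return ExpressionRecord(cell_id=cell_id, ct=ct, reference_gene="Actb")


def build_cell(config: CohortConfig, rng: np.random.Generator,
               div: int, density: str, hybrid: bool,
               expression: ExpressionRecord, cell_id: str) -> CellModel:
    """Realize one cell's biophysical parameters from its expression draw."""
    cpl = config.coupling
    ndct = expression.neg_delta_ct.get(cpl.gene, cpl.offset)
    ln_noise = float(np.exp(rng.normal(0.0, cpl.lognormal_sd)))
    if hybrid:
        g_hcn = cpl.hybrid_hcn_base_g_ns * 2.0 ** ((ndct - cpl.offset) * cpl.strength_hybrid)
        g_kir = cpl.hybrid_kir_base_g_ns * 2.0 ** ((ndct - cpl.offset) * cpl.strength_hybrid)
    else:
        g_hcn = cpl.base_g_ns * 2.0 ** ((ndct - cpl.offset) * cpl.strength_rod)
        g_kir = 0.0
    g_hcn *= ln_noise
    g_kir *= ln_noise

    hcn = GatedChannel(g_max=g_hcn, v_half=config.hcn_v_half_mv,
                       slope=config.hcn_slope_mv, e_rev=config.hcn_e_rev_mv,
                       tau_ms=config.hcn_tau_ms,
                       blocker_sensitivity={"Cs": 1.0})
    e_k = config.kir_e_rev_mv
    kir = GatedChannel(g_max=g_kir, v_half=e_k, slope=config.kir_slope_mv,
                       e_rev=e_k, tau_ms=1e-3,
                       blocker_sensitivity={"Ba": 1.0, "Cs": 1.0})
    cm = float(rng.uniform(*config.cm_range_pf))
    rs = float(rng.uniform(*config.rs_range_mohm))
    return CellModel(hcn=hcn, kir=kir, leak_conductance=config.leak_g_ns,
                     leak_reversal=config.leak_e_mv, cm_pf=cm, rs_mohm=rs,
                     cell_id=cell_id)


def generate_cohort(config: CohortConfig,
                    protocol: Optional[VoltageProtocol] = None,
                    conditions: tuple[str, ...] = CONDITIONS,
                    include_sweeps: bool = True) -> list[CohortCell]:
    """Generate the full crossed cohort, deterministic in ``config.seed``.

    Each cell carries its ground-truth trajectory label ("rod_like" or
    "hybrid") for recovery tests.  Hybrid cells arise only in the
    ``hybrid_density`` group at DIV >= ``hybrid_min_div``, with probability
    ``hybrid_fraction``.
    """
    rng = np.random.default_rng(config.seed)
    # Separate stream for recording-noise seeds so the realized cohort
    # (biophysics, expression, labels) is identical with and without sweeps.
    noise_rng = np.random.default_rng([config.seed, 1])
    if protocol is None:
        protocol = VoltageProtocol()
    cells: list[CohortCell] = []
    idx = 0
    for div in config.div_levels:
        for density in config.density_levels:
            for _ in range(config.n_cells):
                cell_id = f"c{idx:04d}_DIV{div}_{density}"
                idx += 1
                eligible = (density == config.hybrid_density
                            and div >= config.hybrid_min_div)
                hybrid = bool(eligible and rng.random() < config.hybrid_fraction)
                expr = _draw_expression(config, rng, div, density, cell_id)
                model = build_cell(config, rng, div, density, hybrid, expr, cell_id)
                cc = CohortCell(model=model, div=div, density=density,
                                expression=expr,
                                true_label="hybrid" if hybrid else "rod_like")
                if include_sweeps:
                    for cond in conditions:
                        seed = int(noise_rng.integers(2**31))
                        cc.sweeps[cond] = simulate_vclamp(
                            model, protocol, Condition(cond),
                            noise_sd_pa=config.noise_sd_pa, seed=seed)
                    cc.cap_test = simulate_cap_test(
                        model, noise_sd_pa=config.noise_sd_pa,
                        seed=int(noise_rng.integers(2**31)))
                cells.append(cc)
    return cells
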