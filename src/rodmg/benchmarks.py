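"""Parameter-recovery benchmarks exercising the full pipeline end to end.

Each function generates its own synthetic inputs at the study conditions
(four-step 2 s protocol, 2 pA recording noise, 3-7 pF / 50-80 MOhm cells,
5/19 hybrid-derailment probability), runs the measurement chain, and
returns summary recovery metrics.  They power both the regression tests
and the reproduction script.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .cohort import CohortConfig, generate_cohort
from .ephys import (ba_decomposition, capacitance_from_transient,
                    conductance_from_iv, fit_boltzmann, steady_state_iv,
                    subtract_conditions)
from .model import Condition, VoltageProtocol, boltzmann
from .simulate import simulate_cap_test, simulate_vclamp
from .stats import FactorialDataset, gv_expression_trend, two_way_anova
from .study import analyze_cell

__all__ = [
    "boltzmann_recovery",
    "capacitance_recovery",
    "ba_fraction_recovery",
    "classification_recovery",
    "trend_sign_rates",
    "anova_type1_rate",
    "reference_cell",
]

TRUE_G_MAX, TRUE_V_HALF, TRUE_SLOPE = 1.0, -90.0, -8.0


def reference_cell(g_hcn: float = TRUE_G_MAX, g_kir: float = 0.0,
                   cm: float = 5.0, rs: float = 60.0, tau_ms: float = 300.0):
    """A rod-precursor-like cell with the default generative parameters."""
    from .model import CellModel, GatedChannel
    hcn = GatedChannel(g_max=g_hcn, v_half=TRUE_V_HALF, slope=TRUE_SLOPE,
                       e_rev=-30.0, tau_ms=tau_ms,
                       blocker_sensitivity={"Cs": 1.0})
    kir = GatedChannel(g_max=g_kir, v_half=-44.0, slope=-15.0, e_rev=-44.0,
                       tau_ms=1e-3, blocker_sensitivity={"Ba": 1.0, "Cs": 1.0})
    return CellModel(hcn=hcn, kir=kir, leak_conductance=0.2, leak_reversal=-40.0,
                     cm_pf=cm, rs_mohm=rs)


def _fit_one(cell, protocol, noise_sd, seed):
    a = simulate_vclamp(cell, protocol, Condition("highK"), noise_sd, seed=seed)
    b = simulate_vclamp(cell, protocol, Condition("highK_Cs"), noise_sd,
                        seed=None if seed is None else seed + 1)
    ihyp = subtract_conditions(steady_state_iv(a), steady_state_iv(b))
    return fit_boltzmann(conductance_from_iv(ihyp))


def boltzmann_recovery(seed: int = 0, n_cells: int = 500,
                       noise_sd_pa: float = 2.0) -> dict:
    """Boltzmann activation-parameter recovery.

    Noiseless: direct fit of exact G-V points on the four-step grid plus
    holding (worst relative error across g_max, v_half, slope).  Noisy:
    full simulate->subtract->fit chain on ``n_cells`` seeded cells; median
    absolute v_half error (mV) and median relative g_max / slope errors.
    """
    from .model import GVCurve
    grid = np.array([-40.0, -60.0, -80.0, -100.0, -120.0])
    exact = fit_boltzmann(GVCurve(grid, boltzmann(grid, TRUE_G_MAX, TRUE_V_HALF,
                                                  TRUE_SLOPE)))
    noiseless_err = max(abs(exact.g_max - TRUE_G_MAX) / TRUE_G_MAX,
                        abs(exact.v_half - TRUE_V_HALF) / abs(TRUE_V_HALF),
                        abs(exact.slope - TRUE_SLOPE) / abs(TRUE_SLOPE))

    cell = reference_cell()
    protocol = VoltageProtocol()
    base = int(np.random.default_rng(seed).integers(2**30))
    vh, gm, sl = [], [], []
    for i in range(n_cells):
        fit = _fit_one(cell, protocol, noise_sd_pa, base + 2 * i)
        vh.append(abs(fit.v_half - TRUE_V_HALF))
        gm.append(abs(fit.g_max - TRUE_G_MAX) / TRUE_G_MAX)
        sl.append(abs(fit.slope - TRUE_SLOPE) / abs(TRUE_SLOPE))
    return {
        "noiseless_max_rel_err": float(noiseless_err),
        "median_v_half_err_mv": float(np.median(vh)),
        "median_g_max_rel_err": float(np.median(gm)),
        "median_slope_rel_err": float(np.median(sl)),
        "n": n_cells,
    }


def capacitance_recovery(seed: int = 0, noise_sd_pa: float = 2.0) -> dict:
    """Cm = dQ/dV round trip over the 3-7 pF x 50-80 MOhm cell grid."""
    cms = np.linspace(3.0, 7.0, 5)
    rss = np.linspace(50.0, 80.0, 4)
    base = int(np.random.default_rng(seed).integers(2**30))
    err0, errn = [], []
    k = 0
    for cm in cms:
        for rs in rss:
            cell = reference_cell(cm=cm, rs=rs)
            est0 = capacitance_from_transient(simulate_cap_test(cell, noise_sd_pa=0.0))
            estn = capacitance_from_transient(
                simulate_cap_test(cell, noise_sd_pa=noise_sd_pa, seed=base + k))
            err0.append(abs(est0.cm_pf - cm) / cm)
            errn.append(abs(estn.cm_pf - cm) / cm)
            k += 1
    return {
        "max_rel_err_noiseless": float(max(err0)),
        "max_rel_err_noisy": float(max(errn)),
        "n": len(err0),
    }


def ba_fraction_recovery(kir_shares=(0.0, 0.25, 0.5, 0.75)) -> dict:
    """Recovered Ba2+-sensitive share vs the generative Kir share at -120 mV
    (noiseless).  The Kir conductance is chosen so Kir carries exactly the
    requested fraction of the hyperpolarization-activated current."""
    protocol = VoltageProtocol()
    probe = reference_cell()
    m_h = float(probe.hcn.m_inf(-120.0))
    i_h_unit = TRUE_G_MAX * m_h * (-120.0 - probe.hcn.e_rev)
    r_k = float(probe.kir.m_inf(-120.0))
    i_k_unit = r_k * (-120.0 - probe.kir.e_rev)
    errors = {}
    for f in kir_shares:
        g_kir = 0.0 if f == 0.0 else (f / (1.0 - f)) * i_h_unit / i_k_unit
        cell = reference_cell(g_kir=g_kir)
        ivs = [steady_state_iv(simulate_vclamp(cell, protocol, Condition(c), 0.0))
               for c in ("highK", "highK_Ba", "highK_Ba_Cs")]
        d = ba_decomposition(*ivs, at_mv=-120.0)
        errors[f] = abs(d.ba_fraction - f)
    return {"max_abs_err": float(max(errors.values())),
            "per_share": {str(k): float(v) for k, v in errors.items()},
            "n": len(kir_shares)}


def _cohort_config(seed: int, n_cells: int, noise_sd_pa: float,
                   hybrid_fraction: float = 5.0 / 19.0) -> CohortConfig:
    return CohortConfig(n_cells=n_cells, div_levels=[8], density_levels=["1x"],
                        hybrid_fraction=hybrid_fraction,
                        noise_sd_pa=noise_sd_pa, seed=seed)


def classification_recovery(seed: int = 0, n_cells: int = 200,
                            noise_sd_pa: float = 2.0) -> dict:
    """Ground-truth label recovery on a seeded DIV8/1x cohort with the 5/19
    hybrid-derailment probability, at the given noise and noiseless."""
    out = {}
    for tag, noise in (("noisy", noise_sd_pa), ("noiseless", 0.0)):
        cfg = _cohort_config(seed, n_cells, noise)
        cohort = generate_cohort(cfg)
        hits = 0
        n_hybrid = 0
        for cc in cohort:
            rec = analyze_cell(cc.sweeps, cc.cap_test, div=cc.div,
                               density=cc.density)
            hits += rec.label == cc.true_label
            n_hybrid += cc.true_label == "hybrid"
        out[f"accuracy_{tag}"] = hits / len(cohort)
        if tag == "noisy":
            out["hybrid_share"] = n_hybrid / len(cohort)
            lo, hi = sps.binom.interval(0.95, len(cohort), 5.0 / 19.0)
            out["hybrid_share_ci"] = (lo / len(cohort), hi / len(cohort))
    out["n"] = n_cells
    return out


def trend_sign_rates(seed: int = 0, n_reps: int = 200, n_cells: int = 12) -> dict:
    """Fraction of seeded replicate cohorts whose measured conductance vs
    Hcn1 -dCt slope has the expected sign: positive on the rod track,
    negative on the hybrid track."""
    rng = np.random.default_rng(seed)
    rates = {}
    for name, frac, want in (("rod_positive_rate", 0.0, 1),
                             ("hybrid_negative_rate", 1.0, -1)):
        good = 0
        for _ in range(n_reps):
            cfg = _cohort_config(int(rng.integers(2**30)), n_cells, 2.0,
                                 hybrid_fraction=frac)
            cohort = generate_cohort(cfg, conditions=("highK", "highK_Cs"))
            recs = [analyze_cell(cc.sweeps, cc.cap_test, div=cc.div,
                                 density=cc.density,
                                 expression=cc.expression.neg_delta_ct)
                    for cc in cohort]
            good += gv_expression_trend(recs, "Hcn1").slope_sign == want
        rates[name] = good / n_reps
    rates["n"] = n_reps
    return rates


def anova_type1_rate(seed: int = 0, n_reps: int = 2000, alpha: float = 0.05) -> dict:
    """Type-I error of the density main effect under a null generator (no
    density effect on the tested gene), balanced 2x2 design with n=3."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        cfg = CohortConfig(n_cells=3, div_levels=[4, 8],
                           density_levels=["1x", "4x"], hybrid_fraction=0.0,
                           seed=int(rng.integers(2**30)))
        cohort = generate_cohort(cfg, include_sweeps=False)
        y = [cc.expression.neg_delta_ct["Tnfsf9"] for cc in cohort]
        res = two_way_anova(FactorialDataset(y, [cc.div for cc in cohort],
                                             [cc.density for cc in cohort]))
        rejections += res["density"].p < alpha
    return {"rate": rejections / n_reps, "n": n_reps}
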