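#!/usr/bin/env python
"""Ba2+-sensitive decomposition of I_HYP and the conductance-expression trend.

For the low-density DIV8 cells — the group where rod precursors derail
toward the hybrid rod/Muller-glia state — splits the hyperpolarization-
activated current at -120 mV into a Ba2+-sensitive (Kir) and a residual
Cs-sensitive (HCN) component, and fits the normalized-conductance vs
Hcn1 -dCt trend per DIV group.  A hybrid subpopulation shows up as
nonzero Ba2+ fractions; a large enough hybrid share pulls the DIV8 trend
negative (the pure-track contrast is quantified in the benchmarks).
"""

from pathlib import Path

import pandas as pd

from rodmg import (Condition, ba_decomposition, generate_cohort,
                   gv_expression_trend, load_cohort_config, steady_state_iv)
from rodmg.study import analyze_cell

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    config = load_cohort_config(RESULTS / "cohort_config.yaml")
    cohort = generate_cohort(config)

    rows = []
    records_by_div: dict[int, list] = {}
    for cc in cohort:
        if cc.density != "1x":
            continue
        rec = analyze_cell(cc.sweeps, cc.cap_test, div=cc.div, density=cc.density,
                           expression=cc.expression.neg_delta_ct)
        records_by_div.setdefault(cc.div, []).append(rec)
        if cc.div == max(config.div_levels):
            ivs = [steady_state_iv(cc.sweeps[c])
                   for c in ("highK", "highK_Ba", "highK_Ba_Cs")]
            d = ba_decomposition(*ivs, at_mv=-120.0)
            rows.append({
                "cell_id": rec.cell_id, "true_label": cc.true_label,
                "label": rec.label,
                "i_kir_pa": round(d.i_kir_pa, 2), "i_h_pa": round(d.i_h_pa, 2),
                "ba_fraction": None if d.ba_fraction is None else round(d.ba_fraction, 4),
                "i_kir_per_cm_pa_pf": round(d.i_kir_pa / rec.cm_pf, 2),
            })
    decomp = pd.DataFrame(rows)
    decomp.to_csv(RESULTS / "ba_decomposition_div8.csv", index=False)
    print("DIV8 / 1x Ba2+-sensitive decomposition at -120 mV:")
    print(decomp.to_string(index=False))

    trend_rows = []
    for div, recs in sorted(records_by_div.items()):
        try:
            tr = gv_expression_trend(recs, "Hcn1")
        except ValueError:
            continue
        trend_rows.append({"div": div, "slope": round(tr.slope, 4),
                           "r": round(tr.r, 4), "p": round(tr.p, 4), "n": tr.n})
    trends = pd.DataFrame(trend_rows)
    trends.to_csv(RESULTS / "gv_hcn1_trend_by_div.csv", index=False)
    print("\ng_norm vs Hcn1 -dCt trend per DIV (1x cells):")
    print(trends.to_string(index=False))


if __name__ == "__main__":
    main()
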