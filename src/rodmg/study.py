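"""End-to-end study orchestration: cohort -> per-cell pipeline -> statistics.

``run_study`` generates a synthetic cohort, pushes every cell through the
measurement chain, classifies it, and writes a tidy cell-record table plus
a statistics report (per-gene factorial ANOVA, conductance-expression
trends, label counts) and a manifest.  All outputs are deterministic in
the config seed and serialized at fixed precision, so re-running with an
identical config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortCell, CohortConfig, generate_cohort
from .ephys import (DEFAULT_E_HYP_MV, DEFAULT_G_NORM_FLOOR, DEFAULT_HYBRID_BAND,
                    ba_decomposition, capacitance_from_transient, classify_cell,
                    conductance_from_iv, fit_boltzmann, normalize_gmax,
                    steady_state_iv, subtract_conditions)
from .model import CellRecord, SweepSet
from .stats import FactorialDataset, gv_expression_trend, two_way_anova

__all__ = ["analyze_cell", "run_study", "RunManifest", "DERIVED_DECIMALS"]

logger = logging.getLogger("rodmg")

DERIVED_DECIMALS = 4


def analyze_cell(sweeps: dict[str, SweepSet], cap_test: SweepSet,
                 div: int = 0, density: str = "1x",
                 expression: Optional[dict[str, float]] = None,
                 window_ms: float = 200.0, e_hyp_mv: float = DEFAULT_E_HYP_MV,
                 g_norm_floor: float = DEFAULT_G_NORM_FLOOR,
                 hybrid_band: tuple[float, float] = DEFAULT_HYBRID_BAND) -> CellRecord:
    """Run the full measurement chain on one cell's recordings.

    Requires the high-K control and +Cs conditions (for I_HYP isolation)
    plus a capacitance test; the +Ba and +Ba+Cs conditions, when present,
    add the Ba2+-sensitive decomposition.
    """
    if "highK" not in sweeps or "highK_Cs" not in sweeps:
        raise ValueError("need 'highK' and 'highK_Cs' sweep sets to isolate I_HYP")
    iv_k = steady_state_iv(sweeps["highK"], window_ms)
    iv_cs = steady_state_iv(sweeps["highK_Cs"], window_ms)
    i_hyp = subtract_conditions(iv_k, iv_cs)
    gv = conductance_from_iv(i_hyp, e_hyp_mv)
    fit = fit_boltzmann(gv)
    cm = capacitance_from_transient(cap_test)
    g_norm = normalize_gmax(fit, cm)

    ba_fraction = None
    if "highK_Ba" in sweeps and "highK_Ba_Cs" in sweeps:
        iv_ba = steady_state_iv(sweeps["highK_Ba"], window_ms)
        iv_ba_cs = steady_state_iv(sweeps["highK_Ba_Cs"], window_ms)
        decomp = ba_decomposition(iv_k, iv_ba, iv_ba_cs)
        ba_fraction = decomp.ba_fraction

    record = CellRecord(
        cell_id=cap_test.cell_id, div=div, density=density,
        g_norm=g_norm, v_half=fit.v_half, slope=fit.slope, cm_pf=cm.cm_pf,
        ba_fraction=ba_fraction, expression=dict(expression or {}),
    )
    record.label = classify_cell(record, g_norm_floor, hybrid_band)
    return record


@dataclass
class RunManifest:
    """Provenance of one study run."""

    config_hash: str
    seed: int
    software_version: str
    n_generated: int
    n_analyzed: int
    n_quarantined: int
    outputs: dict[str, str] = field(default_factory=dict)
    quarantined: list[dict[str, str]] = field(default_factory=list)
    timestamp: Optional[str] = None

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n"


def _config_hash(config: CohortConfig) -> str:
    canonical = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _round(x: Optional[float]) -> Optional[float]:
    return None if x is None else round(float(x), DERIVED_DECIMALS)


def records_to_frame(records: list[CellRecord], true_labels: list[str]) -> pd.DataFrame:
    rows = []
    for rec, truth in zip(records, true_labels):
        row = {
            "cell_id": rec.cell_id, "div": rec.div, "density": rec.density,
            "g_norm_ns_per_pf": _round(rec.g_norm), "v_half_mv": _round(rec.v_half),
            "slope_mv": _round(rec.slope), "cm_pf": _round(rec.cm_pf),
            "ba_fraction": _round(rec.ba_fraction),
            "label": rec.label, "true_label": truth,
        }
        for gene, val in sorted(rec.expression.items()):
            row[f"ndct_{gene}"] = _round(val)
        rows.append(row)
    return pd.DataFrame(rows)


def _stats_report(frame: pd.DataFrame, records: list[CellRecord]) -> dict:
    report: dict = {"anova": {}, "trend": {}, "labels": {}}
    genes = sorted(c.removeprefix("ndct_") for c in frame.columns if c.startswith("ndct_"))
    for gene in genes:
        col = f"ndct_{gene}"
        sub = frame.dropna(subset=[col])
        if sub["div"].nunique() < 2 and sub["density"].nunique() < 2:
            continue
        try:
            res = two_way_anova(FactorialDataset(sub[col].to_numpy(),
                                                 sub["div"], sub["density"]))
        except ValueError as exc:
            report["anova"][gene] = {"error": str(exc)}
            continue
        report["anova"][gene] = {
            name: {"F": _round(e.F), "df": [e.df_num, e.df_den], "p": _round(e.p)}
            for name, e in res.effects.items()
        }
    for div in sorted(frame["div"].unique()):
        cells = [r for r in records
                 if r.div == div and r.density == "1x" and r.g_norm is not None
                 and "Hcn1" in r.expression]
        if len(cells) < 3:
            continue
        try:
            tr = gv_expression_trend(cells, "Hcn1")
        except ValueError:
            continue
        report["trend"][f"DIV{int(div)}"] = {
            "slope": _round(tr.slope), "r": _round(tr.r), "p": _round(tr.p), "n": tr.n}
    report["labels"] = frame["label"].value_counts().sort_index().to_dict()
    report["label_accuracy"] = _round(float((frame["label"] == frame["true_label"]).mean()))
    return report


def run_study(config: CohortConfig, outdir, window_ms: float = 200.0,
              e_hyp_mv: float = DEFAULT_E_HYP_MV,
              g_norm_floor: float = DEFAULT_G_NORM_FLOOR,
              hybrid_band: tuple[float, float] = DEFAULT_HYBRID_BAND,
              include_timestamp: bool = False) -> RunManifest:
    """Generate a cohort, analyze every cell, and write the study outputs.

    Per-cell failures are logged and quarantined (the run continues);
    quarantined + analyzed always equals generated.  Outputs under
    ``outdir``: cell_records.csv, stats_report.json, manifest.json.
    Timestamps are omitted by default so reruns are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config)

    records: list[CellRecord] = []
    truths: list[str] = []
    quarantined: list[dict[str, str]] = []
    for cc in cohort:
        try:
            rec = analyze_cell(cc.sweeps, cc.cap_test, div=cc.div, density=cc.density,
                               expression=cc.expression.neg_delta_ct,
                               window_ms=window_ms, e_hyp_mv=e_hyp_mv,
                               g_norm_floor=g_norm_floor, hybrid_band=hybrid_band)
        except Exception as exc:  # quarantine, keep going
            logger.warning("cell %s quarantined: %s", cc.model.cell_id, exc)
            quarantined.append({"cell_id": cc.model.cell_id, "reason": str(exc)})
            continue
        records.append(rec)
        truths.append(cc.true_label)

    frame = records_to_frame(records, truths)
    records_path = outdir / "cell_records.csv"
    frame.to_csv(records_path, index=False, float_format=f"%.{DERIVED_DECIMALS}f")

    report = _stats_report(frame, records)
    report_path = outdir / "stats_report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

    manifest = RunManifest(
        config_hash=_config_hash(config), seed=config.seed,
        software_version=__version__,
        n_generated=len(cohort), n_analyzed=len(records),
        n_quarantined=len(quarantined),
        outputs={"cell_records": records_path.name, "stats_report": report_path.name},
        quarantined=quarantined,
        timestamp=datetime.now(timezone.utc).isoformat() if include_timestamp else None,
    )
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest
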