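"""File formats: sweep-set CSV + JSON sidecar, cohort configs, record tables.

A recording is stored as a plain CSV (``time_ms`` plus one ``step_<V>mV``
column per command voltage, currents in pA, 6 decimals) with a JSON
sidecar carrying the metadata needed to reconstruct the protocol.  Both
directions round-trip: metadata bit-exact, currents to 6 decimals.
Unknown sidecar or config keys are rejected by name rather than ignored.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .cohort import CohortConfig
from .model import Condition, SweepSet, VoltageProtocol

__all__ = ["SweepSidecar", "write_sweepset", "read_sweepset", "sidecar_path",
           "load_cohort_config", "SchemaError"]

PathLike = Union[str, Path]
CURRENT_DECIMALS = 6


class SchemaError(ValueError):
    """A file violated the documented schema (wrong/unknown/missing field)."""


class SweepSidecar(BaseModel):
    """Metadata sidecar for one sweep-set CSV."""

    model_config = ConfigDict(extra="forbid")

    cell_id: str
    condition: str
    holding_mv: float
    step_mvs: list[float]
    step_ms: float
    pre_ms: float
    post_ms: float
    sample_rate_hz: float
    filter_hz: Optional[float] = None
    seed: Optional[int] = None


def _column_name(step_mv: float) -> str:
    return f"step_{step_mv:g}mV"


def sidecar_path(path_csv: PathLike) -> Path:
    return Path(path_csv).with_suffix(".json")


def write_sweepset(sweeps: SweepSet, path_csv: PathLike,
                   path_json: Optional[PathLike] = None) -> None:
    """Write a sweep set as CSV + JSON sidecar (6-decimal currents)."""
    path_csv = Path(path_csv)
    path_json = sidecar_path(path_csv) if path_json is None else Path(path_json)
    protocol = sweeps.protocol
    frame = pd.DataFrame({"time_ms": sweeps.time_ms})
    for v, trace in zip(protocol.step_mvs, sweeps.currents_pa):
        frame[_column_name(v)] = trace
    frame.to_csv(path_csv, index=False, float_format=f"%.{CURRENT_DECIMALS}f")
    sidecar = SweepSidecar(
        cell_id=sweeps.cell_id,
        condition=sweeps.condition.name,
        holding_mv=protocol.holding_mv,
        step_mvs=list(protocol.step_mvs),
        step_ms=protocol.step_ms,
        pre_ms=protocol.pre_ms,
        post_ms=protocol.post_ms,
        sample_rate_hz=protocol.sample_rate_hz,
        filter_hz=protocol.filter_hz,
        seed=sweeps.seed,
    )
    path_json.write_text(json.dumps(sidecar.model_dump(), indent=2, sort_keys=True) + "\n")


def read_sweepset(path_csv: PathLike, path_json: Optional[PathLike] = None) -> SweepSet:
    """Read a sweep set written by :func:`write_sweepset`.

    Raises :class:`SchemaError` naming the offending field for a missing
    sidecar, an unknown metadata key, or a CSV/metadata column mismatch.
    """
    path_csv = Path(path_csv)
    path_json = sidecar_path(path_csv) if path_json is None else Path(path_json)
    if not path_csv.exists():
        raise SchemaError(f"sweep CSV not found: {path_csv}")
    if not path_json.exists():
        raise SchemaError(f"metadata sidecar not found: {path_json}")
    try:
        sidecar = SweepSidecar.model_validate(json.loads(path_json.read_text()))
    except ValidationError as exc:
        fields = ", ".join(str(e["loc"][0]) if e["loc"] else "?" for e in exc.errors())
        raise SchemaError(f"invalid sidecar {path_json}: field(s) {fields}") from exc

    frame = pd.read_csv(path_csv)
    expected = ["time_ms"] + [_column_name(v) for v in sidecar.step_mvs]
    if list(frame.columns) != expected:
        missing = set(expected) - set(frame.columns)
        extra = set(frame.columns) - set(expected)
        raise SchemaError(
            f"CSV columns do not match sidecar step_mvs: missing {sorted(missing)}, "
            f"unexpected {sorted(extra)}"
        )
    protocol = VoltageProtocol(
        holding_mv=sidecar.holding_mv,
        step_mvs=tuple(sidecar.step_mvs),
        step_ms=sidecar.step_ms,
        pre_ms=sidecar.pre_ms,
        post_ms=sidecar.post_ms,
        sample_rate_hz=sidecar.sample_rate_hz,
        filter_hz=sidecar.filter_hz,
    )
    currents = np.vstack([frame[_column_name(v)].to_numpy() for v in sidecar.step_mvs])
    return SweepSet(cell_id=sidecar.cell_id, condition=Condition(sidecar.condition),
                    protocol=protocol, time_ms=frame["time_ms"].to_numpy(),
                    currents_pa=currents, seed=sidecar.seed)


def load_cohort_config(path: PathLike) -> CohortConfig:
    """Load a cohort configuration from YAML or JSON; unknown keys rejected."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise SchemaError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return CohortConfig.model_validate(raw)
    except ValidationError as exc:
        fields = ", ".join(".".join(str(p) for p in e["loc"]) or "?" for e in exc.errors())
        raise SchemaError(f"invalid cohort config {path}: field(s) {fields}") from exc
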