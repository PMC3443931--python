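"""Flat-file serialization: trial tables (CSV), sessions (JSON), configs (YAML).

Trial CSVs are UTF-8 with an explicit header and '.' decimal separator;
a ``unit`` column (ms vs deg) travels with every row so temporal and
spatial data cannot be silently mixed.  Schema violations raise with the
offending file row number.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml

from .design import CONDITIONS, DOMAINS, SPACE, TIME
from .observer import ObserverParams, Session, TrialRecord, TrialSpec
from .pipeline import PipelineConfig

__all__ = [
    "TRIAL_COLUMNS",
    "SchemaError",
    "write_trials",
    "read_trials",
    "write_session_json",
    "read_config",
    "write_config",
]

TRIAL_COLUMNS = (
    "observer_id",
    "age_group",
    "domain",
    "condition",
    "conflict",
    "probe_offset",
    "unit",
    "response",
)

_UNITS = {TIME: "ms", SPACE: "deg"}


class SchemaError(ValueError):
    """A trial table violates the expected schema."""


def write_trials(sessions: Sequence[Session], path) -> None:
    """One row per trial; see :data:`TRIAL_COLUMNS` for the schema."""
    rows = []
    for s in sessions:
        for t in s.trials:
            rows.append({
                "observer_id": s.observer_id,
                "age_group": s.age_group,
                "domain": s.domain,
                "condition": t.spec.condition,
                "conflict": t.spec.conflict,
                "probe_offset": t.spec.probe_offset,
                "unit": _UNITS[s.domain],
                "response": t.response,
            })
    # 17 significant digits make write -> read the identity on floats
    pd.DataFrame(rows, columns=list(TRIAL_COLUMNS)).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_trials(path) -> List[Session]:
    """Read a trial CSV back into Sessions (inverse of :func:`write_trials`).

    Errors cite the 1-based file row (header = row 1).  An empty table
    yields an empty list with a warning.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    if len(df) == 0:
        warnings.warn(f"{path}: trial table is empty (header only)")
        return []
    sessions: Dict[tuple, Session] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        file_row = i + 2  # 1-based; header occupies row 1
        if row.domain not in DOMAINS:
            raise SchemaError(f"{path} row {file_row}: unknown domain {row.domain!r}")
        if row.condition not in CONDITIONS:
            raise SchemaError(
                f"{path} row {file_row}: unknown condition {row.condition!r}"
            )
        if row.response not in (0, 1):
            raise SchemaError(
                f"{path} row {file_row}: response must be 0 or 1, got {row.response!r}"
            )
        if row.unit != _UNITS[row.domain]:
            raise SchemaError(
                f"{path} row {file_row}: unit {row.unit!r} does not match "
                f"domain {row.domain!r} (expected {_UNITS[row.domain]!r})"
            )
        try:
            spec = TrialSpec(
                domain=row.domain,
                condition=row.condition,
                conflict=float(row.conflict),
                probe_offset=float(row.probe_offset),
            )
            rec = TrialRecord(spec=spec, response=int(row.response))
        except (ValueError, TypeError) as e:
            raise SchemaError(f"{path} row {file_row}: {e}") from e
        key = (row.observer_id, row.domain)
        if key not in sessions:
            sessions[key] = Session(
                observer_id=str(row.observer_id),
                age_group=str(row.age_group),
                domain=row.domain,
                trials=[],
            )
        sessions[key].trials.append(rec)
    return list(sessions.values())


def write_session_json(
    session: Session,
    path,
    params: Optional[ObserverParams] = None,
    design=None,
    seed: Optional[int] = None,
) -> None:
    """Session with full provenance (observer params, design, seed)."""
    payload = {
        "observer_id": session.observer_id,
        "age_group": session.age_group,
        "domain": session.domain,
        "passed_training": session.passed_training,
        "trials": [
            {
                "condition": t.spec.condition,
                "conflict": t.spec.conflict,
                "probe_offset": t.spec.probe_offset,
                "response": t.response,
            }
            for t in session.trials
        ],
        "params": dataclasses.asdict(params) if params is not None else None,
        "design": dataclasses.asdict(design) if design is not None else None,
        "seed": seed,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return PipelineConfig.from_dict(data)


def write_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
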