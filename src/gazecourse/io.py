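"""CSV schemas and validated readers/writers for every pipeline table."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError

#: Required columns per table kind. Extra columns are allowed and preserved.
SCHEMAS: dict[str, list[str]] = {
    "samples": [
        "subject_id",
        "trial_number",
        "stimulus_id",
        "face_race",
        "speech_type",
        "time_ms",
        "x_px",
        "y_px",
        "valid",
    ],
    "aoi": ["stimulus_id", "time_ms", "region", "x_min", "y_min", "x_max", "y_max"],
    "subjects": ["subject_id", "age_days"],
    "fixations": [
        "subject_id",
        "trial_number",
        "face_race",
        "speech_type",
        "fixation_index",
        "start_ms",
        "end_ms",
        "duration_ms",
        "centroid_x",
        "centroid_y",
        "aoi",
    ],
    "clusters": [
        "condition",
        "cluster_index",
        "sum_t",
        "onset_ms",
        "offset_ms",
        "p_value",
        "significant",
    ],
}

_NUMERIC = {
    "samples": ["trial_number", "time_ms", "valid"],
    "aoi": ["time_ms", "x_min", "y_min", "x_max", "y_max"],
    "subjects": ["age_days"],
    "fixations": ["trial_number", "fixation_index", "start_ms", "end_ms", "duration_ms"],
    "clusters": ["cluster_index", "sum_t", "onset_ms", "offset_ms", "p_value"],
}


def validate_table(df: pd.DataFrame, kind: str, source: str = "<memory>") -> pd.DataFrame:
    """Check required columns and numeric fields; raise SchemaError naming the
    offending file, column, and first bad row."""
    if kind not in SCHEMAS:
        raise SchemaError(f"unknown table kind {kind!r}")
    missing = [c for c in SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing required column(s) {missing} for {kind} table")
    for col in _NUMERIC.get(kind, []):
        vals = pd.to_numeric(df[col], errors="coerce")
        allow_nan = col in ("p_value",)
        bad = vals.isna() & df[col].notna() if allow_nan else vals.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(f"{source}: column {col!r} has non-numeric value at row {row}")
    return df


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    df = pd.read_csv(path)
    return validate_table(df, kind, source=str(path))


def write_table(df: pd.DataFrame, path: str | Path, kind: str | None = None) -> Path:
    path = Path(path)
    if kind is not None:
        validate_table(df, kind, source=str(path))
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
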