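"""Readers and writers for nucleus-object tables and run configuration.

The interchange format is CSV, one row per segmented nucleus, matching the
tabular feature exports of 3D nucleus segmentation: required columns
``sample_id, object_id, x_um, y_um, z_um, area_um2``; marker channels are
auto-detected by the ``int_`` prefix; optional ``true_*`` ground-truth
columns pass through untouched. Border calls and run metadata are JSON,
configuration is YAML.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["REQUIRED_COLUMNS", "read_objects_csv", "write_objects_csv",
           "RunConfig", "intensity_columns"]

REQUIRED_COLUMNS = ("sample_id", "object_id", "x_um", "y_um", "z_um",
                    "area_um2")

NUMERIC_COLUMNS = ("x_um", "y_um", "z_um", "area_um2")


def read_objects_csv(path) -> pd.DataFrame:
    """Read a nucleus-object table, validating structure and values.

    Raises a :class:`ValueError` naming any missing required column, and a
    :class:`ValueError` with 1-based data line numbers for rows whose
    coordinate or area fields are non-numeric or non-finite.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing column: {col}")
    bad_lines: list[int] = []
    for col in NUMERIC_COLUMNS + tuple(intensity_columns(df)):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = ~np.isfinite(coerced.to_numpy(float))
        if bad.any():
            bad_lines.extend((np.flatnonzero(bad) + 2).tolist())  # header = line 1
        df[col] = coerced
    if bad_lines:
        raise ValueError(
            f"non-numeric or non-finite values at line(s) "
            f"{sorted(set(bad_lines))} of {path.name}"
        )
    if df["object_id"].duplicated().groupby(df["sample_id"]).any().any():
        raise ValueError("object_id values must be unique within a sample")
    return df


def write_objects_csv(df: pd.DataFrame, path) -> Path:
    """Write a nucleus-object table with full float precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def intensity_columns(df: pd.DataFrame) -> list[str]:
    """Marker intensity columns, detected by the ``int_`` prefix."""
    return [c for c in df.columns if c.startswith("int_")]


@dataclass
class RunConfig:
    """Resolved parameters of one end-to-end pipeline run.

    Serializes to YAML with a byte-identical write→read→write round trip;
    every run writes its resolved config next to its outputs.
    """

    out_dir: str = "out"
    input_paths: list[str] = field(default_factory=list)
    simulate: bool = True
    n_per_group: int = 8
    slice_count: int = 30
    n_bins: int = 100
    border_variables: list[str] = field(
        default_factory=lambda: ["width", "large_area", "nn_distance",
                                 "total_count"]
    )
    border_weights: dict = field(
        default_factory=lambda: {"width": 1.0, "large_area": 1.0,
                                 "nn_distance": 1.0, "total_count": 0.5}
    )
    border_window: int = 5
    border_k: int = 4
    border_min_separation: int = 5
    marker_threshold_method: str = "bimodal-valley"
    pairing_radius_um: float = 10.0
    exclusion_radius_um: float = 15.0
    alpha: float = 0.05
    compare_features: list[str] = field(
        default_factory=lambda: ["width", "total_count", "large_area"]
    )
    flip_orientation: bool = False
    seed: int = 0

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True,
                              default_flow_style=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            text = Path(source).read_text()
        else:
            text = str(source)
        data = yaml.safe_load(text) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)


def _jsonable(o):
    """Recursively convert numpy scalars/arrays; NaN becomes null."""
    if isinstance(o, dict):
        return {str(k): _jsonable(v) for k, v in o.items()}
    if isinstance(o, np.ndarray):
        return [_jsonable(v) for v in o.tolist()]
    if isinstance(o, (list, tuple)):
        return [_jsonable(v) for v in o]
    if isinstance(o, (np.integer, int)) and not isinstance(o, bool):
        return int(o)
    if isinstance(o, (np.floating, float)):
        f = float(o)
        return None if np.isnan(f) else f
    return o


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True,
                               allow_nan=False))
    return path
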