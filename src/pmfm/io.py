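"""Readers and writers for the package's text formats.

Canonical dialect is TSV with a header row of region ids (comma fallback
auto-detected); spatial maps are two-column tables (region id, value);
results are JSON records carrying a schema version, the seeds used and
SHA-256 digests of the inputs, so every artifact embeds its provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamics import (
    BoldTimeseries,
    Connectome,
    LinearCoefficients,
    SimulationConfig,
    SpatialMap,
)
from .exceptions import InvalidInputError
from .observables import FCDMatrix, FCMatrix, FcdPdf
from .spatial_stats import ExpressionMatrix, ParcelCentroids

__all__ = [
    "read_square_matrix",
    "write_square_matrix",
    "read_spatial_map",
    "write_spatial_map",
    "read_bold",
    "write_bold",
    "read_expression",
    "read_centroids",
    "read_coefficients",
    "write_coefficients",
    "read_config",
    "write_results",
    "read_results",
]

SCHEMA_VERSION = "1.0"


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"no such file: {path}")
    sep = "\t"
    with open(path) as fh:
        first = fh.readline()
    if "\t" not in first and "," in first:
        sep = ","
    try:
        return pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    except ValueError as exc:
        raise InvalidInputError(f"malformed table {path}: {exc}") from exc


def read_square_matrix(path, kind: str = "sc"):
    """Read a labeled square matrix and validate the kind's invariants.

    kind 'sc' -> :class:`Connectome` (nonnegative, symmetric, zero
    diagonal); 'fc' -> :class:`FCMatrix` (entries in [-1,1], unit
    diagonal); 'fcd' -> :class:`FCDMatrix` (symmetric, unit diagonal).
    """
    df = _read_table(path)
    if df.shape[0] != df.shape[1]:
        raise InvalidInputError(
            f"{path}: expected a square matrix, got {df.shape[0]}x{df.shape[1]}"
        )
    values = df.to_numpy(dtype=float)
    labels = tuple(str(c) for c in df.columns)
    if kind == "sc":
        return Connectome(C=values, region_ids=labels)
    if kind == "fc":
        return FCMatrix(values=values, region_ids=labels)
    if kind == "fcd":
        return FCDMatrix(values=values, window_length=0)
    raise InvalidInputError(f"unknown matrix kind {kind!r}")


def write_square_matrix(obj, path) -> None:
    if isinstance(obj, Connectome):
        values, labels = obj.C, obj.region_ids
    elif isinstance(obj, FCMatrix):
        values, labels = obj.values, obj.region_ids
    elif isinstance(obj, FCDMatrix):
        values = obj.values
        labels = [f"window_{i}" for i in range(values.shape[0])]
    else:
        values = np.asarray(obj, dtype=float)
        labels = [f"region_{i}" for i in range(values.shape[0])]
    pd.DataFrame(values, index=labels, columns=labels).to_csv(
        path, sep="\t"
    )


def read_spatial_map(path, name: str | None = None) -> SpatialMap:
    """Two-column TSV (region id, value) -> SpatialMap."""
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"no such file: {path}")
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if df.shape[1] != 2:
        raise InvalidInputError(f"{path}: spatial map needs exactly 2 columns")
    return SpatialMap(
        values=df.iloc[:, 1].to_numpy(dtype=float), name=name or path.stem
    )


def write_spatial_map(m: SpatialMap, path, region_ids=None) -> None:
    ids = region_ids or [f"region_{i}" for i in range(len(m))]
    pd.DataFrame({"region": list(ids), "value": m.values}).to_csv(
        path, sep="\t", index=False
    )


def read_bold(path, tr: float) -> BoldTimeseries:
    df = _read_table(path)
    return BoldTimeseries(
        B=df.to_numpy(dtype=float).T if df.shape[0] > df.shape[1] else df.to_numpy(dtype=float),
        tr=tr,
        region_ids=tuple(str(i) for i in (df.columns if df.shape[0] > df.shape[1] else df.index)),
    )


def write_bold(bold: BoldTimeseries, path) -> None:
    pd.DataFrame(
        bold.B,
        index=list(bold.region_ids),
        columns=[f"frame_{t}" for t in range(bold.n_frames)],
    ).to_csv(path, sep="\t")


def read_expression(path) -> ExpressionMatrix:
    df = _read_table(path)
    return ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        gene_ids=tuple(str(i) for i in df.index),
        region_ids=tuple(str(c) for c in df.columns),
    )


def write_expression(expr: ExpressionMatrix, path) -> None:
    pd.DataFrame(
        expr.values, index=list(expr.gene_ids), columns=list(expr.region_ids)
    ).to_csv(path, sep="\t")


def read_centroids(path) -> ParcelCentroids:
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if df.shape[1] != 4:
        raise InvalidInputError("centroid table needs columns: region, x, y, z")
    return ParcelCentroids(
        xyz=df.iloc[:, 1:4].to_numpy(dtype=float),
        region_ids=tuple(str(r) for r in df.iloc[:, 0]),
    )


def write_centroids(c: ParcelCentroids, path) -> None:
    pd.DataFrame(
        {"region": list(c.region_ids), "x": c.xyz[:, 0], "y": c.xyz[:, 1], "z": c.xyz[:, 2]}
    ).to_csv(path, sep="\t", index=False)


def read_coefficients(path) -> LinearCoefficients:
    with open(path) as fh:
        data = json.load(fh)
    if isinstance(data, dict) and "coefficients" in data:
        data = data["coefficients"]
    if isinstance(data, list):
        return LinearCoefficients.from_array(data)
    return LinearCoefficients(**{k: float(v) for k, v in data.items()})


def write_coefficients(coeffs: LinearCoefficients, path) -> None:
    with open(path, "w") as fh:
        json.dump({"coefficients": coeffs.as_array().tolist()}, fh, indent=2)


def read_config(path) -> SimulationConfig:
    """YAML simulation config with keys dt, t_total, t_burn, tr, seed."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {"dt", "t_total", "t_burn", "tr", "seed"}
    unknown = set(data) - known
    if unknown:
        raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
    return SimulationConfig(**data)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def write_results(record: dict, path, inputs=(), seed: int | None = None) -> None:
    """Write a JSON result record with schema version, input digests and
    the seed; rereading reproduces every numeric value exactly."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "input_digests": {str(p): _digest(p) for p in inputs},
        "results": _jsonable(record),
    }
    try:
        text = json.dumps(payload, indent=2, allow_nan=False)
    except ValueError as exc:
        raise InvalidInputError(f"record is not JSON-serializable: {exc}") from exc
    Path(path).write_text(text)


def read_results(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
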