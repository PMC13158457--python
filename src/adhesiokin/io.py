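"""Readers/writers for force tables and run artifacts.

Interchange format for force-time data is CSV with the fixed header
``condition,time_min,force_pN,replicate`` (extra columns are ignored).
``write_results`` lays out one directory of deterministic artifact files and
a manifest with SHA-256 checksums.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import AdhesionDataset

__all__ = ["read_force_table", "write_force_table", "write_results"]

REQUIRED_COLUMNS = ("condition", "time_min", "force_pN", "replicate")


class SchemaError(ValueError):
    """The input table violates the expected column schema."""


def read_force_table(path) -> dict[str, AdhesionDataset]:
    """Read a force-time CSV into one dataset per condition.

    Raises :class:`SchemaError` naming any missing column, ``ValueError``
    with the offending row number for non-numeric cells or negative forces,
    and on empty files.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty file") from exc
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    for col in ("time_min", "force_pN", "replicate"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise ValueError(f"{path}: non-numeric value in column {col!r} "
                             f"at row {row}")
        df[col] = coerced
    if (df["force_pN"] < 0).any():
        row = int(np.flatnonzero((df["force_pN"] < 0).to_numpy())[0]) + 2
        raise ValueError(f"{path}: negative force at row {row}")
    return {
        str(cond): AdhesionDataset.from_frame(df, str(cond))
        for cond in df["condition"].unique()
    }


def write_force_table(datasets, path) -> None:
    """Write one or more datasets to the interchange CSV."""
    if isinstance(datasets, AdhesionDataset):
        datasets = [datasets]
    frames = [d.to_frame() for d in datasets]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


_ARTIFACT_FILES = {
    "sls_fit": "sls_fit.json",
    "pinn_history": "pinn_history.csv",
    "pinn_state": "pinn_state.json",
    "posterior": "posterior.csv",
    "diagnostics": "diagnostics.json",
    "predictive": "predictive_bands.csv",
    "loo_report": "loo_report.json",
    "sensitivity": "sensitivity.json",
    "correlations": "correlations.json",
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(outputs: dict, directory) -> dict:
    """Write stage outputs to a deterministic file layout plus manifest.

    ``outputs`` maps stage keys (see below) to objects already converted to
    their serializable form: dicts for JSON stages, DataFrames for CSV
    stages, and a JSON string for ``pinn_state``.  Returns the manifest
    (also written as ``manifest.json``) listing every artifact with its
    SHA-256 checksum.
    """
    if not outputs:
        raise ValueError("no stage outputs to write")
    unknown = set(outputs) - set(_ARTIFACT_FILES)
    if unknown:
        raise ValueError(f"unknown stage keys: {sorted(unknown)}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    written = []
    for key, obj in outputs.items():
        fname = _ARTIFACT_FILES[key]
        fpath = directory / fname
        if fname.endswith(".json"):
            if isinstance(obj, str):
                fpath.write_text(obj)
            else:
                fpath.write_text(json.dumps(obj, indent=2, sort_keys=True,
                                            default=_jsonify))
        else:
            obj.to_csv(fpath, index=False)
        written.append(fname)

    manifest = {
        "artifacts": [
            {"file": fname, "sha256": _sha256(directory / fname)}
            for fname in sorted(written)
        ]
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
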