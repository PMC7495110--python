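"""Delimited-text and sidecar I/O for cohorts and pipeline artifacts."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .prep import ComponentTimecourses, MotionParams

MANIFEST_COLUMNS = ["subject_id", "group", "timecourse_path", "motion_path", "cgi", "bdi", "bai"]


def write_matrix(path: Path | str, matrix: np.ndarray) -> None:
    np.savetxt(path, np.asarray(matrix), delimiter="\t", fmt="%.17g")


def _parse_numeric_lines(path: Path) -> np.ndarray:
    rows: list[list[float]] = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.replace(",", "\t").split()
            try:
                values = [float(t) for t in tokens]
            except ValueError as exc:
                if lineno == 1:  # header row with column names
                    continue
                raise ValueError(f"{path}: non-numeric value on line {lineno}") from exc
            if width is None:
                width = len(values)
            elif len(values) != width:
                raise ValueError(
                    f"{path}: ragged row on line {lineno} "
                    f"({len(values)} columns, expected {width})"
                )
            rows.append(values)
    if not rows:
        raise ValueError(f"{path}: no numeric data found")
    return np.asarray(rows)


def read_matrix(path: Path | str) -> np.ndarray:
    """Read a delimited numeric matrix; tolerates one header row of names."""
    return _parse_numeric_lines(Path(path))


def read_timecourses(
    path: Path | str,
    subject_id: str,
    group: str,
    tr_seconds: float = 2.0,
    expected_shape: tuple[int, int] | None = None,
) -> ComponentTimecourses:
    """Load one subject's T x C matrix, warning on unexpected shape."""
    data = read_matrix(path)
    if expected_shape is not None and data.shape != tuple(expected_shape):
        import warnings

        warnings.warn(
            f"{path}: shape {data.shape} differs from expected {tuple(expected_shape)}",
            stacklevel=2,
        )
    return ComponentTimecourses(subject_id=subject_id, group=group, data=data, tr_seconds=tr_seconds)


def write_timecourses(path: Path | str, tc: ComponentTimecourses) -> None:
    write_matrix(path, tc.data)


def read_motion(path: Path | str) -> MotionParams:
    """Motion stored as T rows x 6 columns on disk."""
    return MotionParams(read_matrix(path).T)


def write_motion(path: Path | str, mp: MotionParams) -> None:
    write_matrix(path, mp.data.T)


def write_manifest(path: Path | str, manifest: pd.DataFrame) -> None:
    manifest.to_csv(path, index=False)


def read_manifest(path: Path | str) -> pd.DataFrame:
    manifest = pd.read_csv(path)
    missing = [c for c in ("subject_id", "group", "timecourse_path") if c not in manifest.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing required columns {missing}")
    if manifest["subject_id"].duplicated().any():
        dups = manifest.loc[manifest["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"{path}: duplicate subject ids {dups}")
    bad_groups = set(manifest["group"]) - {"patient", "control"}
    if bad_groups:
        raise ValueError(f"{path}: unknown group labels {sorted(bad_groups)}")
    return manifest


def write_sidecar(path: Path | str, payload: dict) -> None:
    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=_default, allow_nan=True) + "\n")


def read_sidecar(path: Path | str) -> dict:
    return json.loads(Path(path).read_text())


def sha256_of(path: Path | str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
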