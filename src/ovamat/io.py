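"""Shared readers/writers, run configuration and JSON reports.

Hyperspectral cubes travel either as HDF5 (datasets ``wavenumbers``,
``cube`` with shape (channels, ny, nx), scalars ``x_step_um`` / ``y_step_um``)
or as long-format CSV with columns ``x, y, wavenumber, intensity``.  Pixel
order everywhere is row-major over (y, x): y outer, x inner.

Height/stiffness maps are plain whitespace- or comma-separated numeric
matrices, or single-page float TIFF.

Reports are JSON and always embed the tool version, a config hash, the seeds
used, input checksums and any warnings, so a run can be reproduced and
audited.  Readers validate shapes and never guess: a ragged grid or a
truncated matrix is an error naming the offender.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from ovamat import __version__
from ovamat.errors import FormatError, ParameterError
from ovamat.follicle import FollicleRecord
from ovamat.raman.types import HyperspectralMap

__all__ = [
    "read_cube",
    "write_cube",
    "read_matrix",
    "write_matrix",
    "read_follicle_records",
    "build_report",
    "write_report",
    "validate_report",
    "file_checksum",
]


# ---------------------------------------------------------------------------
# hyperspectral cubes
# ---------------------------------------------------------------------------

def read_cube(path) -> HyperspectralMap:
    """Read a hyperspectral map from HDF5 or long CSV.

    CSV grids must be rectangular (every (x, y) combination present with the
    same wavenumber axis); a malformed grid raises :class:`FormatError`
    naming the missing pixels.
    """
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            for name in ("wavenumbers", "cube"):
                if name not in f:
                    raise FormatError(f"{path}: missing dataset {name!r}")
            w = f["wavenumbers"][()]
            cube = f["cube"][()]

            def _step(name):
                if name in f:
                    return float(f[name][()])
                return float(f.attrs.get(name, 1.0))

            x_step = _step("x_step_um")
            y_step = _step("y_step_um")
        if cube.ndim != 3:
            raise FormatError(
                f"{path}: cube must be 3-D (channels, ny, nx), got "
                f"{cube.shape}"
            )
        n, ny, nx = cube.shape
        if n != w.size:
            raise FormatError(
                f"{path}: {n} cube channels vs {w.size} wavenumbers"
            )
        return HyperspectralMap(w, cube.reshape(n, ny * nx), (nx, ny),
                                x_step, y_step)
    return _read_cube_csv(path)


def _read_cube_csv(path) -> HyperspectralMap:
    df = pd.read_csv(path)
    needed = {"x", "y", "wavenumber", "intensity"}
    if not needed.issubset(df.columns):
        raise FormatError(
            f"{path}: long CSV needs columns {sorted(needed)}"
        )
    xs = np.sort(df["x"].unique())
    ys = np.sort(df["y"].unique())
    w = np.sort(df["wavenumber"].unique())
    expected = len(xs) * len(ys) * len(w)
    if len(df) != expected:
        have = {(x, y) for x, y in zip(df["x"], df["y"])}
        missing = [
            (float(x), float(y))
            for y in ys for x in xs if (x, y) not in have
        ]
        raise FormatError(
            f"{path}: ragged grid — {len(df)} rows, expected {expected}; "
            f"missing pixels (first 5): {missing[:5]}"
        )
    pivot = df.pivot_table(
        index="wavenumber", columns=["y", "x"], values="intensity",
        sort=True,
    )
    A = pivot.to_numpy()
    x_step = float(np.diff(xs).mean()) if len(xs) > 1 else 1.0
    y_step = float(np.diff(ys).mean()) if len(ys) > 1 else 1.0
    return HyperspectralMap(w, A, (len(xs), len(ys)), x_step, y_step)


def write_cube(hmap: HyperspectralMap, path) -> Path:
    """Write a map as HDF5 (.h5/.hdf5) or long CSV (anything else)."""
    path = Path(path)
    nx, ny = hmap.grid
    if path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("wavenumbers", data=hmap.wavenumbers)
            f.create_dataset(
                "cube", data=hmap.A.reshape(hmap.n_channels, ny, nx)
            )
            f.create_dataset("x_step_um", data=hmap.x_step)
            f.create_dataset("y_step_um", data=hmap.y_step)
            f.attrs["pixel_order"] = "row-major over (y, x): y outer, x inner"
        return path
    yy, xx = np.mgrid[0:ny, 0:nx]
    rows = {
        "x": np.tile(xx.reshape(-1) * hmap.x_step, hmap.n_channels),
        "y": np.tile(yy.reshape(-1) * hmap.y_step, hmap.n_channels),
        "wavenumber": np.repeat(hmap.wavenumbers, hmap.n_pixels),
        "intensity": hmap.A.reshape(-1),
    }
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# numeric matrices (AFM maps)
# ---------------------------------------------------------------------------

def read_matrix(path) -> np.ndarray:
    """Read a 2-D numeric matrix from whitespace/CSV text or float TIFF.

    A non-numeric cell raises :class:`FormatError` with its row/column;
    ragged rows and empty files are rejected.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = np.asarray(tifffile.imread(path), dtype=float)
        if arr.ndim != 2:
            raise FormatError(f"{path}: TIFF is not a single 2-D page")
        return arr
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    sep = "," if "," in lines[0] else None
    rows = []
    width = None
    for i, ln in enumerate(lines):
        cells = [c for c in (ln.split(sep) if sep else ln.split()) if c != ""]
        if width is None:
            width = len(cells)
        elif len(cells) != width:
            raise FormatError(
                f"{path}: row {i} has {len(cells)} cells, expected {width} "
                "(truncated or ragged file)"
            )
        row = []
        for j, c in enumerate(cells):
            try:
                row.append(float(c))
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell at row {i}, col {j}: {c!r}"
                ) from None
        rows.append(row)
    return np.asarray(rows, dtype=float)


def write_matrix(arr: np.ndarray, path) -> Path:
    path = Path(path)
    arr = np.asarray(arr, dtype=float)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr.astype(np.float32))
        return path
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    np.savetxt(path, arr, delimiter=sep, fmt="%.17g")
    return path


# ---------------------------------------------------------------------------
# follicle records
# ---------------------------------------------------------------------------

_BOOL_COLS = ("nucleus_visible", "antrum_present", "healthy")


def read_follicle_records(path) -> list:
    """Read FollicleRecord rows from CSV (column names match the fields)."""
    df = pd.read_csv(path)
    if "id" not in df.columns:
        raise FormatError(f"{path}: needs an 'id' column")
    records = []
    for _, row in df.iterrows():
        kwargs = {"id": str(row["id"])}
        for col in _BOOL_COLS:
            if col in df.columns:
                kwargs[col] = bool(row[col])
        if "granulosa_layers" in df.columns:
            kwargs["granulosa_layers"] = int(row["granulosa_layers"])
        if "granulosa_shape" in df.columns:
            kwargs["granulosa_shape"] = str(row["granulosa_shape"])
        for col in ("oocyte_diameter", "follicle_diameter"):
            if col in df.columns and pd.notna(row[col]):
                kwargs[col] = float(row[col])
        records.append(FollicleRecord(**kwargs))
    return records


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

REPORT_REQUIRED_KEYS = ("tool_version", "config_hash", "seeds",
                        "input_checksums", "warnings", "result")


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="list"))
    return obj


def build_report(
    result,
    config=None,
    seeds=None,
    inputs: Optional[Iterable] = None,
    warnings: Optional[list] = None,
) -> dict:
    """Assemble the canonical report envelope around a result payload.

    The config hash is the sha256 of the canonical (sorted-keys) JSON of the
    config, so identical configs hash identically across runs; timestamps
    are deliberately absent so re-runs produce byte-identical reports.
    """
    cfg = _jsonable(config) if config is not None else {}
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()
    checksums = {}
    for p in inputs or []:
        if p is not None and os.path.exists(p):
            checksums[str(p)] = file_checksum(p)
    return {
        "tool_version": __version__,
        "config_hash": cfg_hash,
        "config": cfg,
        "seeds": _jsonable(seeds) if seeds is not None else {},
        "input_checksums": checksums,
        "warnings": list(warnings or []),
        "result": _jsonable(result),
    }


def validate_report(report: dict) -> None:
    """Check the report envelope against the bundled schema contract."""
    for key in REPORT_REQUIRED_KEYS:
        if key not in report:
            raise FormatError(f"report missing required key {key!r}")
    if not isinstance(report["warnings"], list):
        raise FormatError("report 'warnings' must be a list")
    if not isinstance(report["input_checksums"], dict):
        raise FormatError("report 'input_checksums' must be a mapping")


def write_report(report: dict, path) -> Path:
    """Validate and write a report as indented JSON."""
    validate_report(report)
    path = Path(path)
    try:
        path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    except OSError as exc:
        raise ParameterError(f"cannot write report to {path}: {exc}") from exc
    return path
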