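"""Readers and writers: elevation-grid CSV, cohort manifests, JSON reports.

Device exports vary: comma- or semicolon-delimited grids (semicolon exports
use decimal commas), elevations in micrometers or millimeters, missing points
as blank cells, "NaN", or a -1000 sentinel.  Readers are total on these
dialects and loud on everything else — a cell that is neither numeric nor a
missing-value token is an error naming its row and column.

The JSON report schema is versioned (``schema_version``); every numeric field
carries its unit in its name.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from .errors import DimensionError, GridDialectError, ManifestError
from .grid import DEFAULT_N, DEFAULT_SPACING_MM, ElevationGrid

REPORT_SCHEMA_VERSION = "1.0"
MISSING_TOKENS = {"", "nan", "na"}
MISSING_SENTINEL = -1000.0


@dataclass(frozen=True)
class GridIOConfig:
    n: int = DEFAULT_N
    spacing_mm: float = DEFAULT_SPACING_MM
    source_units: str = "um"  # "um" or "mm"
    skip_lines: int = 0  # metadata/header lines before the grid
    center: Optional[tuple] = None
    side: str = "OD"
    layer: str = "anterior"


@dataclass
class ManifestEntry:
    pair_id: str
    od_anterior_path: str
    os_anterior_path: str
    od_posterior_path: str
    os_posterior_path: str
    label: str


@dataclass
class CohortManifest:
    entries: List[ManifestEntry]
    root: Path

    def __len__(self) -> int:
        return len(self.entries)


def _sniff_dialect(line: str) -> tuple:
    """Returns (delimiter, decimal).  Semicolon exports use decimal commas."""
    if ";" in line:
        return ";", ","
    return ",", "."


def _parse_cell(cell: str, row: int, col: int, decimal: str) -> float:
    token = cell.strip()
    if token.lower() in MISSING_TOKENS:
        return np.nan
    if decimal == ",":
        token = token.replace(",", ".")
    try:
        value = float(token)
    except ValueError:
        raise GridDialectError(
            f"non-numeric cell {cell!r} at row {row}, column {col}"
        ) from None
    if value == MISSING_SENTINEL:
        return np.nan
    return value


def read_elevation_csv(path, config: GridIOConfig = GridIOConfig()) -> ElevationGrid:
    """Read one elevation matrix.  Dimensions are checked against config and
    source units converted to the internal micrometers."""
    path = Path(path)
    lines = path.read_text().splitlines()[config.skip_lines :]
    lines = [ln for ln in lines if ln.strip() != ""]
    if not lines:
        raise DimensionError(f"{path}: no data rows (expected {config.n})")
    delim, decimal = _sniff_dialect(lines[0])
    rows = []
    for i, ln in enumerate(lines):
        cells = ln.split(delim)
        rows.append([_parse_cell(c, i, j, decimal) for j, c in enumerate(cells)])
    widths = {len(r) for r in rows}
    shape = (len(rows), widths.pop() if len(widths) == 1 else -1)
    if shape != (config.n, config.n):
        raise DimensionError(
            f"{path}: expected {config.n}x{config.n} grid, found "
            f"{len(rows)} rows x {sorted({len(r) for r in rows})} columns"
        )
    values = np.asarray(rows, dtype=float)
    if config.source_units == "mm":
        values = values * 1000.0
    elif config.source_units != "um":
        raise GridDialectError(f"unknown source_units {config.source_units!r}")
    return ElevationGrid(
        values=values,
        spacing_mm=config.spacing_mm,
        center=config.center,
        side=config.side,
        layer=config.layer,
        meta={"source": str(path)},
    )


def write_elevation_csv(grid: ElevationGrid, path) -> None:
    """Write a grid re-readable to equality: shortest round-trip decimal
    representation per value, missing points as empty cells, comma-delimited."""
    path = Path(path)
    with path.open("w") as fh:
        for row in grid.values:
            fh.write(
                ",".join("" if not np.isfinite(v) else repr(float(v)) for v in row)
            )
            fh.write("\n")


MANIFEST_COLUMNS = [
    "pair_id",
    "od_anterior_path",
    "os_anterior_path",
    "od_posterior_path",
    "os_posterior_path",
    "label",
]


def read_manifest(path) -> CohortManifest:
    """Read a cohort manifest CSV; validates columns, unique pair ids, and
    that every referenced file exists (paths resolved against the manifest's
    directory)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ManifestError(f"{path}: missing columns {missing_cols}")
    dup = df["pair_id"][df["pair_id"].duplicated()].tolist()
    if dup:
        raise ManifestError(f"{path}: duplicate pair_id values {sorted(set(dup))}")
    root = path.parent
    entries = []
    for _, row in df.iterrows():
        dangling = []
        for col in MANIFEST_COLUMNS[1:-1]:
            p = row[col]
            if p and not (root / p).exists():
                dangling.append(p)
        if dangling:
            raise ManifestError(
                f"{path}: pair {row['pair_id']!r} references missing files {dangling}"
            )
        entries.append(
            ManifestEntry(
                pair_id=row["pair_id"],
                od_anterior_path=row["od_anterior_path"],
                os_anterior_path=row["os_anterior_path"],
                od_posterior_path=row["od_posterior_path"],
                os_posterior_path=row["os_posterior_path"],
                label=row["label"].strip().lower(),
            )
        )
    return CohortManifest(entries=entries, root=root)


def write_manifest(manifest: CohortManifest, path) -> None:
    df = pd.DataFrame([dataclasses.asdict(e) for e in manifest.entries])
    df.to_csv(path, index=False)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, pd.DataFrame):
        return [
            {k: _jsonable(v) for k, v in rec.items()}
            for rec in obj.to_dict(orient="records")
        ]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj


def write_report(report, path) -> None:
    """Serialize an analysis/screening report (dataclass or dict) to JSON.

    Units are carried in field names (``*_um``, ``*_mm``, ``*_deg``); the
    schema version is stamped at the top level.
    """
    payload = _jsonable(report)
    if isinstance(payload, dict):
        payload = {"schema_version": REPORT_SCHEMA_VERSION, **payload}
    Path(path).write_text(json.dumps(payload, indent=2, allow_nan=False) + "\n")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
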