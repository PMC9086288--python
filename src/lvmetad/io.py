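"""PLUMED-dialect text files: COLVAR, HILLS and FES grids.

All artifacts are plain text.  Files written by this package begin
with a provenance comment block (tool version, config hash, seed)
followed by a PLUMED-style ``#! FIELDS ...`` header, so externally
produced PLUMED files can be read back and, conversely, our files can
be inspected with the usual command-line tools.  ``#! SET ...`` lines
are preserved on read into the table metadata.

Float formatting is fixed (%.6f for CVs and times, %.10g for
energies) so that re-running with the same config reproduces
byte-identical data sections.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError

__all__ = [
    "ColvarTable",
    "read_colvar",
    "write_colvar",
    "read_hills",
    "write_hills",
    "write_fes_grid",
    "read_fes_grid",
    "write_xyz",
    "config_hash",
    "TOOL_VERSION",
]

TOOL_VERSION = "lvmetad 0.1.0"

#: columns formatted at full precision (%.10g); everything else uses %.6f
ENERGY_COLUMNS = {"bias", "height", "free", "err", "energy", "weight"}

HILLS_FIELDS = [
    "time", "rho", "tau", "theta",
    "sigma_rho", "sigma_tau", "sigma_theta",
    "height", "biasf",
]


def config_hash(obj) -> str:
    """Short stable hash of a config-like object (dict/str)."""
    text = repr(obj) if not isinstance(obj, str) else obj
    return hashlib.sha256(text.encode()).hexdigest()[:12]


@dataclass
class ColvarTable:
    """Time series of CVs, instantaneous bias and observables.

    Thin wrapper over a pandas DataFrame (column-name addressed) plus
    provenance metadata (config hash, seed).  Construction validates
    the invariants: strictly increasing time, no NaN anywhere.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if "time" not in self.data.columns:
            raise SchemaError("COLVAR table needs a 'time' column")
        t = self.data["time"].to_numpy()
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise SchemaError("COLVAR time must be strictly increasing")
        if self.data.isna().any().any():
            bad = [c for c in self.data.columns if self.data[c].isna().any()]
            raise SchemaError(f"NaN values in COLVAR columns {bad}")

    def __len__(self) -> int:
        return len(self.data)

    def __getitem__(self, col: str) -> np.ndarray:
        if col not in self.data.columns:
            raise SchemaError(f"COLVAR table has no column {col!r}; have {list(self.data.columns)}")
        return self.data[col].to_numpy()

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)


# ---------------------------------------------------------------------------
# generic field-table machinery
# ---------------------------------------------------------------------------

def _provenance_lines(metadata: dict) -> list[str]:
    lines = [f"# {TOOL_VERSION}"]
    for key in ("config_hash", "seed"):
        if key in metadata:
            lines.append(f"# {key}: {metadata[key]}")
    return lines


def _format_row(values, columns) -> str:
    parts = []
    for v, c in zip(values, columns):
        if c in ENERGY_COLUMNS:
            parts.append(f"{v:.10g}")
        else:
            parts.append(f"{v:.6f}")
    return " ".join(parts)


def _write_field_table(df: pd.DataFrame, path, metadata: dict, set_lines: dict | None = None):
    path = Path(path)
    with path.open("w") as fh:
        for line in _provenance_lines(metadata or {}):
            fh.write(line + "\n")
        fh.write("#! FIELDS " + " ".join(df.columns) + "\n")
        for key, val in (set_lines or {}).items():
            fh.write(f"#! SET {key} {val}\n")
        cols = list(df.columns)
        for row in df.itertuples(index=False):
            fh.write(_format_row(row, cols) + "\n")


def _read_field_table(path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    columns: list[str] | None = None
    rows: list[list[float]] = []
    metadata: dict = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#!"):
                tokens = line.split()
                if len(tokens) >= 2 and tokens[1] == "FIELDS":
                    if columns is not None and rows:
                        # multi-block PLUMED file (restarted run): require same header
                        if tokens[2:] != columns:
                            raise ParseError("FIELDS header changed mid-file", lineno)
                        continue
                    columns = tokens[2:]
                elif len(tokens) >= 3 and tokens[1] == "SET":
                    metadata.setdefault("set", {})[tokens[2]] = " ".join(tokens[3:])
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    metadata[key.strip()] = val.strip()
                continue
            if columns is None:
                raise ParseError("data before '#! FIELDS' header", lineno)
            parts = line.split()
            if len(parts) != len(columns):
                raise ParseError(
                    f"ragged row: {len(parts)} values for {len(columns)} fields", lineno
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ParseError(f"non-numeric value: {exc}", lineno) from None
    if columns is None:
        raise ParseError(f"{path}: missing '#! FIELDS' header")
    return pd.DataFrame(rows, columns=columns), metadata


# ---------------------------------------------------------------------------
# COLVAR
# ---------------------------------------------------------------------------

def write_colvar(table: ColvarTable, path) -> None:
    _write_field_table(table.data, path, table.metadata)


def read_colvar(path) -> ColvarTable:
    df, metadata = _read_field_table(path)
    return ColvarTable(data=df, metadata=metadata)


# ---------------------------------------------------------------------------
# HILLS
# ---------------------------------------------------------------------------

def write_hills(hills_df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a HILLS table (columns per :data:`HILLS_FIELDS`)."""
    missing = set(HILLS_FIELDS) - set(hills_df.columns)
    if missing:
        raise SchemaError(f"HILLS table missing columns {sorted(missing)}")
    _write_field_table(hills_df[HILLS_FIELDS], path, metadata or {})


def read_hills(path) -> pd.DataFrame:
    """Read a HILLS file; returns a DataFrame.

    Accepts both this package's 3-CV layout and PLUMED HILLS files
    with matching column names.
    """
    df, _ = _read_field_table(path)
    if "time" not in df.columns or "height" not in df.columns:
        raise SchemaError(f"not a HILLS file: columns {list(df.columns)}")
    return df


# ---------------------------------------------------------------------------
# FES grid files
# ---------------------------------------------------------------------------

def write_fes_grid(fes, path, metadata: dict | None = None) -> None:
    """Write an FES2D-like object (x_edges/y_edges/F/err) as a grid file.

    Layout: "#! FIELDS d nhb free err", one row per cell centre in
    y-fastest order; unsampled cells carry free = err = NaN (written as
    'nan', accepted back by :func:`read_fes_grid`).
    """
    xc = 0.5 * (fes.x_edges[:-1] + fes.x_edges[1:])
    yc = 0.5 * (fes.y_edges[:-1] + fes.y_edges[1:])
    path = Path(path)
    with path.open("w") as fh:
        for line in _provenance_lines(metadata or {}):
            fh.write(line + "\n")
        fh.write("#! FIELDS d nhb free err\n")
        fh.write(f"#! SET kT {fes.kT:.10g}\n")
        for i, x in enumerate(xc):
            for j, y in enumerate(yc):
                fh.write(f"{x:.6f} {y:.6f} {fes.F[i, j]:.10g} {fes.err[i, j]:.10g}\n")

    return None


def write_xyz(positions, path, element: str = "X", comment: str = "") -> None:
    """Write guest positions (n_frames, 3) as a multi-frame XYZ file.

    Visualization convenience for 3D runs; 1D trajectories are better
    served by the COLVAR table.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    if pos.shape[-1] != 3:
        raise SchemaError("XYZ output needs (n, 3) coordinates")
    with Path(path).open("w") as fh:
        for frame in pos:
            fh.write(f"1\n{comment}\n{element} {frame[0]:.6f} {frame[1]:.6f} {frame[2]:.6f}\n")


def read_fes_grid(path) -> dict:
    """Read an FES grid file back into arrays (inverse of write_fes_grid)."""
    path = Path(path)
    xs, ys, free, err = [], [], [], []
    kT = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#!"):
                tokens = line.split()
                if tokens[1] == "SET" and tokens[2] == "kT":
                    kT = float(tokens[3])
                continue
            if line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ParseError("FES rows need 4 fields (d nhb free err)", lineno)
            x, y, f, e = (float(p) for p in parts)
            xs.append(x)
            ys.append(y)
            free.append(f)
            err.append(e)
    xu = np.unique(np.asarray(xs))
    yu = np.unique(np.asarray(ys))
    F = np.full((len(xu), len(yu)), np.nan)
    E = np.full((len(xu), len(yu)), np.nan)
    for x, y, f, e in zip(xs, ys, free, err):
        i = int(np.searchsorted(xu, x))
        j = int(np.searchsorted(yu, y))
        F[i, j] = f
        E[i, j] = e
    return {"x_centers": xu, "y_centers": yu, "F": F, "err": E, "kT": kT}
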