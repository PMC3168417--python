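"""Spectra containers and file I/O.

The canonical in-memory object is :class:`SpectraSet`: a samples x channels
absorbance matrix on a shared, strictly ascending wavenumber grid (cm^-1),
with one metadata record per row and an append-only log of the processing
steps that produced the matrix.

Two on-disk dialects are read: a wide CSV ("wavenumber,<id1>,<id2>,...",
one row per channel) which is also the write format, and single-spectrum
JCAMP-DX files with an (X++(Y..Y)) AFFN table.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ROLES",
    "META_COLUMNS",
    "SampleMeta",
    "SpectraSet",
    "load_spectra",
    "save_spectra",
    "attach_metadata",
    "read_jcamp",
    "base_id",
]

ROLES = ("unknown", "reference", "calibration")
META_COLUMNS = ("sample_id", "batch_id", "line_id", "replicate", "role")

#: separator between a leaf-sample id and its replicate-scan index.  The
#: primary scan carries the bare id; repeated scans of the same leaf (the
#: per-batch reference protocol) carry "<id>#s<k>".
SCAN_SEP = "#s"


def base_id(sample_id: str) -> str:
    """Leaf-sample id with any replicate-scan suffix removed."""
    return sample_id.split(SCAN_SEP, 1)[0]


@dataclass
class SampleMeta:
    """Per-row sample annotation."""

    sample_id: str
    batch_id: str = "default"
    line_id: str = ""
    replicate: int = 0
    role: str = "unknown"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.replicate < 0:
            raise ValueError("replicate index must be non-negative")


def _default_meta(sample_ids: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "batch_id": "default",
            "line_id": "",
            "replicate": 0,
            "role": "unknown",
        }
    )


@dataclass
class SpectraSet:
    """Absorbance matrix + wavenumber grid + per-sample metadata.

    Invariants (checked on construction): the grid is strictly increasing
    with at least 3 positive finite points, the matrix is finite with one
    row per metadata record and one column per grid point, and sample ids
    are unique.
    """

    grid: np.ndarray
    absorbance: np.ndarray
    meta: pd.DataFrame
    processing_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.grid.ndim != 1 or self.grid.size < 3:
            raise ValueError("wavenumber grid must be 1-D with at least 3 points")
        if not np.all(np.isfinite(self.grid)) or np.any(self.grid <= 0):
            raise ValueError("wavenumbers must be positive and finite")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("wavenumber grid must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance matrix contains non-finite values")
        if self.absorbance.shape != (len(self.meta), self.grid.size):
            raise ValueError(
                f"shape mismatch: absorbance {self.absorbance.shape}, "
                f"{len(self.meta)} metadata rows x {self.grid.size} channels"
            )
        if list(self.meta.columns) != list(META_COLUMNS):
            self.meta = self.meta.loc[:, list(META_COLUMNS)]
        ids = self.meta["sample_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValueError(f"duplicate sample ids: {dupes}")
        bad = set(self.meta["role"]) - set(ROLES)
        if bad:
            raise ValueError(f"unknown role values: {sorted(bad)}")
        self.meta = self.meta.reset_index(drop=True)

    # -- introspection -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_channels(self) -> int:
        return self.grid.size

    @property
    def sample_ids(self) -> list[str]:
        return self.meta["sample_id"].tolist()

    @property
    def batch_ids(self) -> list[str]:
        return sorted(self.meta["batch_id"].unique())

    def has_step(self, step: str) -> bool:
        return any(entry.get("step") == step for entry in self.processing_log)

    # -- derivation helpers (operations return new sets) ---------------
    def evolve(
        self,
        *,
        grid: np.ndarray | None = None,
        absorbance: np.ndarray | None = None,
        meta: pd.DataFrame | None = None,
        log_entry: dict | None = None,
    ) -> "SpectraSet":
        log = [dict(e) for e in self.processing_log]
        if log_entry is not None:
            log.append(dict(log_entry))
        return SpectraSet(
            grid=self.grid.copy() if grid is None else np.asarray(grid, float),
            absorbance=self.absorbance.copy() if absorbance is None else np.asarray(absorbance, float),
            meta=(self.meta if meta is None else meta).copy(),
            processing_log=log,
        )

    def select(self, sample_ids: Iterable[str]) -> "SpectraSet":
        wanted = list(sample_ids)
        pos = {sid: i for i, sid in enumerate(self.sample_ids)}
        missing = [s for s in wanted if s not in pos]
        if missing:
            raise KeyError(f"sample ids not in set: {missing}")
        idx = [pos[s] for s in wanted]
        return self.evolve(
            absorbance=self.absorbance[idx],
            meta=self.meta.iloc[idx],
        )

    def batch(self, batch_id: str) -> "SpectraSet":
        mask = self.meta["batch_id"] == batch_id
        if not mask.any():
            raise KeyError(f"batch {batch_id!r} not present")
        return self.evolve(absorbance=self.absorbance[mask.to_numpy()], meta=self.meta[mask])


# ---------------------------------------------------------------------
# wide-matrix CSV
# ---------------------------------------------------------------------

def _read_wide_csv(path: Path) -> SpectraSet:
    with open(path) as fh:
        header = fh.readline().strip()
    cols = [c.strip() for c in header.split(",")]
    if len(cols) < 2:
        raise ValueError(f"{path}: expected 'wavenumber,<id>,...' header")
    sample_ids = cols[1:]
    seen: set[str] = set()
    for sid in sample_ids:
        if sid in seen:
            raise ValueError(f"{path}: duplicate sample id {sid!r} in header")
        seen.add(sid)

    df = pd.read_csv(path, header=0, names=cols, dtype=str, skipinitialspace=True)
    values = np.empty((len(df), len(cols)))
    for j, col in enumerate(cols):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if converted.isna().any():
            row = int(np.argmax((converted.isna() | bad).to_numpy()))
            raise ValueError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} at data row "
                f"{row + 1}, column {col!r}"
            )
        values[:, j] = converted.to_numpy()
    wavenumber = values[:, 0]
    order = np.argsort(wavenumber, kind="stable")
    grid = wavenumber[order]
    if np.any(np.diff(grid) <= 0):
        dup = grid[:-1][np.diff(grid) <= 0]
        raise ValueError(f"{path}: duplicate wavenumber(s) {np.unique(dup).tolist()}")
    absorbance = values[order, 1:].T  # samples x channels
    return SpectraSet(
        grid=grid,
        absorbance=absorbance,
        meta=_default_meta(sample_ids),
        processing_log=[{"step": "loaded", "path": path.name, "format": "wide-csv"}],
    )


# ---------------------------------------------------------------------
# JCAMP-DX (single spectrum, AFFN (X++(Y..Y)) tables)
# ---------------------------------------------------------------------

_LDR = re.compile(r"^##\s*([^=]+?)\s*=\s*(.*)$")


def read_jcamp(path: str | Path) -> SpectraSet:
    """Read one spectrum from a JCAMP-DX file.

    Honors ##XFACTOR, ##YFACTOR, ##FIRSTX/##LASTX/##NPOINTS for an
    ``(X++(Y..Y))`` numeric (AFFN) table.  Compressed ordinate encodings
    (SQZ/DIF/DUP) and multi-block files are not supported.
    """
    path = Path(path)
    labels: dict[str, str] = {}
    ydata: list[float] = []
    in_table = False
    title = path.stem
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("$$"):
                continue
            m = _LDR.match(line)
            if m:
                key = m.group(1).upper().replace(" ", "")
                val = m.group(2).split("$$")[0].strip()
                if key == "TITLE" and val:
                    title = val
                if key in ("XYDATA", "DATATABLE"):
                    if "X++(Y..Y)" not in val.replace(" ", ""):
                        raise ValueError(f"{path}: unsupported data table {val!r}")
                    in_table = True
                    continue
                if key == "END":
                    in_table = False
                labels[key] = val
                continue
            if in_table:
                nums = re.split(r"[,\s]+", line)
                try:
                    row = [float(tok) for tok in nums if tok]
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: non-numeric token in data table line {line!r}"
                    ) from exc
                # first number on each line is the abscissa of that line
                ydata.extend(row[1:])
    required = ("FIRSTX", "LASTX", "NPOINTS")
    missing = [k for k in required if k not in labels]
    if missing:
        raise ValueError(f"{path}: missing JCAMP labels {missing}")
    npoints = int(float(labels["NPOINTS"]))
    if len(ydata) != npoints:
        raise ValueError(
            f"{path}: ##NPOINTS={npoints} but table holds {len(ydata)} ordinates"
        )
    # FIRSTX/LASTX are in actual units; YFACTOR scales the stored
    # ordinates (XFACTOR applies only to in-table abscissas, which the
    # evenly spaced (X++(Y..Y)) form reconstructs from FIRSTX/LASTX)
    yfactor = float(labels.get("YFACTOR", 1.0))
    firstx = float(labels["FIRSTX"])
    lastx = float(labels["LASTX"])
    x = np.linspace(firstx, lastx, npoints)
    y = np.asarray(ydata, dtype=float) * yfactor
    order = np.argsort(x, kind="stable")
    return SpectraSet(
        grid=x[order],
        absorbance=y[order][None, :],
        meta=_default_meta([title]),
        processing_log=[{"step": "loaded", "path": path.name, "format": "jcamp-dx"}],
    )


# ---------------------------------------------------------------------
# public load / save / metadata
# ---------------------------------------------------------------------

def _looks_like_jcamp(path: Path) -> bool:
    if path.suffix.lower() in (".jdx", ".dx", ".jcm"):
        return True
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return line.lstrip().startswith("##")
    return False


def load_spectra(path: str | Path, meta_path: str | Path | None = None) -> SpectraSet:
    """Load spectra from a wide CSV or a single-spectrum JCAMP-DX file.

    The grid is sorted ascending on load (absorbance columns reordered
    consistently).  Without ``meta_path`` every sample defaults to
    role=unknown in batch "default".
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sset = read_jcamp(path) if _looks_like_jcamp(path) else _read_wide_csv(path)
    if meta_path is not None:
        table = pd.read_csv(meta_path, dtype={"sample_id": str})
        sset = attach_metadata(sset, table)
    return sset


def save_spectra(sset: SpectraSet, path: str | Path) -> None:
    """Write a wide CSV plus ``<stem>.meta.csv`` and ``<stem>.log.json`` sidecars."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(sset.absorbance.T, columns=sset.sample_ids)
    df.insert(0, "wavenumber", sset.grid)
    df.to_csv(path, index=False, float_format="%.17g")
    sset.meta.to_csv(path.with_suffix(".meta.csv"), index=False)
    with open(path.with_suffix(".log.json"), "w") as fh:
        json.dump(sset.processing_log, fh, indent=1)


def attach_metadata(sset: SpectraSet, table: pd.DataFrame) -> SpectraSet:
    """Replace the metadata with records from ``table`` (row order unchanged).

    Every sample id in the set must appear exactly once in the table.
    """
    table = table.copy()
    if "sample_id" not in table.columns:
        raise ValueError("metadata table lacks a 'sample_id' column")
    table["sample_id"] = table["sample_id"].astype(str)
    if table["sample_id"].duplicated().any():
        dupes = sorted(table["sample_id"][table["sample_id"].duplicated()].unique())
        raise ValueError(f"duplicate sample ids in metadata table: {dupes}")
    missing = [s for s in sset.sample_ids if s not in set(table["sample_id"])]
    if missing:
        raise ValueError(f"metadata table missing sample ids: {missing}")
    defaults = {"batch_id": "default", "line_id": "", "replicate": 0, "role": "unknown"}
    for col, val in defaults.items():
        if col not in table.columns:
            table[col] = val
    bad = set(table["role"]) - set(ROLES)
    if bad:
        raise ValueError(f"unknown role values in metadata table: {sorted(bad)}")
    indexed = table.set_index("sample_id")
    meta = indexed.loc[sset.sample_ids, ["batch_id", "line_id", "replicate", "role"]].reset_index()
    meta["replicate"] = meta["replicate"].astype(int)
    return sset.evolve(meta=meta, log_entry={"step": "metadata_attached"})
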