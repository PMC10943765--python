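"""Spectral data model and I/O.

A :class:`SpectraSet` holds an aligned absorbance matrix on a single
wavenumber grid together with per-row sample metadata.  It is the currency
every other module consumes: preprocessing transforms it, correlation
spectroscopy summarises it, and the latent-variable models are calibrated
on its rows.

Spectra are exchanged as delimited wide tables: the first column is the
wavenumber in cm^-1 (nominally 4000 down to 450 in 4 cm^-1 steps), every
further column is one scan.  A separate metadata table maps scan column
names to (sample_id, month, part, replicate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpectraSet",
    "SpectraFormatError",
    "read_spectra",
    "write_spectra",
    "average_replicates",
    "restrict_range",
]

#: grids are considered shared when they agree pointwise to this tolerance (cm^-1)
GRID_ATOL = 1e-6

META_COLUMNS = ("sample_id", "month", "part", "replicate")
PARTS = ("stem", "leaf")


class SpectraFormatError(ValueError):
    """Raised for malformed spectral files, metadata or grids."""


@dataclass
class SpectraSet:
    """Absorbance matrix (rows = spectra) on one strictly monotone grid.

    Parameters
    ----------
    wavenumbers : ndarray, shape (p,)
        Strictly monotone wavenumber grid in cm^-1.
    absorbance : ndarray, shape (n, p)
        Absorbance in AU; must be finite.
    meta : DataFrame with columns sample_id, month, part, replicate
        One row of metadata per spectrum, aligned with ``absorbance``.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        diffs = np.diff(self.wavenumbers)
        if len(self.wavenumbers) > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise SpectraFormatError("wavenumber grid must be strictly monotone")
        if self.absorbance.shape[1] != len(self.wavenumbers):
            raise SpectraFormatError(
                f"absorbance has {self.absorbance.shape[1]} columns but the grid "
                f"has {len(self.wavenumbers)} points"
            )
        if not np.isfinite(self.absorbance).all():
            raise SpectraFormatError("absorbance contains non-finite values")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise SpectraFormatError(f"metadata is missing columns {missing}")
        if len(self.meta) != self.absorbance.shape[0]:
            raise SpectraFormatError("metadata row count does not match spectra")
        key = self.meta[list(META_COLUMNS)]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].to_dict()
            raise SpectraFormatError(f"duplicate spectrum key {dup}")
        self.meta = self.meta.reset_index(drop=True)

    # -- basic container protocol -------------------------------------
    @property
    def n_spectra(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_points(self) -> int:
        return self.absorbance.shape[1]

    def same_grid(self, other: "SpectraSet") -> bool:
        return self.n_points == other.n_points and np.allclose(
            self.wavenumbers, other.wavenumbers, rtol=0.0, atol=GRID_ATOL
        )

    def select(self, mask) -> "SpectraSet":
        """Row subset by boolean mask or integer index array."""
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SpectraSet(
            self.wavenumbers.copy(),
            self.absorbance[idx].copy(),
            self.meta.iloc[idx].reset_index(drop=True),
        )

    def with_absorbance(self, values: np.ndarray) -> "SpectraSet":
        """Same grid and metadata, new absorbance matrix."""
        return SpectraSet(self.wavenumbers.copy(), np.asarray(values, float), self.meta.copy())


def _read_table(path) -> pd.DataFrame:
    """Read a delimited table; comma is the default dialect, tab accepted."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] == 1:  # probably tab separated
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return df


def read_spectra(path, meta_path) -> SpectraSet:
    """Load a wide spectral table plus its metadata table.

    The spectral file has one header row; its first column is the wavenumber
    and every other column one scan.  ``meta_path`` is a CSV with columns
    ``column`` (the scan's column name in the spectral file) and the four
    metadata fields.  Rows are ordered as the spectral file's columns; an
    unsorted wavenumber column is sorted to a monotone (descending) grid with
    absorbance values carried along.
    """
    df = _read_table(path)
    if df.shape[1] < 2:
        raise SpectraFormatError(f"{path}: need a wavenumber column plus at least one scan")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SpectraFormatError(f"{path}: non-numeric cell at row {row}, column {col!r}")
    if df.isna().any().any():
        raise SpectraFormatError(f"{path}: missing values in spectral table")

    grid = df.iloc[:, 0].to_numpy(dtype=float)
    values = df.iloc[:, 1:].to_numpy(dtype=float).T  # rows = scans
    if len(np.unique(grid)) != len(grid):
        raise SpectraFormatError(f"{path}: duplicated wavenumbers in grid")
    diffs = np.diff(grid)
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        order = np.argsort(grid)[::-1]  # sort to the conventional 4000 -> 450 direction
        grid = grid[order]
        values = values[:, order]

    meta = pd.read_csv(meta_path)
    if "column" not in meta.columns:
        raise SpectraFormatError(f"{meta_path}: metadata needs a 'column' field")
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise SpectraFormatError(f"{meta_path}: metadata is missing columns {missing}")
    meta = meta.set_index("column")
    scan_cols = list(df.columns[1:])
    absent = [c for c in scan_cols if c not in meta.index]
    if absent:
        raise SpectraFormatError(f"{meta_path}: no metadata for scan columns {absent}")
    meta = meta.loc[scan_cols, list(META_COLUMNS)].reset_index(drop=True)
    meta["month"] = meta["month"].astype(int)
    meta["replicate"] = meta["replicate"].astype(int)
    return SpectraSet(grid, values, meta)


def write_spectra(s: SpectraSet, path, meta_path) -> None:
    """Write a SpectraSet back to the wide-table + metadata representation.

    Round-trips with :func:`read_spectra` at full float precision.
    """
    cols = [f"scan{i}" for i in range(s.n_spectra)]
    df = pd.DataFrame(s.absorbance.T, columns=cols)
    df.insert(0, "wavenumber", s.wavenumbers)
    df.to_csv(path, index=False, float_format="%.17g")
    meta = s.meta[list(META_COLUMNS)].copy()
    meta.insert(0, "column", cols)
    meta.to_csv(meta_path, index=False)


def average_replicates(s: SpectraSet) -> SpectraSet:
    """Average replicate scans to one spectrum per (sample_id, month, part).

    Instrument protocols take several consecutive scans per sample; analysis
    runs on their arithmetic mean.  Output rows are sorted by
    (month, part, sample_id) and the replicate field is reset to 1.
    Idempotent; an empty input gives an empty output.
    """
    if s.n_spectra == 0:
        return s
    frame = s.meta.copy()
    frame["_row"] = np.arange(s.n_spectra)
    groups = frame.groupby(["month", "part", "sample_id"], sort=True)
    rows, meta_rows = [], []
    for (month, part, sample_id), g in groups:
        rows.append(s.absorbance[g["_row"].to_numpy()].mean(axis=0))
        meta_rows.append(
            {"sample_id": sample_id, "month": month, "part": part, "replicate": 1}
        )
    return SpectraSet(
        s.wavenumbers.copy(), np.vstack(rows), pd.DataFrame(meta_rows)
    )


def restrict_range(s: SpectraSet, lo: float, hi: float) -> SpectraSet:
    """Keep only grid points with ``lo <= wavenumber <= hi`` (closed interval).

    Column order is preserved.  Raises if the interval is empty on this grid.
    """
    if not lo < hi:
        raise ValueError(f"need lo < hi, got [{lo}, {hi}]")
    keep = (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
    if not keep.any():
        raise SpectraFormatError(
            f"no grid points in [{lo}, {hi}] cm^-1 (grid spans "
            f"{s.wavenumbers.min():g}-{s.wavenumbers.max():g})"
        )
    return SpectraSet(s.wavenumbers[keep], s.absorbance[:, keep], s.meta.copy())
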