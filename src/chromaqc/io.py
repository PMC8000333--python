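"""Chromatogram and peak-table I/O.

The canonical on-disk chromatogram format is a two-row delimited text file:
the first row holds the retention times in minutes and the second row the
detector intensities in absorbance units (AU).  A row-per-point two-column
dialect is auto-detected by shape.  ANDI/AIA chromatograms (NetCDF-3
"CDF" exports) are read through :func:`scipy.io.netcdf_file`; only the
standard ordinate/run-time variables are interpreted.

Peak tables (samples x named peaks, integrated areas in AU*min) travel as
delimited text with a ``sample_id`` column, an optional ``level`` column of
nominal concentrations (ug/mL) and one column per peak.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Chromatogram",
    "PeakTable",
    "ChromatogramParseError",
    "ChromatogramValidationError",
    "read_chromatogram",
    "write_chromatogram",
    "read_peak_table",
    "write_peak_table",
    "write_report_tables",
    "peak_name",
]

ROLES = ("calibration", "batch", "reference", "unknown")


class ChromatogramParseError(ValueError):
    """Raised when a chromatogram file cannot be parsed."""


class ChromatogramValidationError(ValueError):
    """Raised when parsed data violate the trace invariants."""


def peak_name(center: float) -> str:
    """Name a peak by its retention time rounded to 2 decimals."""
    return f"peak_{center:.2f}"


@dataclass(frozen=True)
class Chromatogram:
    """A single-channel detector trace.

    Parameters
    ----------
    sample_id : str
        Identifier of the injected sample.
    time : ndarray
        Retention times in minutes, strictly increasing.
    intensity : ndarray
        Detector response in AU, same length as ``time``.
    level : float, optional
        Nominal concentration in ug/mL (calibration standards).
    role : str
        One of ``calibration``, ``batch``, ``reference``, ``unknown``.
    """

    sample_id: str
    time: np.ndarray
    intensity: np.ndarray
    level: Optional[float] = None
    role: str = "unknown"

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "intensity", y)
        if t.ndim != 1 or y.ndim != 1:
            raise ChromatogramValidationError("time and intensity must be 1-D")
        if t.size != y.size:
            raise ChromatogramValidationError(
                f"length mismatch: {t.size} times vs {y.size} intensities"
            )
        if t.size < 2:
            raise ChromatogramValidationError("a trace needs at least 2 points")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise ChromatogramValidationError("non-finite values in trace")
        if not np.all(np.diff(t) > 0):
            i = int(np.argmin(np.diff(t) > 0))
            raise ChromatogramValidationError(
                f"time must be strictly increasing (violated near index {i + 1})"
            )
        if self.role not in ROLES:
            raise ChromatogramValidationError(f"unknown role {self.role!r}")

    def __len__(self) -> int:
        return int(self.time.size)

    def with_intensity(self, intensity: np.ndarray) -> "Chromatogram":
        return replace(self, intensity=np.asarray(intensity, dtype=float))


@dataclass
class PeakTable:
    """Integrated peak areas for a set of samples.

    ``areas`` has shape (n_samples, n_peaks) in AU*min; peaks carry
    retention-time based names such as ``peak_7.28``.
    """

    sample_ids: list
    peak_names: list
    areas: np.ndarray
    levels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.peak_names = list(self.peak_names)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.shape != (len(self.sample_ids), len(self.peak_names)):
            raise ValueError(
                f"areas shape {self.areas.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.peak_names)} peaks"
            )
        if len(set(self.peak_names)) != len(self.peak_names):
            dupes = sorted({n for n in self.peak_names if self.peak_names.count(n) > 1})
            raise ValueError(f"duplicate peak names: {dupes}")
        if np.any(self.areas < 0):
            raise ValueError("negative peak areas are not allowed")
        if self.levels is not None:
            self.levels = np.asarray(self.levels, dtype=float)
            if self.levels.size != len(self.sample_ids):
                raise ValueError("levels length must match sample count")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_peaks(self) -> int:
        return len(self.peak_names)

    def row(self, sample_id: str) -> np.ndarray:
        return self.areas[self.sample_ids.index(sample_id)]

    def subset(self, peaks: Sequence[str]) -> "PeakTable":
        """Restrict the table to the given peaks, in the given order."""
        idx = [self.peak_names.index(p) for p in peaks]
        return PeakTable(self.sample_ids, list(peaks), self.areas[:, idx], self.levels)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.areas, index=self.sample_ids, columns=self.peak_names)
        df.index.name = "sample_id"
        if self.levels is not None:
            df.insert(0, "level", self.levels)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PeakTable":
        levels = None
        if "level" in df.columns:
            levels = df["level"].to_numpy(dtype=float)
            df = df.drop(columns=["level"])
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float), levels)


def _parse_delimited(path: Path, delimiter: str) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                rows.append([float(tok) for tok in line.split(delimiter)])
            except ValueError as exc:
                raise ChromatogramParseError(
                    f"{path}: cannot parse row {lineno}: {exc}"
                ) from None
    if not rows:
        raise ChromatogramParseError(f"{path}: no data rows")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ChromatogramParseError(f"{path}: ragged rows with lengths {sorted(lengths)}")
    return np.asarray(rows, dtype=float)


def read_chromatogram(
    path: os.PathLike | str,
    format: str = "tworow_text",
    delimiter: str = ",",
    sample_id: Optional[str] = None,
    level: Optional[float] = None,
    role: str = "unknown",
) -> Chromatogram:
    """Read a chromatogram from disk.

    ``tworow_text`` expects the time row above the intensity row; a file of
    shape (n, 2) is transparently treated as the long (row-per-point)
    dialect.  ``andi_netcdf`` reads an ANDI/AIA NetCDF-3 chromatogram.
    Times are returned in minutes and intensities unchanged.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    if format == "tworow_text":
        mat = _parse_delimited(path, delimiter)
        if mat.shape[0] == 2 and mat.shape[1] != 2:
            t, y = mat[0], mat[1]
        elif mat.shape[1] == 2:
            t, y = mat[:, 0], mat[:, 1]
        elif mat.shape[0] == 2:  # genuinely 2x2: two-row wins by convention
            t, y = mat[0], mat[1]
        else:
            raise ChromatogramParseError(
                f"{path}: expected 2 rows or 2 columns, got shape {mat.shape}"
            )
        return Chromatogram(sample_id, t, y, level=level, role=role)
    if format == "andi_netcdf":
        return _read_andi(path, sample_id=sample_id, level=level, role=role)
    raise ValueError(f"unknown format {format!r}")


def _read_andi(path: Path, sample_id: str, level, role) -> Chromatogram:
    from scipy.io import netcdf_file

    with netcdf_file(str(path), "r", mmap=False) as nc:
        if "ordinate_values" not in nc.variables:
            raise ChromatogramParseError(f"{path}: no ordinate_values variable")
        y = np.array(nc.variables["ordinate_values"][:], dtype=float)
        if "raw_data_retention" in nc.variables:
            t_sec = np.array(nc.variables["raw_data_retention"][:], dtype=float)
        else:
            n = y.size
            delay = float(getattr(nc, "actual_delay_time", 0.0))
            interval = float(getattr(nc, "actual_sampling_interval", 0.0))
            if interval <= 0 and "actual_run_time_length" in dir(nc):
                interval = float(nc.actual_run_time_length) / max(n - 1, 1)
            if interval <= 0:
                raise ChromatogramParseError(
                    f"{path}: no retention axis or sampling interval"
                )
            t_sec = delay + interval * np.arange(n)
    return Chromatogram(sample_id, t_sec / 60.0, y, level=level, role=role)


def write_chromatogram(
    chrom: Chromatogram, path: os.PathLike | str, delimiter: str = ","
) -> None:
    """Write the two-row text representation (full double precision)."""
    with open(path, "w") as fh:
        fh.write(delimiter.join(repr(float(v)) for v in chrom.time) + "\n")
        fh.write(delimiter.join(repr(float(v)) for v in chrom.intensity) + "\n")


def read_peak_table(path: os.PathLike | str, delimiter: str = ",") -> PeakTable:
    """Read a samples x peaks area table (header row of peak names)."""
    with open(path) as fh:
        header = fh.readline().strip().split(delimiter)
    dupes = sorted({c for c in header if header.count(c) > 1})
    if dupes:
        raise ValueError(f"{path}: duplicated peak columns {dupes}")
    df = pd.read_csv(path, sep=delimiter, index_col="sample_id")
    return PeakTable.from_frame(df)


def write_peak_table(
    table: PeakTable, path: os.PathLike | str, delimiter: str = ","
) -> None:
    table.to_frame().to_csv(path, sep=delimiter, float_format="%.12g")


def write_report_tables(
    results: Mapping[str, pd.DataFrame],
    outdir: os.PathLike | str,
    decimals: int = 2,
    delimiter: str = ",",
) -> list:
    """Write each named DataFrame as ``<name>.csv`` with fixed formatting.

    Numeric columns are rounded to ``decimals`` places at serialization;
    identical inputs produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(results):
        df = results[name]
        dest = outdir / f"{name}.csv"
        df.to_csv(dest, sep=delimiter, float_format=f"%.{decimals}f")
        written.append(dest)
    return written
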