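"""Spectrum containers and plain-text I/O.

An FTIR absorbance spectrum lives on a uniform, descending wavenumber grid
(instrument convention).  A :class:`SpectraSet` is the X-matrix of a
chemometric analysis: many spectra sharing one grid, with per-spectrum
metadata (strain, medium, run, well, technical replicate).

On-disk format: a wide tab-separated table whose first column is the
wavenumber and whose remaining columns are spectra (header row carries the
spectrum ids), plus an optional sidecar metadata CSV keyed by ``spectrum_id``.
A minimal JCAMP-DX reader (single-block ``XYDATA=(X++(Y..Y))`` dialect,
``AFFN`` form) is provided as an import convenience.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Relative tolerance for grid uniformity / equality checks.
GRID_RTOL = 1e-9

METADATA_COLUMNS = ("spectrum_id", "sample_id", "strain", "medium", "run",
                    "well", "replicate")


class SpectraError(ValueError):
    """Malformed spectra input (ragged grids, non-numeric cells, ...)."""


def _check_grid(wavenumbers: np.ndarray) -> np.ndarray:
    wn = np.asarray(wavenumbers, dtype=float)
    if wn.ndim != 1 or wn.size < 2:
        raise SpectraError("wavenumber grid must be 1-D with at least 2 points")
    steps = np.diff(wn)
    if not np.all(steps < 0):
        raise SpectraError("wavenumber grid must be strictly descending")
    scale = abs(steps[0])
    if np.max(np.abs(steps - steps[0])) > GRID_RTOL * max(scale, abs(wn[0])):
        raise SpectraError("wavenumber grid must be uniformly spaced")
    return wn


@dataclass
class Spectrum:
    """One absorbance trace on a uniform descending wavenumber grid."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = _check_grid(self.wavenumbers)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.shape != self.wavenumbers.shape:
            raise SpectraError(
                f"absorbance length {self.absorbance.size} != grid length "
                f"{self.wavenumbers.size}")

    @property
    def spacing(self) -> float:
        """Grid spacing in cm^-1 (positive)."""
        return float(abs(self.wavenumbers[1] - self.wavenumbers[0]))

    def index_of(self, wavenumber: float) -> int:
        """Index of the grid point nearest ``wavenumber``."""
        return int(np.argmin(np.abs(self.wavenumbers - wavenumber)))

    def window(self, high: float, low: float) -> np.ndarray:
        """Boolean mask selecting grid points in [low, high] cm^-1."""
        if low > high:
            high, low = low, high
        return (self.wavenumbers <= high) & (self.wavenumbers >= low)


class SpectraSet:
    """Aligned collection of spectra sharing one wavenumber grid.

    Stores the absorbance traces as an ``(n_spectra, n_points)`` matrix and
    the per-spectrum metadata as a DataFrame indexed like the matrix rows.
    """

    def __init__(self, wavenumbers: np.ndarray, absorbance: np.ndarray,
                 metadata: pd.DataFrame | None = None):
        self.wavenumbers = _check_grid(wavenumbers)
        A = np.atleast_2d(np.asarray(absorbance, dtype=float))
        if A.shape[1] != self.wavenumbers.size:
            raise SpectraError(
                f"absorbance matrix has {A.shape[1]} columns, grid has "
                f"{self.wavenumbers.size} points")
        self.absorbance = A
        if metadata is None:
            metadata = pd.DataFrame(
                {"spectrum_id": [f"s{i}" for i in range(A.shape[0])]})
        if len(metadata) != A.shape[0]:
            raise SpectraError("metadata rows do not match spectra count")
        self.metadata = metadata.reset_index(drop=True)

    # -- basic container protocol -------------------------------------
    def __len__(self) -> int:
        return self.absorbance.shape[0]

    def __iter__(self) -> Iterator[Spectrum]:
        for i in range(len(self)):
            yield self[i]

    def __getitem__(self, i: int) -> Spectrum:
        return Spectrum(self.wavenumbers, self.absorbance[i],
                        dict(self.metadata.iloc[i]))

    @property
    def spacing(self) -> float:
        return float(abs(self.wavenumbers[1] - self.wavenumbers[0]))

    @property
    def ids(self) -> list[str]:
        if "spectrum_id" in self.metadata:
            return [str(x) for x in self.metadata["spectrum_id"]]
        return [f"s{i}" for i in range(len(self))]

    def same_grid(self, other: "SpectraSet") -> bool:
        if self.wavenumbers.size != other.wavenumbers.size:
            return False
        scale = abs(self.wavenumbers[0])
        return bool(np.max(np.abs(self.wavenumbers - other.wavenumbers))
                    <= GRID_RTOL * max(scale, 1.0))

    def select(self, mask) -> "SpectraSet":
        """Row subset by boolean mask or integer index array."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.nonzero(mask)[0]
        else:
            idx = mask
        return SpectraSet(self.wavenumbers, self.absorbance[idx],
                          self.metadata.iloc[idx])

    def restrict(self, high: float, low: float) -> "SpectraSet":
        """Sub-grid between two wavenumbers (inclusive, snapped to grid)."""
        if low > high:
            high, low = low, high
        m = (self.wavenumbers <= high) & (self.wavenumbers >= low)
        if m.sum() < 2:
            raise SpectraError(
                f"region {high}-{low} cm^-1 covers fewer than 2 grid points")
        return SpectraSet(self.wavenumbers[m], self.absorbance[:, m],
                          self.metadata)

    @classmethod
    def from_spectra(cls, spectra: Iterable[Spectrum]) -> "SpectraSet":
        spectra = list(spectra)
        if not spectra:
            raise SpectraError("no spectra")
        wn = spectra[0].wavenumbers
        for k, s in enumerate(spectra[1:], start=1):
            if s.wavenumbers.size != wn.size or np.max(
                    np.abs(s.wavenumbers - wn)) > GRID_RTOL * abs(wn[0]):
                raise SpectraError(f"record {k} has a mismatched grid")
        A = np.vstack([s.absorbance for s in spectra])
        meta = pd.DataFrame([s.metadata for s in spectra])
        return cls(wn, A, meta)


# ---------------------------------------------------------------------------
# Plain-text tabular I/O
# ---------------------------------------------------------------------------

def write_spectra(spectra: SpectraSet, path: str | Path,
                  metadata_path: str | Path | None = None,
                  float_format: str = "%.17g") -> None:
    """Write a wide TSV (wavenumber + one column per spectrum).

    Metadata goes to ``metadata_path`` (default: ``<path>.meta.csv``).
    """
    path = Path(path)
    df = pd.DataFrame(spectra.absorbance.T, columns=spectra.ids)
    df.insert(0, "wavenumber", spectra.wavenumbers)
    df.to_csv(path, sep="\t", index=False, float_format=float_format)
    if metadata_path is None:
        metadata_path = path.with_suffix(path.suffix + ".meta.csv")
    spectra.metadata.to_csv(metadata_path, index=False)


def read_spectra(path: str | Path,
                 metadata_path: str | Path | None = None) -> SpectraSet:
    """Read the wide TSV format written by :func:`write_spectra`.

    Ascending input grids are accepted and flipped to the descending
    convention (the flip is logged).  A sidecar metadata CSV is merged by
    ``spectrum_id`` when present.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise SpectraError(f"no spectra in {path}") from None
    if df.shape[1] < 2 or df.shape[0] < 2:
        raise SpectraError(f"no spectra in {path}")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(np.nonzero(bad.values)[0][0]) + 2  # header is line 1
            raise SpectraError(
                f"non-numeric cell in column {col!r} at line {line} of {path}")
        df[col] = pd.to_numeric(df[col])
    if df.isna().any().any():
        col = df.columns[df.isna().any().values][0]
        raise SpectraError(f"missing values in record {col!r} of {path}")
    wn = df.iloc[:, 0].to_numpy(float)
    A = df.iloc[:, 1:].to_numpy(float).T
    if wn.size >= 2 and wn[1] > wn[0]:
        logger.info("read_spectra: ascending grid in %s flipped to "
                    "descending convention", path)
        wn = wn[::-1]
        A = A[:, ::-1]
    meta = pd.DataFrame({"spectrum_id": list(df.columns[1:])})
    if metadata_path is None:
        candidate = path.with_suffix(path.suffix + ".meta.csv")
        metadata_path = candidate if candidate.exists() else None
    if metadata_path is not None:
        side = pd.read_csv(metadata_path)
        if "spectrum_id" in side.columns:
            side["spectrum_id"] = side["spectrum_id"].astype(str)
            meta = meta.merge(side, on="spectrum_id", how="left")
    return SpectraSet(wn, A, meta)


# ---------------------------------------------------------------------------
# JCAMP-DX import (reader-only convenience)
# ---------------------------------------------------------------------------

def read_jcamp(path: str | Path) -> Spectrum:
    """Read one spectrum from a single-block JCAMP-DX file.

    Supports the ``XYDATA=(X++(Y..Y))`` record with AFFN (plain decimal)
    values, honouring ``XFACTOR``/``YFACTOR``.  Compressed ordinate forms
    (SQZ/DIF/DUP) are not supported.
    """
    text = Path(path).read_text()
    labels: dict[str, str] = {}
    data_lines: list[str] = []
    in_data = False
    for raw in io.StringIO(text):
        line = raw.strip()
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            if key == "XYDATA":
                in_data = True
                continue
            if key == "END":
                in_data = False
                continue
            in_data = False
            labels[key] = value.strip()
        elif in_data and line:
            data_lines.append(line)
    if not data_lines:
        raise SpectraError(f"no XYDATA block in {path}")
    xfactor = float(labels.get("XFACTOR", "1"))
    yfactor = float(labels.get("YFACTOR", "1"))
    xs: list[float] = []
    ys: list[float] = []
    for line in data_lines:
        vals = [float(v) for v in line.replace(",", " ").split()]
        if len(vals) < 2:
            raise SpectraError(f"short XYDATA line in {path}: {line!r}")
        x0 = vals[0] * xfactor
        yvals = [v * yfactor for v in vals[1:]]
        xs.append(x0)
        ys.extend(yvals)
    # reconstruct the full abscissa from FIRSTX/LASTX/NPOINTS when given
    n = int(labels.get("NPOINTS", len(ys)))
    firstx = float(labels.get("FIRSTX", xs[0]))
    lastx = float(labels.get("LASTX", xs[-1]))
    wn = np.linspace(firstx, lastx, n)
    a = np.asarray(ys[:n], dtype=float)
    if wn[0] < wn[-1]:
        wn = wn[::-1]
        a = a[::-1]
    meta = {"spectrum_id": labels.get("TITLE", Path(path).stem)}
    return Spectrum(wn, a, meta)


def default_grid(high: float = 4000.0, low: float = 500.0,
                 spacing: float = 2.0) -> np.ndarray:
    """Descending wavenumber grid, ``high`` → ``low`` cm^-1 inclusive."""
    n = int(round((high - low) / spacing)) + 1
    return np.linspace(high, low, n)
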