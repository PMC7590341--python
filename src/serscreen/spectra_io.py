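"""Reading, writing, validating and regridding Raman/SERS spectra.

Spectra are plain two-column delimited text (wavenumber in cm^-1,
intensity in arbitrary units).  The handheld instrument this package
targets records 1,024 channels spanning 204-1,986 cm^-1; that axis is
available as :data:`DEFAULT_GRID` and every downstream scoring step
assumes spectra have been resampled onto it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "WavenumberGrid",
    "Spectrum",
    "DEFAULT_GRID",
    "SpectrumFormatError",
    "SpectrumValidationError",
    "CoverageError",
    "read_spectrum",
    "write_spectrum",
    "resample_to_grid",
]


class SpectrumFormatError(ValueError):
    """A spectrum file could not be parsed (bad row, too few columns...)."""


class SpectrumValidationError(ValueError):
    """Parsed numbers violate a spectrum invariant (duplicates, NaN...)."""


class CoverageError(ValueError):
    """Requested grid extends beyond the spectrum's wavenumber support."""


@dataclass(frozen=True)
class WavenumberGrid:
    """Evenly spaced wavenumber axis (cm^-1).

    Parameters
    ----------
    start, stop
        First and last wavenumber in cm^-1; ``start < stop``.
    n_points
        Number of channels (>= 2).
    """

    start: float = 204.0
    stop: float = 1986.0
    n_points: int = 1024

    def __post_init__(self) -> None:
        if not (self.start < self.stop):
            raise ValueError(f"grid start must be < stop, got {self.start} >= {self.stop}")
        if self.n_points < 2:
            raise ValueError(f"grid needs at least 2 points, got {self.n_points}")

    @property
    def points(self) -> np.ndarray:
        """The grid wavenumbers, strictly increasing, evenly spaced."""
        return np.linspace(self.start, self.stop, self.n_points)

    @property
    def spacing(self) -> float:
        return (self.stop - self.start) / (self.n_points - 1)


#: The instrument axis: 1,024 channels over 204-1,986 cm^-1.
DEFAULT_GRID = WavenumberGrid()


@dataclass
class Spectrum:
    """A single sample's spectrum on an increasing wavenumber axis."""

    sample_id: str
    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise SpectrumValidationError("wavenumbers and intensities must be 1-D")
        if len(self.wavenumbers) != len(self.intensities):
            raise SpectrumValidationError(
                f"length mismatch: {len(self.wavenumbers)} wavenumbers vs "
                f"{len(self.intensities)} intensities"
            )
        if len(self.wavenumbers) < 2:
            raise SpectrumValidationError("spectrum needs at least 2 points")
        if not np.all(np.isfinite(self.wavenumbers)) or not np.all(
            np.isfinite(self.intensities)
        ):
            raise SpectrumValidationError("non-finite values in spectrum")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise SpectrumValidationError("wavenumbers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.wavenumbers)


_DELIMITERS = [",", "\t", ";", None]  # None = any whitespace


def _detect_delimiter(line: str) -> str | None:
    for d in [",", "\t", ";"]:
        if d in line:
            return d
    return None


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_spectrum(
    path: str | Path,
    dialect: str | None = "auto",
    sample_id: str | None = None,
) -> Spectrum:
    """Read a two-column delimited text spectrum.

    Lines starting with ``#`` are comments; one optional non-numeric
    header line is tolerated.  The delimiter is auto-detected among
    comma / tab / semicolon / whitespace unless ``dialect`` gives one
    explicitly.  Rows are re-sorted by ascending wavenumber; duplicated
    wavenumbers are rejected.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()

    delim: str | None
    if dialect is None or dialect == "auto":
        delim = "auto"  # decide per first data line
    else:
        delim = dialect

    wn: list[float] = []
    inten: list[float] = []
    header_seen = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        d = _detect_delimiter(line) if delim == "auto" else delim
        toks = [t for t in (line.split(d) if d else line.split()) if t.strip()]
        if len(toks) < 2:
            raise SpectrumFormatError(
                f"{path}:{lineno}: expected at least 2 columns, got {len(toks)}"
            )
        if not (_is_number(toks[0]) and _is_number(toks[1])):
            if not header_seen and not wn:
                header_seen = True  # single header line allowed
                continue
            raise SpectrumFormatError(f"{path}:{lineno}: unparseable row {line!r}")
        wn.append(float(toks[0]))
        inten.append(float(toks[1]))

    if len(wn) < 2:
        raise SpectrumFormatError(f"{path}: fewer than 2 data points")

    w = np.array(wn)
    y = np.array(inten)
    if not np.all(np.isfinite(w)) or not np.all(np.isfinite(y)):
        raise SpectrumValidationError(f"{path}: non-finite values")
    order = np.argsort(w, kind="stable")
    w, y = w[order], y[order]
    if np.any(np.diff(w) == 0):
        dup = w[:-1][np.diff(w) == 0][0]
        raise SpectrumValidationError(f"{path}: duplicated wavenumber {dup}")

    sid = sample_id if sample_id is not None else path.stem
    return Spectrum(sample_id=sid, wavenumbers=w, intensities=y, meta={"source": str(path)})


def write_spectrum(s: Spectrum, path: str | Path, delimiter: str = ",") -> None:
    """Write a spectrum as two-column delimited text (full double precision)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# sample_id: {s.sample_id}\n")
        fh.write(f"# columns: wavenumber_cm-1{delimiter}intensity_au\n")
        for w, y in zip(s.wavenumbers, s.intensities):
            fh.write(f"{w:.17g}{delimiter}{y:.17g}\n")


def resample_to_grid(
    s: Spectrum, g: WavenumberGrid = DEFAULT_GRID, edge_hold: bool = False
) -> Spectrum:
    """Linearly interpolate a spectrum onto a fixed wavenumber grid.

    Values at input knots are preserved wherever a knot coincides with a
    grid point, and a spectrum already on the grid is returned unchanged
    (idempotence).  Grid points outside the spectrum's support raise
    :class:`CoverageError` unless ``edge_hold`` extends the first/last
    intensity outward.
    """
    pts = g.points
    if len(s) == g.n_points and np.allclose(s.wavenumbers, pts, rtol=0, atol=1e-9):
        return Spectrum(s.sample_id, pts, s.intensities.copy(), dict(s.meta))
    if not edge_hold and (pts[0] < s.wavenumbers[0] or pts[-1] > s.wavenumbers[-1]):
        raise CoverageError(
            f"grid [{pts[0]}, {pts[-1]}] exceeds spectrum support "
            f"[{s.wavenumbers[0]}, {s.wavenumbers[-1]}]; pass edge_hold=True to clamp"
        )
    y = np.interp(pts, s.wavenumbers, s.intensities)
    meta = dict(s.meta)
    meta["resampled"] = True
    return Spectrum(s.sample_id, pts, y, meta)
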