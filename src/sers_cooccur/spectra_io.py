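"""Spectral matrix I/O and wavenumber-axis calibration.

The on-disk format is a plain CSV matrix: a header row of wavenumber
centers preceded by a ``label`` column, then one row per spectrum
(``label,v1,...,vp``).  The format is deliberately diffable; vendor binary
containers are out of scope.

Axis calibration follows common Raman practice: measured peak positions of
a toluene-acetonitrile (1:1) standard are matched to their nominal shifts
and a least-squares affine map (gain + offset) is fitted and applied to the
whole axis.  The affine model is the minimal one correcting both grating
offset and dispersion error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources as _importlib_resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    AxisError,
    CalibrationError,
    LabelError,
    SpectraFormatError,
)

__all__ = [
    "WavenumberAxis",
    "Spectrum",
    "SpectraSet",
    "read_spectra",
    "write_spectra",
    "calibrate_axis",
    "load_calibration_standard",
]

#: admissible wavenumber range for any axis center, cm^-1
AXIS_RANGE = (200.0, 2000.0)
#: maximum allowed ratio between largest and smallest channel spacing
MAX_SPACING_RATIO = 1.05


@dataclass(frozen=True)
class WavenumberAxis:
    """Shared wavenumber axis, strictly increasing, approximately uniform.

    Parameters
    ----------
    centers
        Channel center positions in cm^-1.  Must be strictly increasing,
        lie within :data:`AXIS_RANGE` and have a max/min spacing ratio of
        at most :data:`MAX_SPACING_RATIO`.
    """

    centers: np.ndarray

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float)
        object.__setattr__(self, "centers", centers)
        if centers.ndim != 1 or centers.size < 2:
            raise AxisError("axis needs at least two centers")
        if not np.all(np.isfinite(centers)):
            raise AxisError("non-finite wavenumber centers")
        d = np.diff(centers)
        if np.any(d <= 0):
            raise AxisError("wavenumber axis must be strictly increasing")
        if d.max() / d.min() > MAX_SPACING_RATIO:
            raise AxisError(
                f"axis spacing not approximately uniform "
                f"(ratio {d.max() / d.min():.3f} > {MAX_SPACING_RATIO})"
            )
        lo, hi = AXIS_RANGE
        if centers[0] < lo or centers[-1] > hi:
            raise AxisError(f"axis centers must lie within [{lo}, {hi}] cm^-1")

    def __len__(self) -> int:
        return self.centers.size

    @property
    def step(self) -> float:
        """Mean channel spacing in cm^-1."""
        return float(np.mean(np.diff(self.centers)))


@dataclass
class Spectrum:
    """A single acquisition: intensities on a shared axis plus metadata."""

    axis: WavenumberAxis
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.axis),):
            raise SpectraFormatError(
                f"intensity vector of length {self.intensities.size} does not "
                f"match axis of length {len(self.axis)}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise SpectraFormatError("non-finite intensities")


@dataclass
class SpectraSet:
    """A labelled spectral matrix: rows are spectra, columns are channels."""

    axis: WavenumberAxis
    matrix: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.matrix.ndim != 2:
            raise SpectraFormatError("spectral matrix must be two-dimensional")
        n, p = self.matrix.shape
        if n < 1:
            raise SpectraFormatError("spectral matrix needs at least one row")
        if p != len(self.axis):
            raise SpectraFormatError(
                f"matrix has {p} columns but axis has {len(self.axis)} centers"
            )
        if self.labels.shape != (n,):
            raise LabelError("one label per spectrum is required")
        for lab in self.labels:
            if lab is None or str(lab) == "" or (isinstance(lab, float) and np.isnan(lab)):
                raise LabelError("empty or missing condition label")
        if not np.all(np.isfinite(self.matrix)):
            raise SpectraFormatError("non-finite intensities in matrix")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]

    def spectrum(self, i: int) -> Spectrum:
        """Row ``i`` as a :class:`Spectrum` (label preserved in ``meta``)."""
        return Spectrum(self.axis, self.matrix[i].copy(), {"condition": self.labels[i]})

    def subset(self, mask: np.ndarray) -> "SpectraSet":
        """Row subset by boolean mask or integer index array."""
        return SpectraSet(self.axis, self.matrix[mask], self.labels[mask])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_LABEL_COLUMN = "label"


def read_spectra(path: str | Path, dialect: str = "csv") -> SpectraSet:
    """Read a labelled spectral matrix from a delimited text file.

    The first header cell must be ``label``; the remaining header cells are
    the wavenumber centers.  Each subsequent row is ``label,v1,...,vp``.
    Row order is preserved.
    """
    if dialect != "csv":
        raise SpectraFormatError(f"unknown dialect {dialect!r}")
    path = Path(path)
    try:
        frame = pd.read_csv(path, header=0, dtype=str)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise SpectraFormatError(f"cannot parse {path}: {exc}") from exc
    if frame.shape[1] < 3 or frame.columns[0] != _LABEL_COLUMN:
        raise SpectraFormatError(
            f"{path}: expected header 'label,<wavenumbers...>'"
        )
    try:
        centers = np.array([float(c) for c in frame.columns[1:]])
    except ValueError as exc:
        raise SpectraFormatError(f"{path}: non-numeric wavenumber header") from exc
    axis = WavenumberAxis(centers)
    labels = frame.iloc[:, 0].to_numpy(dtype=object)
    if any(lab is None or (isinstance(lab, float) and np.isnan(lab)) for lab in labels):
        raise LabelError(f"{path}: missing labels")
    try:
        matrix = frame.iloc[:, 1:].to_numpy(dtype=float)
    except ValueError as exc:
        raise SpectraFormatError(f"{path}: non-numeric intensity cell") from exc
    if np.isnan(matrix).any():
        raise SpectraFormatError(f"{path}: missing intensity values (ragged rows?)")
    return SpectraSet(axis, matrix, labels)


def write_spectra(sset: SpectraSet, path: str | Path) -> Path:
    """Write a :class:`SpectraSet` as CSV, readable by :func:`read_spectra`.

    Output is deterministic byte-for-byte for a fixed input.  Values are
    written with 17 significant digits so the read/write round trip is
    lossless at float64 precision.
    """
    path = Path(path)
    header = [_LABEL_COLUMN] + [repr(float(c)) for c in sset.axis.centers]
    lines = [",".join(header)]
    for lab, row in zip(sset.labels, sset.matrix):
        lines.append(str(lab) + "," + ",".join(repr(float(v)) for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

#: fitted gain must stay within this distance of 1 to be plausible
MAX_GAIN_DEVIATION = 0.1


def calibrate_axis(
    measured_peaks: np.ndarray,
    reference_peaks: np.ndarray,
    axis: WavenumberAxis,
) -> WavenumberAxis:
    """Affine frequency calibration against a peak standard.

    Fits ``reference = a * measured + b`` by least squares over matched
    peak pairs and returns the axis mapped through the fitted transform.

    Raises
    ------
    CalibrationError
        With fewer than two peak pairs, mismatched pair counts, unsorted
        pairs, or a fitted gain further than 10% from unity.
    """
    measured = np.asarray(measured_peaks, dtype=float)
    reference = np.asarray(reference_peaks, dtype=float)
    if measured.ndim != 1 or measured.shape != reference.shape:
        raise CalibrationError("measured and reference peak lists must match one-to-one")
    if measured.size < 2:
        raise CalibrationError("at least two matched peak pairs are required")
    if np.any(np.diff(measured) <= 0) or np.any(np.diff(reference) <= 0):
        raise CalibrationError("peak pairs must be sorted and strictly increasing")
    a, b = np.polyfit(measured, reference, 1)
    if abs(a - 1.0) > MAX_GAIN_DEVIATION:
        raise CalibrationError(
            f"implausible calibration gain a={a:.4f} (|a-1| > {MAX_GAIN_DEVIATION})"
        )
    return WavenumberAxis(a * axis.centers + b)


def load_calibration_standard() -> pd.DataFrame:
    """Nominal Raman shifts of the packaged toluene-acetonitrile standard.

    Shipped as an editable CSV resource (columns ``shift_cm1``, ``species``),
    not hard-coded truth: replace the file to use a different standard.
    """
    ref = _importlib_resources.files("sers_cooccur.resources").joinpath(
        "toluene_acetonitrile_peaks.csv"
    )
    with _importlib_resources.as_file(ref) as fp:
        return pd.read_csv(fp)
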