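"""Moving-window band-occurrence statistics.

A band is "present" in a spectrum when the trapezoidal integral over a
window of +/- ``half_width`` cm^-1 around a grid center exceeds the mean
integral of a signal-free reference set at the same center by ``k_sigma``
reference standard deviations.  Scanning the grid (default 400 to 1800
cm^-1 in 5 cm^-1 steps) over every spectrum of a dataset yields the
relative band-occurrence histogram: the fraction of spectra of a condition
in which each spectral feature is present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CountError, CoverageError
from .spectra_io import SpectraSet, Spectrum

__all__ = [
    "OccurrenceGrid",
    "ReferenceIntegrals",
    "OccurrenceHistogram",
    "window_integral",
    "window_integrals_set",
    "build_reference",
    "detect_bands",
    "occurrence_histogram",
]


@dataclass(frozen=True)
class OccurrenceGrid:
    """Equally spaced window centers with a common half-width.

    The default grid runs from 400 to 1800 cm^-1 in steps of 5 cm^-1
    (281 centers) with half-width 10 cm^-1; windows are closed intervals.
    """

    centers: np.ndarray = field(
        default_factory=lambda: np.arange(400.0, 1800.0 + 2.5, 5.0)
    )
    half_width: float = 10.0

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float)
        object.__setattr__(self, "centers", centers)
        if centers.ndim != 1 or centers.size < 1:
            raise CountError("grid needs at least one center")
        if self.half_width <= 0:
            raise CoverageError("half_width must be positive")
        if centers.size > 1:
            d = np.diff(centers)
            if np.any(d <= 0) or not np.allclose(d, d[0]):
                raise CoverageError("grid centers must increase with constant step")

    @property
    def step(self) -> float:
        c = self.centers
        return float(c[1] - c[0]) if c.size > 1 else 0.0

    def __len__(self) -> int:
        return self.centers.size


@dataclass
class ReferenceIntegrals:
    """Per-center mean and sd of window integrals over a reference set."""

    grid: OccurrenceGrid
    mean_integral: np.ndarray
    sd_integral: np.ndarray
    n_reference: int

    def __post_init__(self) -> None:
        if (
            self.mean_integral.shape != (len(self.grid),)
            or self.sd_integral.shape != (len(self.grid),)
        ):
            raise CoverageError("reference integral vectors must match the grid")
        if np.any(self.sd_integral < 0):
            raise CoverageError("negative reference sd")


@dataclass
class OccurrenceHistogram:
    """Counts and relative frequency of band detection per grid center."""

    grid: OccurrenceGrid
    counts: np.ndarray
    n_spectra: int

    @property
    def relative(self) -> np.ndarray:
        return self.counts / self.n_spectra


def _window_slice(centers: np.ndarray, center: float, half_width: float) -> slice:
    lo = np.searchsorted(centers, center - half_width, side="left")
    hi = np.searchsorted(centers, center + half_width, side="right")
    if hi <= lo:
        raise CoverageError(
            f"no channel inside [{center - half_width}, {center + half_width}] cm^-1"
        )
    return slice(lo, hi)


def window_integral(spectrum: Spectrum, center: float, half_width: float) -> float:
    """Trapezoidal integral over channels inside the closed window.

    The integral is taken on the physical wavenumber axis, so it is exact
    for linear segments and aware of the channel spacing.  Edge centers
    whose windows extend past the axis use the covered part of the window.
    """
    sl = _window_slice(spectrum.axis.centers, center, half_width)
    x = spectrum.axis.centers[sl]
    y = spectrum.intensities[sl]
    if x.size == 1:
        return 0.0
    return float(np.trapezoid(y, x))


def window_integrals_set(sset: SpectraSet, grid: OccurrenceGrid) -> np.ndarray:
    """(n, n_centers) matrix of window integrals for a whole set."""
    out = np.empty((sset.n, len(grid)))
    centers = sset.axis.centers
    for c, center in enumerate(grid.centers):
        sl = _window_slice(centers, center, grid.half_width)
        x = centers[sl]
        if x.size == 1:
            out[:, c] = 0.0
        else:
            out[:, c] = np.trapezoid(sset.matrix[:, sl], x, axis=1)
    return out


def build_reference(reference_set: SpectraSet, grid: OccurrenceGrid) -> ReferenceIntegrals:
    """Mean and population sd of window integrals over the reference set.

    The reference set must have been preprocessed with the same chain as
    the analysis spectra (minus the detectable-signal filter, which would
    reject signal-free spectra by construction).
    """
    integrals = window_integrals_set(reference_set, grid)
    return ReferenceIntegrals(
        grid,
        integrals.mean(axis=0),
        integrals.std(axis=0, ddof=0),
        reference_set.n,
    )


def detect_bands(
    spectrum: Spectrum,
    grid: OccurrenceGrid,
    ref: ReferenceIntegrals,
    k_sigma: float = 3.0,
) -> np.ndarray:
    """0/1 vector over grid centers; 1 where the window integral strictly
    exceeds the reference mean plus ``k_sigma`` reference sd."""
    if k_sigma <= 0:
        raise CountError("k_sigma must be positive")
    integrals = np.array(
        [window_integral(spectrum, c, grid.half_width) for c in grid.centers]
    )
    return (integrals > ref.mean_integral + k_sigma * ref.sd_integral).astype(np.int8)


def occurrence_histogram(
    sset: SpectraSet,
    grid: OccurrenceGrid,
    ref: ReferenceIntegrals,
    k_sigma: float = 3.0,
) -> OccurrenceHistogram:
    """Relative band occurrence of a dataset against a reference."""
    if sset.n < 1:
        raise CountError("empty spectra set")
    if k_sigma <= 0:
        raise CountError("k_sigma must be positive")
    integrals = window_integrals_set(sset, grid)
    detected = integrals > (ref.mean_integral + k_sigma * ref.sd_integral)[None, :]
    return OccurrenceHistogram(grid, detected.sum(axis=0).astype(int), sset.n)
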