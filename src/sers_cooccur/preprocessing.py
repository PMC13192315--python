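"""Preprocessing chain for single-acquisition SERS spectra.

The chain runs in a fixed order: cosmic-ray spike removal, asymmetric
least-squares (AsLS) baseline estimation, baseline subtraction with vector
normalization, a detectable-signal filter, and cropping to the analysis
range (400-1800 cm^-1 by default).

AsLS estimates the baseline z as the minimizer of

    sum_i w_i (y_i - z_i)^2 + lambda * sum_i (Delta^2 z_i)^2,

with asymmetric weights w_i = p where y_i > z_i and 1 - p otherwise,
iterated to a fixed point of the weight assignment.  Positive peaks are
thereby largely ignored while the smooth background is tracked.  The system
matrix (W + lambda D'D) is symmetric pentadiagonal and solved in banded
form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solveh_banded
from scipy import sparse

from .errors import DegenerateSpectrumError, RangeError, SizeError
from .spectra_io import SpectraSet, Spectrum, WavenumberAxis

__all__ = [
    "PreprocessConfig",
    "remove_spikes",
    "asls_baseline",
    "subtract_and_normalize",
    "estimate_noise_sd",
    "has_detectable_signal",
    "crop",
    "preprocess_spectrum",
    "preprocess_set",
]


@dataclass
class PreprocessConfig:
    """Tunable parameters of the preprocessing chain.

    ``spike_z_threshold`` is the modified z-score cut on first differences;
    ``asls_lambda`` and ``asls_p`` are the AsLS smoothness and asymmetry
    parameters (defaults follow the usual recommended ranges for Raman
    baselines); ``signal_snr_min`` is the minimal peak signal-to-noise
    ratio a spectrum must reach to count as carrying detectable signal.
    """

    spike_z_threshold: float = 8.0
    spike_window: int = 5
    asls_lambda: float = 1e5
    asls_p: float = 0.01
    asls_max_iter: int = 10
    asls_tol: float = 1e-6
    signal_snr_min: float = 5.0
    crop_min: float = 400.0
    crop_max: float = 1800.0

    def __post_init__(self) -> None:
        if min(
            self.spike_z_threshold,
            self.spike_window,
            self.asls_lambda,
            self.asls_max_iter,
            self.asls_tol,
            self.signal_snr_min,
        ) <= 0:
            raise ValueError("all preprocessing parameters must be positive")
        if not 0.0 < self.asls_p < 1.0:
            raise ValueError("asls_p must lie in (0, 1)")
        if self.crop_min >= self.crop_max:
            raise ValueError("crop_min must be below crop_max")


# ---------------------------------------------------------------------------
# spike removal
# ---------------------------------------------------------------------------


def _modified_zscores(d: np.ndarray) -> np.ndarray:
    med = np.median(d)
    mad = np.median(np.abs(d - med))
    if mad == 0.0:
        # degenerate spread: any deviating difference is an outlier
        return np.where(d == med, 0.0, np.inf) * np.sign(d - med + 0.0)
    return 0.6745 * (d - med) / mad


def remove_spikes(spectrum: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Replace cosmic-ray spikes by the median of unflagged neighbors.

    A channel is flagged when the modified z-score of the first difference
    into it exceeds ``spike_z_threshold`` (upward step) or the difference
    out of it falls below the negative threshold (downward step); a
    single-channel positive spike is flagged twice by this rule while its
    neighbors stay untouched.  Flagged channels are replaced by the median
    of non-flagged channels within ``spike_window`` channels.  The
    operation is idempotent on its own output.
    """
    cfg = cfg or PreprocessConfig()
    y = spectrum.intensities
    n = y.size
    if n <= cfg.spike_window:
        raise SizeError(f"spectrum of length {n} shorter than spike window")
    z = _modified_zscores(np.diff(y))
    flagged = np.zeros(n, dtype=bool)
    flagged[1:][z > cfg.spike_z_threshold] = True   # upward step into channel k+1
    flagged[:-1][z < -cfg.spike_z_threshold] = True  # downward step out of channel k
    if not flagged.any():
        return Spectrum(spectrum.axis, y.copy(), dict(spectrum.meta))
    cleaned = y.copy()
    w = cfg.spike_window
    for i in np.flatnonzero(flagged):
        lo, hi = max(0, i - w), min(n, i + w + 1)
        neighbors = y[lo:hi][~flagged[lo:hi]]
        if neighbors.size == 0:  # whole window flagged: widen until data found
            lo, hi = 0, n
            neighbors = y[~flagged]
        cleaned[i] = np.median(neighbors)
    return Spectrum(spectrum.axis, cleaned, dict(spectrum.meta))


# ---------------------------------------------------------------------------
# AsLS baseline
# ---------------------------------------------------------------------------


def _second_difference_penalty(n: int, lam: float) -> np.ndarray:
    """Upper-banded form of lambda * D'D for the second-difference matrix D."""
    d2 = sparse.diags_array([1.0, -2.0, 1.0], offsets=[0, 1, 2], shape=(n - 2, n))
    m = (lam * (d2.T @ d2)).tocsc()
    ab = np.zeros((3, n))
    ab[0, 2:] = m.diagonal(2)
    ab[1, 1:] = m.diagonal(1)
    ab[2, :] = m.diagonal(0)
    return ab


def asls_baseline(
    intensities: np.ndarray,
    lam: float = 1e5,
    p: float = 0.01,
    max_iter: int = 10,
    tol: float = 1e-6,
) -> np.ndarray:
    """Asymmetric least-squares baseline of a single intensity vector.

    Iterates the weighted Whittaker smoother until the asymmetric weight
    assignment is stable, the baseline change drops below ``tol`` (relative
    L2), or ``max_iter`` passes have run.
    """
    y = np.asarray(intensities, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise SizeError("AsLS needs a 1-D vector of length >= 3")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite input to asls_baseline")
    if lam <= 0 or not 0.0 < p < 1.0:
        raise ValueError("require lambda > 0 and 0 < p < 1")
    n = y.size
    penalty = _second_difference_penalty(n, lam)
    w = np.ones(n)
    z = y
    for _ in range(max_iter):
        ab = penalty.copy()
        ab[2, :] += w
        z_new = solveh_banded(ab, w * y)
        w_new = np.where(y > z_new, p, 1.0 - p)
        converged_w = np.array_equal(w_new, w)
        dz = np.linalg.norm(z_new - z) / max(np.linalg.norm(z_new), 1e-300)
        z, w = z_new, w_new
        if converged_w or dz < tol:
            break
    return z


def subtract_and_normalize(spectrum: Spectrum, baseline: np.ndarray) -> Spectrum:
    """Baseline-subtract and scale to unit Euclidean norm."""
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape != spectrum.intensities.shape:
        raise SizeError("baseline length does not match spectrum")
    corrected = spectrum.intensities - baseline
    norm = np.linalg.norm(corrected)
    if norm == 0.0:
        raise DegenerateSpectrumError("all-zero spectrum after baseline subtraction")
    return Spectrum(spectrum.axis, corrected / norm, dict(spectrum.meta))


# ---------------------------------------------------------------------------
# detectable-signal filter and cropping
# ---------------------------------------------------------------------------


def estimate_noise_sd(intensities: np.ndarray) -> float:
    """Robust noise estimate from first differences.

    For white noise of standard deviation sigma the first differences have
    standard deviation sigma * sqrt(2); the median absolute difference,
    scaled by 1.4826 and divided by sqrt(2), is therefore a robust
    estimator of sigma that is insensitive to sparse smooth bands.
    """
    d = np.abs(np.diff(np.asarray(intensities, dtype=float)))
    return float(1.4826 * np.median(d) / np.sqrt(2.0))


def has_detectable_signal(
    spectrum: Spectrum,
    noise_sd_estimate: float | None = None,
    cfg: PreprocessConfig | None = None,
) -> bool:
    """True when the maximum intensity exceeds ``signal_snr_min`` times noise.

    Intended for baseline-corrected spectra.  When no noise estimate is
    supplied it is derived from the spectrum itself via
    :func:`estimate_noise_sd`, which makes the decision scale-invariant and
    hence equally valid before or after vector normalization.
    """
    cfg = cfg or PreprocessConfig()
    if noise_sd_estimate is None:
        noise_sd_estimate = estimate_noise_sd(spectrum.intensities)
    if noise_sd_estimate <= 0:
        return bool(np.max(spectrum.intensities) > 0)
    return bool(np.max(spectrum.intensities) > cfg.signal_snr_min * noise_sd_estimate)


def crop(spectrum: Spectrum, lo: float, hi: float) -> Spectrum:
    """Retain channels whose centers lie in the closed interval [lo, hi]."""
    if lo >= hi:
        raise RangeError("crop interval empty: lo >= hi")
    centers = spectrum.axis.centers
    mask = (centers >= lo) & (centers <= hi)
    if not mask.any():
        raise RangeError(f"no channels in [{lo}, {hi}] cm^-1")
    return Spectrum(
        WavenumberAxis(centers[mask]), spectrum.intensities[mask], dict(spectrum.meta)
    )


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------


def preprocess_spectrum(
    spectrum: Spectrum,
    cfg: PreprocessConfig | None = None,
    apply_signal_filter: bool = True,
) -> Spectrum | None:
    """Run the full chain on one spectrum; ``None`` when filtered out.

    Order: spike removal -> AsLS baseline -> subtract + vector-normalize ->
    detectable-signal filter -> crop.  The signal filter can be disabled,
    as it must be when preprocessing the signal-free reference set.
    """
    cfg = cfg or PreprocessConfig()
    despiked = remove_spikes(spectrum, cfg)
    baseline = asls_baseline(
        despiked.intensities, cfg.asls_lambda, cfg.asls_p, cfg.asls_max_iter, cfg.asls_tol
    )
    normalized = subtract_and_normalize(despiked, baseline)
    if apply_signal_filter and not has_detectable_signal(normalized, None, cfg):
        return None
    return crop(normalized, cfg.crop_min, cfg.crop_max)


def preprocess_set(
    sset: SpectraSet,
    cfg: PreprocessConfig | None = None,
    apply_signal_filter: bool = True,
) -> tuple[SpectraSet, list]:
    """Preprocess every spectrum of a set, dropping filtered-out rows.

    Returns the preprocessed set and a rejection log of ``(row_index,
    reason)`` tuples.  Raises :class:`DegenerateSpectrumError` only if a
    spectrum cannot be normalized; spectra without detectable signal are
    logged and dropped, not errors.
    """
    cfg = cfg or PreprocessConfig()
    kept_rows, kept_labels, rejections = [], [], []
    out_axis = None
    for i in range(sset.n):
        try:
            result = preprocess_spectrum(sset.spectrum(i), cfg, apply_signal_filter)
        except DegenerateSpectrumError:
            rejections.append((i, "degenerate"))
            continue
        if result is None:
            rejections.append((i, "no detectable signal"))
            continue
        out_axis = result.axis
        kept_rows.append(result.intensities)
        kept_labels.append(sset.labels[i])
    if not kept_rows:
        raise DegenerateSpectrumError("no spectrum survived preprocessing")
    return (
        SpectraSet(out_axis, np.vstack(kept_rows), np.array(kept_labels, dtype=object)),
        rejections,
    )
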