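"""Synthetic SERS-like spectrum generator.

Real endolysosomal SERS spectra fluctuate strongly from acquisition to
acquisition: a band is either present or absent in a given spectrum,
depending on which molecules sit in the nanoparticle's near field at that
moment.  The generator reproduces exactly the statistical structure the
downstream analysis relies on:

* Lorentzian bands at literature positions, with class-dependent Bernoulli
  occurrence (a band is present in a spectrum with a probability that
  differs between experimental conditions),
* planted co-occurrence between designated band pairs, modelled through a
  Gaussian copula so marginal occurrence probabilities stay exact while the
  pairwise dependence is tunable,
* a smooth polynomial baseline, additive Gaussian noise, and sparse
  single-channel positive spikes (cosmic rays) at a Poisson rate,
* lognormal amplitude variation with a configurable coefficient of
  variation.

Signal-free reference spectra (baseline + noise only) emulate acquisitions
away from any probe, as required by the band-occurrence thresholding.

The generator makes no attempt at physical SERS enhancement modelling; it
is a statistical stand-in whose planted truth is known, so recovery can be
quantified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtri

from .errors import ConfigError, CountError
from .spectra_io import SpectraSet, WavenumberAxis

__all__ = [
    "BandSpec",
    "CooccurrencePair",
    "GeneratorConfig",
    "default_band_table",
    "default_config",
    "generate_dataset",
    "generate_signal_free",
    "REFERENCE_LABEL",
]

REFERENCE_LABEL = "reference"

#: default condition labels of the two-group comparison
CONTROL = "control"
TREATED = "saclac_10um"


@dataclass(frozen=True)
class BandSpec:
    """One vibrational band and its per-condition occurrence statistics.

    ``mean_amplitude`` is the mean peak height in detector counts;
    ``occurrence_prob`` maps each condition label to the probability that
    the band appears in a single spectrum of that condition.
    """

    center: float
    fwhm: float
    mean_amplitude: float
    occurrence_prob: dict
    class_tag: str = "other"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ConfigError(f"band at {self.center}: fwhm must be positive")
        if self.mean_amplitude < 0:
            raise ConfigError(f"band at {self.center}: negative amplitude")
        for cls, prob in self.occurrence_prob.items():
            if not 0.0 <= prob <= 1.0:
                raise ConfigError(
                    f"band at {self.center}: occurrence probability {prob} "
                    f"for {cls!r} outside [0, 1]"
                )
        if self.class_tag not in {"protein", "lipid", "dna", "other"}:
            raise ConfigError(f"unknown class tag {self.class_tag!r}")


@dataclass(frozen=True)
class CooccurrencePair:
    """Planted latent correlation between the occurrences of two bands."""

    band_i: int
    band_j: int
    rho: float

    def __post_init__(self) -> None:
        if self.band_i == self.band_j:
            raise ConfigError("a co-occurrence pair needs two distinct bands")
        if not -1.0 < self.rho < 1.0:
            raise ConfigError(f"rho={self.rho} outside (-1, 1)")


@dataclass
class GeneratorConfig:
    """Full description of one synthetic acquisition campaign.

    ``baseline_coeffs`` are polynomial coefficients in ascending order,
    evaluated on the normalized coordinate ``u = (x - axis_min) /
    (axis_max - axis_min)`` so their magnitudes stay interpretable as
    counts.  ``spike_rate`` is the expected number of cosmic-ray spikes per
    spectrum; each spike adds ``spike_amplitude`` counts to one channel.
    """

    axis_min: float = 400.0
    axis_max: float = 1800.0
    axis_step: float = 2.0
    baseline_coeffs: tuple = (120.0, -40.0, 25.0)
    noise_sd: float = 1.0
    spike_rate: float = 0.05
    spike_amplitude: float = 200.0
    bands: list = field(default_factory=list)
    pairs: list = field(default_factory=list)
    n_per_class: dict = field(default_factory=dict)
    amplitude_cv: float = 0.3
    lineshape: str = "lorentzian"

    def __post_init__(self) -> None:
        if self.axis_min >= self.axis_max:
            raise ConfigError("axis_min must be below axis_max")
        if self.axis_step <= 0:
            raise ConfigError("axis_step must be positive")
        if self.noise_sd < 0 or self.spike_rate < 0 or self.amplitude_cv < 0:
            raise ConfigError("noise_sd, spike_rate and amplitude_cv must be >= 0")
        if self.lineshape not in {"lorentzian", "gaussian"}:
            raise ConfigError(f"unknown lineshape {self.lineshape!r}")
        for count in self.n_per_class.values():
            if count < 0:
                raise ConfigError("per-class counts must be >= 0")
        nb = len(self.bands)
        for pair in self.pairs:
            if not (0 <= pair.band_i < nb and 0 <= pair.band_j < nb):
                raise ConfigError("co-occurrence pair refers to a missing band")
        for band in self.bands:
            if not self.axis_min <= band.center <= self.axis_max:
                raise ConfigError(
                    f"band center {band.center} outside axis range "
                    f"[{self.axis_min}, {self.axis_max}]"
                )

    def axis(self) -> WavenumberAxis:
        centers = np.arange(self.axis_min, self.axis_max + 0.5 * self.axis_step, self.axis_step)
        return WavenumberAxis(centers)

    def baseline(self) -> np.ndarray:
        x = self.axis().centers
        u = (x - self.axis_min) / (self.axis_max - self.axis_min)
        return np.polynomial.polynomial.polyval(u, np.asarray(self.baseline_coeffs, float))


def _band_profiles(config: GeneratorConfig) -> np.ndarray:
    """(n_bands, p) matrix of unit-height line profiles."""
    x = config.axis().centers
    profiles = np.empty((len(config.bands), x.size))
    for b, band in enumerate(config.bands):
        if config.lineshape == "lorentzian":
            gamma = band.fwhm / 2.0
            profiles[b] = gamma**2 / ((x - band.center) ** 2 + gamma**2)
        else:
            profiles[b] = np.exp(-4.0 * np.log(2.0) * (x - band.center) ** 2 / band.fwhm**2)
    return profiles


def _copula_cholesky(config: GeneratorConfig) -> np.ndarray:
    nb = len(config.bands)
    corr = np.eye(nb)
    for pair in config.pairs:
        corr[pair.band_i, pair.band_j] = pair.rho
        corr[pair.band_j, pair.band_i] = pair.rho
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ConfigError("pair correlation matrix is not positive definite") from exc


def generate_dataset(
    config: GeneratorConfig, seed: int
) -> tuple[SpectraSet, np.ndarray]:
    """Generate a labelled dataset plus its band-occurrence ground truth.

    Each spectrum is ``baseline + sum_b occ_b * amp_b * profile_b + noise +
    spikes``.  Occurrence indicators are drawn per condition from a Gaussian
    copula: latent correlated standard normals thresholded at the normal
    quantile of each band's occurrence probability, which leaves marginals
    exact while planting the configured pairwise dependence.  Amplitudes
    are lognormal with mean ``mean_amplitude`` and coefficient of variation
    ``amplitude_cv`` (degenerate at the mean when the cv is zero).

    Returns the dataset and an ``(n, n_bands)`` 0/1 truth matrix whose rows
    align with the dataset rows.  Identical ``(config, seed)`` pairs yield
    bit-identical output.
    """
    if not config.n_per_class:
        raise ConfigError("n_per_class is empty")
    if not config.bands:
        raise ConfigError("no bands configured")
    rng = np.random.default_rng(seed)
    axis = config.axis()
    p = len(axis)
    nb = len(config.bands)
    profiles = _band_profiles(config)
    baseline = config.baseline()
    chol = _copula_cholesky(config)

    missing = [
        (band.center, cls)
        for band in config.bands
        for cls in config.n_per_class
        if cls not in band.occurrence_prob
    ]
    if missing:
        raise ConfigError(f"bands lack occurrence probabilities for: {missing}")

    blocks, label_blocks, truth_blocks = [], [], []
    for cls, n_c in config.n_per_class.items():
        if n_c == 0:
            continue
        z = rng.standard_normal((n_c, nb)) @ chol.T
        thresholds = ndtri(
            np.clip([band.occurrence_prob[cls] for band in config.bands], 0.0, 1.0)
        )
        occ = (z < thresholds[None, :]).astype(float)

        if config.amplitude_cv > 0:
            sigma2 = np.log1p(config.amplitude_cv**2)
            mu = np.log([band.mean_amplitude for band in config.bands]) - sigma2 / 2.0
            amps = np.exp(rng.normal(mu[None, :], np.sqrt(sigma2), size=(n_c, nb)))
        else:
            amps = np.broadcast_to(
                np.array([band.mean_amplitude for band in config.bands]), (n_c, nb)
            ).copy()

        spectra = baseline[None, :] + (occ * amps) @ profiles
        if config.noise_sd > 0:
            spectra = spectra + rng.normal(0.0, config.noise_sd, size=(n_c, p))
        if config.spike_rate > 0:
            counts = rng.poisson(config.spike_rate, size=n_c)
            for i in np.flatnonzero(counts):
                channels = rng.integers(0, p, size=counts[i])
                np.add.at(spectra[i], channels, config.spike_amplitude)
        blocks.append(spectra)
        label_blocks.append(np.full(n_c, cls, dtype=object))
        truth_blocks.append(occ.astype(np.int8))

    if not blocks:
        raise ConfigError("all per-class counts are zero")
    sset = SpectraSet(axis, np.vstack(blocks), np.concatenate(label_blocks))
    return sset, np.vstack(truth_blocks)


def generate_signal_free(config: GeneratorConfig, n: int, seed: int) -> SpectraSet:
    """Signal-free reference spectra: baseline + noise, no bands, no spikes."""
    if n < 1:
        raise CountError("at least one reference spectrum is required")
    rng = np.random.default_rng(seed)
    axis = config.axis()
    baseline = config.baseline()
    matrix = np.broadcast_to(baseline, (n, len(axis))).copy()
    if config.noise_sd > 0:
        matrix = matrix + rng.normal(0.0, config.noise_sd, size=matrix.shape)
    return SpectraSet(axis, matrix, np.full(n, REFERENCE_LABEL, dtype=object))


def default_band_table() -> list[BandSpec]:
    """Bands at literature positions for endolysosomal cell spectra.

    Positions are Raman shifts reported for cellular SERS fingerprints:
    phenylalanine ring modes (1006, 1028), amide I/II/III backbone modes
    (1704, 1574, 1276, 1230), tryptophan (1347, 755), tyrosine (837, 641),
    disulfide and C-S stretches (465, 503, 553, 658), protein backbone C-C
    (1132), lipid chain modes (779, 1056, 1102, 1318, 1389, 1436) and
    nucleic-acid signals (adenine 725, backbone 810).

    The two default conditions differ in occurrence probability by at least
    0.3 for more than ten bands, so the conditions are separable by design;
    the disulfide pair 465/503 is the canonical planted co-occurrence.
    """

    def band(center, fwhm, amp, tag, p_ctrl, p_trt):
        return BandSpec(center, fwhm, amp, {CONTROL: p_ctrl, TREATED: p_trt}, tag)

    return [
        band(465.0, 12.0, 14.0, "protein", 0.20, 0.60),
        band(503.0, 12.0, 14.0, "protein", 0.30, 0.70),
        band(553.0, 12.0, 12.0, "protein", 0.25, 0.25),
        band(641.0, 12.0, 12.0, "protein", 0.30, 0.30),
        band(658.0, 12.0, 12.0, "protein", 0.20, 0.50),
        band(725.0, 10.0, 16.0, "dna", 0.15, 0.55),
        band(755.0, 10.0, 13.0, "protein", 0.40, 0.40),
        band(779.0, 12.0, 12.0, "lipid", 0.50, 0.15),
        band(810.0, 12.0, 12.0, "dna", 0.10, 0.40),
        band(837.0, 10.0, 12.0, "protein", 0.35, 0.35),
        band(870.0, 10.0, 12.0, "protein", 0.30, 0.60),
        band(1006.0, 8.0, 20.0, "protein", 0.90, 0.85),
        band(1028.0, 8.0, 14.0, "protein", 0.60, 0.60),
        band(1056.0, 12.0, 13.0, "lipid", 0.50, 0.20),
        band(1102.0, 12.0, 12.0, "lipid", 0.30, 0.30),
        band(1132.0, 12.0, 13.0, "protein", 0.40, 0.75),
        band(1230.0, 14.0, 13.0, "protein", 0.50, 0.80),
        band(1276.0, 14.0, 13.0, "protein", 0.60, 0.30),
        band(1318.0, 14.0, 13.0, "lipid", 0.55, 0.25),
        band(1347.0, 12.0, 13.0, "protein", 0.35, 0.65),
        band(1389.0, 12.0, 12.0, "lipid", 0.20, 0.20),
        band(1436.0, 14.0, 14.0, "lipid", 0.70, 0.40),
        band(1574.0, 14.0, 13.0, "protein", 0.50, 0.50),
        band(1704.0, 14.0, 13.0, "protein", 0.30, 0.65),
    ]


def default_config(n_per_class: int = 400) -> GeneratorConfig:
    """The standard two-condition campaign used throughout the package."""
    return GeneratorConfig(
        bands=default_band_table(),
        pairs=[CooccurrencePair(0, 1, 0.8)],
        n_per_class={CONTROL: n_per_class, TREATED: n_per_class},
    )
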