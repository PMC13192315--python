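import numpy as np
import pytest

from sers_cooccur import synthetic
from sers_cooccur.spectra_io import SpectraSet, Spectrum, WavenumberAxis


@pytest.fixture
def axis():
    return WavenumberAxis(np.arange(400.0, 1801.0, 2.0))


@pytest.fixture
def small_axis():
    return WavenumberAxis(np.arange(400.0, 421.0, 2.0))


@pytest.fixture
def small_set(small_axis):
    rng = np.random.default_rng(0)
    matrix = rng.normal(size=(6, len(small_axis)))
    labels = np.array(["a", "a", "a", "b", "b", "b"], dtype=object)
    return SpectraSet(small_axis, matrix, labels)


@pytest.fixture
def scaled_config():
    """Coarse-axis version of the default campaign for fast forest tests."""
    cfg = synthetic.default_config(100)
    cfg.axis_step = 8.0
    return cfg


def make_spectrum(axis, intensities, **meta):
    return Spectrum(axis, np.asarray(intensities, dtype=float), meta)
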