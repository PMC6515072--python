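import numpy as np
import pytest

from copigment.colorimetry import SampleMeta, Spectrum, default_grid


@pytest.fixture(scope="session")
def grid():
    return default_grid()


def flat_spectrum(a: float, sample_id: str = "flat", **meta) -> Spectrum:
    wl = np.arange(400.0, 801.0, 5.0)
    return Spectrum(sample_id, wl, np.full(wl.size, a), SampleMeta(**meta))


def gaussian_spectrum(
    amp: float = 1.0,
    center: float = 520.0,
    width: float = 30.0,
    step: float = 1.0,
    sample_id: str = "band",
    **meta,
) -> Spectrum:
    wl = np.arange(400.0, 800.0 + 1e-9, step)
    ab = amp * np.exp(-((wl - center) ** 2) / (2.0 * width**2))
    return Spectrum(sample_id, wl, ab, SampleMeta(**meta))


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
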