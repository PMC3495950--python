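import numpy as np
import pytest

from seldikit import synthetic
from seldikit.core_io import Group, Spectrum, SpectrumSet, Stage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_spectrum(mz, intensity, sid="s1", stage=Stage.RAW, **kw):
    return Spectrum(mz=np.asarray(mz, float), intensity=np.asarray(intensity, float),
                    id=sid, stage=stage, **kw)


@pytest.fixture
def flat_grid():
    return np.linspace(1000.0, 2000.0, 512)


@pytest.fixture(scope="session")
def small_sim():
    cfg = synthetic.default_config(seed=42, n_spectra=6)
    return synthetic.simulate_spectrum_set(cfg)


@pytest.fixture(scope="session")
def op1024(tmp_path_factory):
    from seldikit.wavelet_denoise import build_wavelet_operator

    cache = tmp_path_factory.mktemp("wcache") / "op1024.npz"
    return build_wavelet_operator(1024, family="db8", levels=6, cache_path=cache)


@pytest.fixture(scope="session")
def op256():
    from seldikit.wavelet_denoise import build_wavelet_operator

    return build_wavelet_operator(256, family="db8", levels=4)
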