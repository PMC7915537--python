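import numpy as np
import pytest

from meiboquant.eic_quant import calibrate_response
from meiboquant.lipid_registry import build_default_registry
from meiboquant.synthetic_data import SimConfig, make_preset, simulate_chromatogram


@pytest.fixture(scope="session")
def registry():
    return build_default_registry()


@pytest.fixture(scope="session")
def noiseless_cfg():
    return SimConfig(seed=1, intensity_noise_cv=0.0, mz_jitter_sd_mda=0.0)


@pytest.fixture(scope="session")
def noisy_cfg():
    # defaults: 2% intensity CV, 3 mDa m/z jitter
    return SimConfig(seed=101)


@pytest.fixture(scope="session")
def std_scans_noiseless(registry, noiseless_cfg):
    return simulate_chromatogram(make_preset("standard_mix"), noiseless_cfg, registry)


@pytest.fixture(scope="session")
def factors_noiseless(std_scans_noiseless, registry):
    return calibrate_response(std_scans_noiseless, registry)


@pytest.fixture(scope="session")
def wt_scans_noiseless(registry, noiseless_cfg):
    return simulate_chromatogram(make_preset("wild_type"), noiseless_cfg, registry)


@pytest.fixture(scope="session")
def std_scans_noisy(registry, noisy_cfg):
    return simulate_chromatogram(make_preset("standard_mix"), noisy_cfg, registry)


@pytest.fixture(scope="session")
def factors_noisy(std_scans_noisy, registry):
    return calibrate_response(std_scans_noisy, registry)


@pytest.fixture(scope="session")
def wt_scans_noisy(registry):
    return simulate_chromatogram(make_preset("wild_type"), SimConfig(seed=102),
                                 registry)


@pytest.fixture(scope="session")
def null_scans_noisy(registry):
    return simulate_chromatogram(make_preset("soat1_null"), SimConfig(seed=103),
                                 registry)
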