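import numpy as np
import pytest

from maldimtu.io import Spectrum
from maldimtu.preprocess import ParamSet
from maldimtu.synth import SynthConfig, generate_bts, generate_library

WIDE_RANGE = (0.0, 30000.0)


def mk_spectrum(mz, intensity, sid="s1", group="isolate", target="T1",
                isolate=None):
    """Small-spectrum helper with a permissive acquisition range."""
    return Spectrum(
        spectrum_id=sid,
        isolate_id=isolate or sid,
        group=group,
        target_id=target,
        mz=np.asarray(mz, dtype=float),
        intensity=np.asarray(intensity, dtype=float),
        mass_range=WIDE_RANGE,
    )


@pytest.fixture(scope="session")
def default_params():
    return ParamSet(
        smooth_halfwindow=10,
        baseline_halfwindow=100,
        align_halfwindow=20,
        align_tolerance=0.002,
        align_snr=8.0,
        peak_halfwindow=20,
        peak_snr=8.0,
    )


@pytest.fixture(scope="session")
def small_cfg():
    # 6 species x 2 strains on a 2 Da grid: fast but realistic
    return SynthConfig(n_species=6, strains_per_species=2, grid_step=2.0, seed=11)


@pytest.fixture(scope="session")
def small_library(small_cfg):
    return generate_library(small_cfg)


@pytest.fixture(scope="session")
def bts_spectra(small_cfg):
    return generate_bts(small_cfg, n_targets=2, replicates_per_target=2)
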