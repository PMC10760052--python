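import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from smassay import FieldParams, PhotophysicsParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_trace_params():
    """Dimer photophysics producing sharp, homoscedastic traces (step SNR 10)."""
    return PhotophysicsParams(
        copies_n=2, p_mature=0.8, bleach_rate=1.0 / 30.0,
        unit_intensity=100.0, background_level=0.0, read_noise_sd=10.0,
        frame_interval_s=0.1, n_frames=1200, shot_noise=False)


@pytest.fixture
def small_field():
    return FieldParams(rows=192, cols=192, psf_sigma_px=1.3, spot_density=25,
                       min_separation_px=12, edge_margin_px=12)
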