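import numpy as np
import pytest

from flimda import DecayImage, InstrumentConfig, decay_curve
from flimda.instrument import FluorSpecies


@pytest.fixture
def cfg():
    """Default instrument: 80 MHz, 256 bins, tiny 4x4 field for speed."""
    return InstrumentConfig(width_px=4, height_px=4)


@pytest.fixture
def small_cfg():
    """Coarse instrument for cohort-level tests: 32x32 px, 64 bins."""
    return InstrumentConfig(n_bins=64, width_px=32, height_px=32)


def uniform_decay_image(tau_ns: float, cfg: InstrumentConfig,
                        photons: float = 1e6) -> DecayImage:
    """Noise-free homogeneous field of a single mono-exponential species."""
    curve = decay_curve([(FluorSpecies("sp", tau_ns), 1.0)], cfg, photons)
    counts = np.broadcast_to(curve, (*cfg.shape, cfg.n_bins)).copy()
    return DecayImage(counts=counts, cfg=cfg)
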