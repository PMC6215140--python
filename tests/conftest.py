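import numpy as np
import pytest

from muxrec import FrontEndConfig, MuxTiming, SceneConfig, generate_scene


@pytest.fixture
def config():
    return FrontEndConfig()


@pytest.fixture
def timing20():
    # 20 electrodes at 30 kHz/channel: 600 kHz aggregate, 166.7 ns
    # conversion window, 1.5 us integration window
    return MuxTiming(M=20, fch=30e3, Tconv=1e-6 / 6.0)


@pytest.fixture
def grounded_scene():
    """All-zero scene: no offsets, spikes, background or thermal noise."""
    cfg = SceneConfig(
        n_electrodes=20,
        offset_range=(-1e-12, 1e-12),
        spike_rate=0.0,
        background_noise_rms=0.0,
        electrode_model=None,
    )
    return generate_scene(cfg, seed=7)


def dc_scene(offsets, seed=0):
    """Scene with exact DC offsets and every noise source disabled."""
    offsets = np.atleast_1d(np.asarray(offsets, float))
    cfg = SceneConfig(
        n_electrodes=offsets.size,
        offset_range=(-1.0, 1.0),
        spike_rate=0.0,
        background_noise_rms=0.0,
        electrode_model=None,
    )
    scene = generate_scene(cfg, seed=seed)
    scene.dc_offsets = offsets.copy()
    return scene
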