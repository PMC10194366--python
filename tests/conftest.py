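import numpy as np
import pytest

from greenrow import (
    SynthFieldConfig,
    fit_color_model,
    generate_field_sequence,
    generate_greenhouse_refs,
    remove_background,
    segment_plants,
)


@pytest.fixture(scope="session")
def small_cfg():
    """A fast 120x160 scene: 3 foreground plants, 40 frames, overlap mid-way."""
    return SynthFieldConfig(
        rows=120,
        cols=160,
        n_plants=3,
        n_bg_plants=4,
        n_frames=40,
        fg_baseline=8,
        bg_baseline=55,
        fg_max_height=(60.0, 75.0),
        bg_max_height=(45.0, 60.0),
        growth_rate=(0.18, 0.25),
        midpoint_frame=(16.0, 22.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_scene(small_cfg):
    """Frames + truth + segmentation artifacts for the small scene."""
    frames, truth = generate_field_sequence(small_cfg)
    refs = generate_greenhouse_refs(small_cfg)
    model = fit_color_model(refs, k=3, seed=0)
    masks = [segment_plants(f, model) for f in frames]
    bg_removed = [remove_background(f, m) for f, m in zip(frames, masks)]
    return {
        "cfg": small_cfg,
        "frames": frames,
        "truth": truth,
        "masks": masks,
        "bg_removed": bg_removed,
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
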