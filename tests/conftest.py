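import numpy as np
import pytest

from cinepc.combine import average_combine
from cinepc.network import NetConfig, TrainConfig, build_network, train
from cinepc.phantom import render_phase_cycled_cine, sample_scene
from cinepc.protocol import ScanProtocol

# desk-scale study conditions shared by the heavier experiments:
# 26 randomized short-axis scenes at 64x64, 8 frames; first 20 train the
# network, the last 6 are held out for evaluation
N_SCENES = 26
N_TRAIN = 20
SCENE_GRID = (64, 64)
SCENE_FRAMES = 8
SCENE_SEED0 = 100
PAIR = (90.0, 270.0)


@pytest.fixture(scope="session")
def testing_protocol():
    return ScanProtocol(tr_ms=2.98, te_ms=1.37, flip_deg=60.0,
                        views_per_segment=24, n_cardiac_phases=25,
                        phase_increments_deg=[90.0, 270.0])


@pytest.fixture(scope="session")
def lv_scenes():
    """Rendered randomized LV short-axis phase-cycled sets."""
    scenes = []
    for i in range(N_SCENES):
        config, protocol = sample_scene("lv_short_axis", seed=SCENE_SEED0 + i,
                                        grid=SCENE_GRID, n_frames=SCENE_FRAMES)
        scenes.append(render_phase_cycled_cine(config, protocol, list(PAIR)))
    return scenes


@pytest.fixture(scope="session")
def trained_model(lv_scenes):
    """Dual-encoder network trained on the first N_TRAIN scenes."""
    triples = [(s.movies[0], s.movies[1], s.reference)
               for s in lv_scenes[:N_TRAIN]]
    model = build_network(NetConfig(n_levels=3, base_channels=8), seed=0)
    model, history = train(
        model, triples,
        TrainConfig(lr=1e-3, steps=900, batch=2, crop=(6, 32, 32), seed=7))
    model.history = history
    return model


@pytest.fixture(scope="session")
def heldout_scenes(lv_scenes):
    return lv_scenes[N_TRAIN:]
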