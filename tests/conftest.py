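import numpy as np
import pytest

from vesiclefuse.io import Epoch, EpochTimeline, StimulationProtocol, build_timeline
from vesiclefuse.simulate import SceneConfig, condition_preset, default_timeline, make_scene, render_movie


@pytest.fixture(scope="session")
def fusion_assay_timeline():
    """Canonical 2x8x50 AP paradigm with NH4 dequench at +50 s."""
    return build_timeline(StimulationProtocol(), 150.0, nh4_delay_s=50.0,
                          nh4_duration_s=10.0)


@pytest.fixture(scope="session")
def wt_scene(fusion_assay_timeline):
    cfg = condition_preset("WT-like", seed=3)
    truth = make_scene(cfg, fusion_assay_timeline)
    movie = render_movie(truth, cfg, fusion_assay_timeline)
    return cfg, truth, movie


@pytest.fixture(scope="session")
def transport_scene():
    cfg = condition_preset("NPY-like", seed=5)
    timeline = EpochTimeline((Epoch("baseline", 0.0, cfg.duration_s),))
    truth = make_scene(cfg, timeline)
    movie = render_movie(truth, cfg, timeline)
    return cfg, truth, movie, timeline
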