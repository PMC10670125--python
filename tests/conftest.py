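import numpy as np
import pytest

from histovasc.phantom import PhantomConfig, generate_network, render_stack


@pytest.fixture(scope="session")
def small_phantom():
    """Small aligned phantom (no misalignment, no artifacts): 6 slices,
    4 vessels, 256x256 — fast enough for per-operation tests."""
    cfg = PhantomConfig(
        volume_vox=(6, 256, 256),
        n_vessels=4,
        radius_range_vox=(6, 18),
        branching_prob=0.0,
        misalign_max_rotation_deg=0.0,
        misalign_max_translation_px=0.0,
        misalign_max_scale_dev=0.0,
        artifact_rate=0.0,
        seed=5,
    )
    graph = generate_network(cfg)
    slices, truth = render_stack(graph, cfg)
    return cfg, graph, slices, truth


@pytest.fixture(scope="session")
def misaligned_phantom():
    """10-slice phantom with per-slice similarity misalignment."""
    cfg = PhantomConfig(
        volume_vox=(10, 256, 256),
        n_vessels=4,
        radius_range_vox=(6, 18),
        branching_prob=0.0,
        misalign_max_rotation_deg=6.0,
        misalign_max_translation_px=10.0,
        misalign_max_scale_dev=0.01,
        artifact_rate=0.0,
        seed=9,
    )
    graph = generate_network(cfg)
    slices, truth = render_stack(graph, cfg)
    return cfg, graph, slices, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
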