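import dataclasses

import numpy as np
import pytest

import pulsechase as pc


def match_f1(detected: np.ndarray, truth: np.ndarray, radius: float) -> float:
    """Detection F1 with greedy nearest matching at the given radius."""
    from scipy.spatial import cKDTree

    if len(detected) == 0 or len(truth) == 0:
        return 0.0
    d, j = cKDTree(truth).query(detected)
    matched: set[int] = set()
    tp = 0
    for dd, jj in sorted(zip(d, j)):
        if dd <= radius and jj not in matched:
            matched.add(int(jj))
            tp += 1
    precision = tp / len(detected)
    recall = tp / len(truth)
    return 2 * precision * recall / (precision + recall) if tp else 0.0


@pytest.fixture(scope="session")
def demo_config():
    return pc.default_config(seed=3)


@pytest.fixture(scope="session")
def demo_movie(demo_config):
    """One rendered five-cycle movie at default noise, with ground truth."""
    return pc.simulate_movie(demo_config)


@pytest.fixture(scope="session")
def demo_masks(demo_config, demo_movie):
    return pc.segment_movie(demo_movie, demo_config.segmentation)


@pytest.fixture(scope="session")
def demo_trace(demo_movie, demo_masks):
    return pc.measure_trace(demo_movie, demo_masks)


@pytest.fixture(scope="session")
def demo_cycles(demo_config, demo_movie, demo_masks):
    return pc.detect_cycles(demo_movie, demo_masks, demo_config.cycle_detection)


@pytest.fixture(scope="session")
def noiseless_constant_movie():
    """Noiseless movie with constant light pool (no degradation, no synthesis),
    no photoswitch events: every cycle's plateau should be identical."""
    cfg = pc.default_config(seed=0)
    plan = pc.build_plan(cfg)
    params = pc.KineticParams(synthesis_rate=0.0,
                              schedule=pc.RateSchedule.constant(0.0), L0=100.0)
    traj = pc.simulate_kinetics(params, plan)
    noise = pc.NoiseParams(seed=0, photons_per_unit=0.0, read_sigma=0.0)
    movie = pc.render_movie(traj, plan, cfg.imaging, noise)
    return cfg, movie


@pytest.fixture(scope="session")
def pipeline_runs(tmp_path_factory):
    """The demo pipeline run twice with the same config and seed."""
    import warnings

    cfg = pc.default_config(seed=7)
    root = tmp_path_factory.mktemp("pipeline")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rep1 = pc.run_pipeline(cfg, root / "run1")
        rep2 = pc.run_pipeline(cfg, root / "run2")
    return root, rep1, rep2
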