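import numpy as np
import pytest
from hypothesis import settings

import meamicro as mm

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def layout5():
    """Standard five-electrode in-channel path at 200 μm pitch."""
    return mm.build_circuit_layout(5, 200.0)


@pytest.fixture(scope="session")
def sim_circuit():
    """One rendered two-neuron circuit shared by read-only tests."""
    cfg = mm.SimConfig(n_neurons=2, duration=10.0, seed=7)
    layout = mm.build_circuit_layout(5, 200.0)
    rec, sts, gt = mm.simulate_circuit(cfg, layout)
    return cfg, layout, rec, sts, gt


def render_events(times, layout, cfg):
    """Render explicit AP times (single axon, velocity v0) to a recording."""
    times = np.asarray(times, float)
    gt = mm.GroundTruth(times, np.zeros(times.size, int),
                        np.ones(times.size, int),
                        np.full(times.size, cfg.v0))
    return mm.render_extracellular(gt, layout, cfg)


def detection_scores(detected, truth, tol_s=0.5e-3):
    """(recall, n_false) of detected vs ground-truth spike times."""
    detected = np.asarray(detected, float)
    truth = np.asarray(truth, float)
    if truth.size == 0:
        return float("nan"), detected.size
    hits = 0
    used = np.zeros(detected.size, bool)
    for t in truth:
        if detected.size == 0:
            break
        d = np.abs(detected - t)
        i = int(np.argmin(d))
        if d[i] <= tol_s and not used[i]:
            used[i] = True
            hits += 1
    return hits / truth.size, int((~used).sum())
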