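import numpy as np
import pytest

from bcpnn_cue import SimulationConfig, derive_constants, run_simulation
from bcpnn_cue.io import make_patterns


@pytest.fixture(scope="session")
def cfg():
    return SimulationConfig()


@pytest.fixture(scope="session")
def k(cfg):
    return derive_constants(cfg)


@pytest.fixture(scope="session")
def small_net_runs():
    """Lazy / CUE(oracle) / flushing / CUE(static) runs of a 4x5 network
    under common random numbers (shared across strategy tests)."""
    cfg = SimulationConfig(n_hcu=4, n_mcu=5, seed=3)
    sched = make_patterns(4, 5, n_patterns=4, duration=300, seed=1)
    runs = {}
    for strat, approx in [("lazy", "none"), ("cue", "oracle"),
                          ("flushing", "none"), ("cue", "static")]:
        runs[(strat, approx)] = run_simulation(
            cfg.replace(strategy=strat, approx=approx), sched)
    return runs


@pytest.fixture(scope="session")
def paper_scale_runs():
    """10x10 network trained on 10 patterns x 500 ms: the study conditions
    for the trajectory-equivalence and memory-demand checks."""
    cfg = SimulationConfig(n_hcu=10, n_mcu=10, seed=7)
    sched = make_patterns(10, 10, n_patterns=10, duration=500, seed=7)
    runs = {}
    for strat, approx in [("lazy", "none"), ("cue", "oracle"),
                          ("flushing", "none"), ("cue", "static")]:
        runs[(strat, approx)] = run_simulation(
            cfg.replace(strategy=strat, approx=approx), sched)
    return runs
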