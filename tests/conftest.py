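import numpy as np
import pytest

from plumecoding import GeneratorConfig
from plumecoding import synthetic as syn


@pytest.fixture(scope="session")
def cfg():
    return GeneratorConfig(seed=7)


@pytest.fixture(scope="session")
def sniff_truth(cfg):
    """4 Hz jitter-free sniffing over one trial, with ground truth."""
    trace, onsets, peaks = syn.gen_sniff_trace(4.0, cfg, jitter=0.0)
    return trace, onsets, peaks


@pytest.fixture(scope="session")
def small_session():
    """Six planted glomeruli, 24 square-wave trials, both clusters."""
    config = GeneratorConfig(seed=42)
    gloms = syn.gen_glomerulus_population(6, 0.5, config)
    trials, truth = syn.gen_session(
        config, gloms, n_trials=24, n_engagement=0,
        cs_plus_menu=(0.2, 0.5, 0.8), cs_minus_menu=None,
        gains=(1.0,), kind="square")
    return trials, truth


@pytest.fixture(scope="session")
def go_nogo_session():
    """Default 64-trial Go/No-Go session without imaging."""
    config = GeneratorConfig(seed=99)
    trials, truth = syn.gen_session(config, [], n_trials=64)
    return trials, truth
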