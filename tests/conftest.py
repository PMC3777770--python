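import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from mslseg.phantom import PhantomSpec, generate_phantom
from mslseg.pipeline import run_phantom_pipeline

PHANTOM_SEED = 7


@pytest.fixture(scope="session")
def phantom():
    """Default 64^3 phantom (default noise and bias), fixed seed."""
    return generate_phantom(PhantomSpec(seed=PHANTOM_SEED))


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless, bias-free phantom: exactly piecewise-constant per class."""
    return generate_phantom(PhantomSpec(seed=PHANTOM_SEED, noise_sd=0.0,
                                        bias_amplitude=0.0))


@pytest.fixture(scope="session")
def pipeline_result(phantom):
    """Full end-to-end pipeline run on the default phantom."""
    return run_phantom_pipeline(phantom)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_mask(rng, shape, p=0.4):
    m = rng.random(shape) < p
    if not m.any():
        m[tuple(d // 2 for d in shape)] = True
    return m
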