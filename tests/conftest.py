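import numpy as np
import pytest

from neurogain.connectome import Connectome
from neurogain.synthetic import SynthConnectomeSpec, generate_connectome


@pytest.fixture(scope="session")
def triangle() -> Connectome:
    w = np.ones((3, 3)) - np.eye(3)
    return Connectome(w)


@pytest.fixture(scope="session")
def path3() -> Connectome:
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 1.0
    w[1, 2] = w[2, 1] = 1.0
    return Connectome(w)


def random_connectome(n: int, seed: int, density: float = 0.6) -> Connectome:
    """Small random weighted graph for oracle comparisons."""
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    w = np.where(rng.random(iu[0].size) < density, rng.random(iu[0].size), 0.0)
    out = np.zeros((n, n))
    out[iu] = w
    out += out.T
    return Connectome(out)


@pytest.fixture(scope="session")
def synth90() -> Connectome:
    """Default synthetic connectome with a planted club."""
    return generate_connectome(SynthConnectomeSpec(seed=1))


@pytest.fixture(scope="session")
def synth_dynamic() -> Connectome:
    """Synthetic connectome tuned so the synchronization transition falls
    inside r0 in [0.33, 1] at alpha = 0.65 (milder core boost)."""
    return generate_connectome(SynthConnectomeSpec(seed=1, core_boost=2.0))
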