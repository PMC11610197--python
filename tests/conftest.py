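import numpy as np
import pytest

from smartdeconv.data import MarkerSpec, ModelConfig, SpotCounts


@pytest.fixture
def tiny_counts():
    # spot0 holds one molecule each of g0,g1,g2; spot1 holds two of g0
    mat = np.array([[1, 2], [1, 0], [1, 0]])
    return SpotCounts(mat, ["g0", "g1", "g2"], ["s0", "s1"])


@pytest.fixture
def tiny_markers():
    return MarkerSpec(["M", "N"], {"M": ["g0"], "N": []})


@pytest.fixture
def tiny_config():
    return ModelConfig(beta=0.05, beta_tilde=0.3, gamma1=1.0, gamma2=1.0,
                       iterations=10, burn_in=5, thin=1,
                       use_weighting=False, seed=0)


@pytest.fixture
def small_sim():
    from smartdeconv.simulate import generate_from_model
    return generate_from_model(V=50, D=40, K=3, K_tilde=3,
                               markers_per_type=4, N_d=200, seed=7)
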