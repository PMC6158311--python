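import numpy as np
import pytest

from rnnica import model as M
from rnnica import preprocess, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_state():
    """A D=3, H=5 model with random well-conditioned parameters."""
    cfg = M.ModelConfig(dim=3, hidden=5, init_width=7, dropout=0.2)
    return M.initialize(cfg, seed=0)


@pytest.fixture
def toy_dataset():
    """Tiny linear-mixture dataset for fast training tests."""
    seqs, Mtrue = simulate.generate_linear_ica_toy(4, 80, 8, seed=7)
    return preprocess.ReducedDataset(sequences=seqs), Mtrue


def constant_head_state(D, mu_const=0.0, sigma_const=1.0, W=None, hidden=4):
    """Model whose predictive density is frozen at (mu_const, sigma_const):
    heads zeroed, biases solved so sigma = softplus(b) + floor = sigma_const."""
    cfg = M.ModelConfig(dim=D, hidden=hidden, init_width=4, dropout=0.0)
    st = M.initialize(cfg, seed=0)
    st.W_mu[:] = 0.0
    st.b_mu[:] = mu_const
    st.W_sigma[:] = 0.0
    st.b_sigma[:] = np.log(np.expm1(sigma_const - cfg.sigma_floor))
    if W is not None:
        st.W = np.asarray(W, dtype=float)
    return st
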