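"""Probabilistic core of RNN-ICA.

The model couples a square linear unmixing transform ``s_t = W x_t`` with a
vanilla recurrent network that emits, at every time step, the location and
scale of a factorized logistic density over the *next* source vector.  The
sequence log-likelihood is the change-of-variables objective

    log p(x_{1:T}) = T log|det W| + sum_t sum_d log Logistic(s_{t,d}; mu_{t,d}, sigma_{t,d})

where (mu_t, sigma_t) are read out from the hidden state h_t, itself driven by
the previous *data* frames.  The hidden state generating the first frame of a
window is predicted from a reserved context frame by a two-layer softplus
feed-forward network with dropout.

Everything here is plain NumPy with analytic gradients (backpropagation
through time, hand-derived); the gradient of every parameter is exercised
against central finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np

SIGMA_FLOOR = 1e-4

# ---------------------------------------------------------------------------
# numerically safe primitives
# ---------------------------------------------------------------------------


def softplus(x: np.ndarray) -> np.ndarray:
    """log(1 + exp(x)), overflow-safe."""
    return np.logaddexp(0.0, x)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def logistic_log_density(x, mu, sigma):
    """Elementwise log-density of the logistic distribution.

    Stable for standardized residuals up to ~1e3: the density is evaluated as
    ``-z - 2*log1p(exp(-z)) - log(sigma)`` through log-add-exp, never via the
    raw pdf.
    """
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("logistic scale must be strictly positive")
    z = (np.asarray(x, dtype=float) - mu) / sigma
    return -z - 2.0 * softplus(-z) - np.log(sigma)


def log_abs_det(W: np.ndarray) -> float:
    """Sign-aware log|det W| via LU (never det-then-log)."""
    sign, logdet = np.linalg.slogdet(W)
    if sign == 0 or not np.isfinite(logdet):
        raise np.linalg.LinAlgError(
            f"unmixing matrix is singular (cond={np.linalg.cond(W):.3e})"
        )
    return float(logdet)


def unmix(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Apply the unmixing transform row-wise: row t of the result is W @ x_t."""
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != W.shape[1]:
        raise ValueError(f"dimension mismatch: X has {X.shape[-1]} columns, W is {W.shape}")
    cond = np.linalg.cond(W)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(f"unmixing matrix is singular (cond={cond:.3e})")
    return X @ W.T


def mixing_matrix(W: np.ndarray) -> np.ndarray:
    """Inverse of the unmixing matrix; its columns are the component loadings."""
    return np.linalg.inv(W)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass
class ModelConfig:
    dim: int
    hidden: int = 100
    init_width: int = 100
    dropout: float = 0.2
    sigma_floor: float = SIGMA_FLOOR
    rnn_input: str = "data"  # "data": RNN sees x_{t-1}; "sources": RNN sees W x_{t-1}
    init_mode: str = "network"  # "network": context-frame init net; "constant": learned h0

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        return cls(**json.loads(s))


@dataclass
class ModelState:
    """All trainable parameters: unmixing matrix, recurrence, heads, init net."""

    config: ModelConfig
    W: np.ndarray
    U_R: np.ndarray
    U_I: np.ndarray
    b: np.ndarray
    W_mu: np.ndarray
    b_mu: np.ndarray
    W_sigma: np.ndarray
    b_sigma: np.ndarray
    A1: np.ndarray
    c1: np.ndarray
    A2: np.ndarray
    c2: np.ndarray
    A3: np.ndarray
    c3: np.ndarray
    h0: np.ndarray = field(default=None)  # used only when init_mode == "constant"

    PARAM_NAMES = (
        "W", "U_R", "U_I", "b", "W_mu", "b_mu", "W_sigma", "b_sigma",
        "A1", "c1", "A2", "c2", "A3", "c3", "h0",
    )

    def params(self) -> dict:
        return {k: getattr(self, k) for k in self.PARAM_NAMES}

    def to_vector(self) -> np.ndarray:
        return np.concatenate([getattr(self, k).ravel() for k in self.PARAM_NAMES])

    def from_vector(self, v: np.ndarray) -> "ModelState":
        out, i = {}, 0
        for k in self.PARAM_NAMES:
            a = getattr(self, k)
            out[k] = v[i:i + a.size].reshape(a.shape).copy()
            i += a.size
        return ModelState(config=self.config, **out)

    def copy(self) -> "ModelState":
        return ModelState(config=self.config, **{k: getattr(self, k).copy() for k in self.PARAM_NAMES})


def initialize(config: ModelConfig, seed: int = 0) -> ModelState:
    """Reference initialization: orthogonal recurrence, scaled-uniform input
    weights and heads, W = identity + small noise."""
    rng = np.random.default_rng(seed)
    D, H, P = config.dim, config.hidden, config.init_width

    def uniform(shape, fan_in, fan_out):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=shape)

    q, _ = np.linalg.qr(rng.standard_normal((H, H)))
    return ModelState(
        config=config,
        W=np.eye(D) + 0.01 * rng.standard_normal((D, D)),
        U_R=q,
        U_I=uniform((H, D), D, H),
        b=np.zeros(H),
        W_mu=uniform((D, H), H, D),
        b_mu=np.zeros(D),
        W_sigma=uniform((D, H), H, D),
        b_sigma=np.zeros(D),
        A1=uniform((P, D), D, P),
        c1=np.zeros(P),
        A2=uniform((P, P), P, P),
        c2=np.zeros(P),
        A3=uniform((H, P), P, H),
        c3=np.zeros(H),
        h0=np.zeros(H),
    )


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------


def recurrent_step(h_prev: np.ndarray, x_prev: np.ndarray, state: ModelState) -> np.ndarray:
    """One hidden-state update: tanh(U_R h_{t-1} + U_I x_{t-1} + b)."""
    h_prev = np.atleast_2d(h_prev)
    x_prev = np.atleast_2d(x_prev)
    if h_prev.shape[-1] != state.U_R.shape[1] or x_prev.shape[-1] != state.U_I.shape[1]:
        raise ValueError("shape mismatch in recurrent step")
    return np.tanh(h_prev @ state.U_R.T + x_prev @ state.U_I.T + state.b)


def predict_distribution(h: np.ndarray, state: ModelState):
    """Logistic density parameters read out from a hidden state.

    mu is a plain linear head; sigma passes through softplus plus a small
    floor so the scale is strictly positive.
    """
    h = np.asarray(h, dtype=float)
    mu = h @ state.W_mu.T + state.b_mu
    a = h @ state.W_sigma.T + state.b_sigma
    sigma = softplus(a) + state.config.sigma_floor
    return mu, sigma


def initial_state(x_context: np.ndarray, state: ModelState, *,
                  training: bool = False, rng: np.random.Generator | None = None):
    """Hidden state generating the first modeled frame, predicted from the
    reserved context frame by two softplus layers (dropout in training mode)
    with a tanh output."""
    cache = _init_forward(np.atleast_2d(x_context), state, training=training, rng=rng)
    h1 = cache["h0"]
    mu, sigma = predict_distribution(h1, state)
    return h1, (mu, sigma)


def _init_forward(x0, state, *, training, rng):
    cfg = state.config
    if cfg.init_mode == "constant":
        h0 = np.tanh(np.broadcast_to(state.h0, (x0.shape[0], state.h0.size)).copy())
        return {"h0": h0, "mode": "constant"}
    p = cfg.dropout if training else 0.0
    if p > 0 and rng is None:
        raise ValueError("training-mode dropout needs a seeded Generator")
    u1 = x0 @ state.A1.T + state.c1
    z1 = softplus(u1)
    m1 = (rng.random(z1.shape) >= p) / (1.0 - p) if p > 0 else np.ones_like(z1)
    z1d = z1 * m1
    u2 = z1d @ state.A2.T + state.c2
    z2 = softplus(u2)
    m2 = (rng.random(z2.shape) >= p) / (1.0 - p) if p > 0 else np.ones_like(z2)
    z2d = z2 * m2
    u0 = z2d @ state.A3.T + state.c3
    return {"x0": x0, "u1": u1, "m1": m1, "z1d": z1d, "u2": u2, "m2": m2,
            "z2d": z2d, "h0": np.tanh(u0), "mode": "network"}


def forward(state: ModelState, X: np.ndarray, x_context: np.ndarray, *,
            training: bool = False, rng: np.random.Generator | None = None) -> dict:
    """Run the model over a batch of windows.

    Parameters
    ----------
    X : (B, T, D) modeled frames (the first is generated from the context
        frame's predicted hidden state; the last is the window's target frame).
    x_context : (B, D) reserved frame preceding each window.

    Returns a cache with sources, mu, sigma, hidden states, per-window
    log-likelihoods, and everything the backward pass needs.
    """
    X = np.asarray(X, dtype=float)
    x_context = np.asarray(x_context, dtype=float)
    B, T, D = X.shape
    cfg = state.config
    if D != cfg.dim:
        raise ValueError(f"data dimension {D} != model dimension {cfg.dim}")
    if T < 2:
        raise ValueError("window must contain at least 2 frames")

    logdet = log_abs_det(state.W)
    S = X @ state.W.T

    init_cache = _init_forward(x_context, state, training=training, rng=rng)
    H = np.empty((B, T, cfg.hidden))
    H[:, 0] = init_cache["h0"]
    inputs = S if cfg.rnn_input == "sources" else X
    for t in range(1, T):
        H[:, t] = np.tanh(H[:, t - 1] @ state.U_R.T + inputs[:, t - 1] @ state.U_I.T + state.b)

    Hf = H.reshape(B * T, cfg.hidden)
    mu = (Hf @ state.W_mu.T + state.b_mu).reshape(B, T, D)
    a_sig = (Hf @ state.W_sigma.T + state.b_sigma).reshape(B, T, D)
    sigma = softplus(a_sig) + cfg.sigma_floor

    z = (S - mu) / sigma
    logp = -z - 2.0 * softplus(-z) - np.log(sigma)
    if not np.all(np.isfinite(logp)):
        bad = np.argwhere(~np.isfinite(logp))[0]
        raise FloatingPointError(
            f"non-finite log-density at window {bad[0]}, time step {bad[1]}")
    ll = T * logdet + logp.sum(axis=(1, 2))

    return {"X": X, "S": S, "H": H, "mu": mu, "sigma": sigma, "a_sig": a_sig,
            "z": z, "ll": ll, "logdet": logdet, "init": init_cache,
            "inputs": inputs}


def sequence_log_likelihood(state: ModelState, X: np.ndarray, x_context: np.ndarray) -> float:
    """Mean per-window sequence log-likelihood (evaluation mode)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        X = X[None]
        x_context = np.atleast_2d(x_context)
    return float(forward(state, X, x_context)["ll"].mean())


# ---------------------------------------------------------------------------
# backward pass (BPTT)
# ---------------------------------------------------------------------------


def loss_and_grads(state: ModelState, X: np.ndarray, x_context: np.ndarray, *,
                   l2_decay: float = 0.0, training: bool = False,
                   rng: np.random.Generator | None = None):
    """Mean negative log-likelihood over the batch plus the L2 decay on W,
    with analytic gradients for every parameter.

    The decay penalty ``l2_decay * sum(W**2)`` applies to the unmixing matrix
    only, never to the recurrent parameters.
    """
    cache = forward(state, X, x_context, training=training, rng=rng)
    B, T, D = cache["X"].shape
    cfg = state.config

    X_, S, H, sigma, z = cache["X"], cache["S"], cache["H"], cache["sigma"], cache["z"]
    th = np.tanh(z / 2.0)
    d_s = -th / sigma                      # d ll / d s
    d_mu = th / sigma                      # d ll / d mu
    d_sig = (z * th - 1.0) / sigma         # d ll / d sigma
    d_asig = d_sig * sigmoid(cache["a_sig"])

    g = {k: np.zeros_like(v) for k, v in state.params().items()}

    # heads
    g["W_mu"] = np.einsum("btd,bth->dh", d_mu, H)
    g["b_mu"] = d_mu.sum(axis=(0, 1))
    g["W_sigma"] = np.einsum("btd,bth->dh", d_asig, H)
    g["b_sigma"] = d_asig.sum(axis=(0, 1))

    # unmixing matrix: determinant term + source path
    g["W"] = B * T * np.linalg.inv(state.W).T + np.einsum("btd,bte->de", d_s, X_)

    # backprop through time
    head_dh = d_mu @ state.W_mu + d_asig @ state.W_sigma  # (B,T,H)
    inputs = cache["inputs"]
    carry = np.zeros((B, cfg.hidden))
    for t in range(T - 1, 0, -1):
        delta = (head_dh[:, t] + carry) * (1.0 - H[:, t] ** 2)
        g["U_R"] += delta.T @ H[:, t - 1]
        g["U_I"] += delta.T @ inputs[:, t - 1]
        g["b"] += delta.sum(axis=0)
        if cfg.rnn_input == "sources":
            g["W"] += (delta @ state.U_I).T @ X_[:, t - 1]
        carry = delta @ state.U_R

    # initial-state network
    dh0 = head_dh[:, 0] + carry
    ic = cache["init"]
    delta0 = dh0 * (1.0 - H[:, 0] ** 2)
    if ic["mode"] == "constant":
        g["h0"] = delta0.sum(axis=0)
    else:
        g["A3"] = delta0.T @ ic["z2d"]
        g["c3"] = delta0.sum(axis=0)
        du2 = (delta0 @ state.A3) * ic["m2"] * sigmoid(ic["u2"])
        g["A2"] = du2.T @ ic["z1d"]
        g["c2"] = du2.sum(axis=0)
        du1 = (du2 @ state.A2) * ic["m1"] * sigmoid(ic["u1"])
        g["A1"] = du1.T @ ic["x0"]
        g["c1"] = du1.sum(axis=0)

    # loss = mean(-ll) + l2 * ||W||^2
    scale = -1.0 / B
    grads = {k: scale * v for k, v in g.items()}
    grads["W"] = grads["W"] + 2.0 * l2_decay * state.W
    nll = -cache["ll"].mean()
    loss = nll + l2_decay * float(np.sum(state.W ** 2))
    return loss, grads, cache


# ---------------------------------------------------------------------------
# checkpoint I/O
# ---------------------------------------------------------------------------


def save_model(path, state: ModelState) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["config"] = state.config.to_json()
        f.create_dataset("W", data=state.W)
        grp_r = f.create_group("recurrent")
        for k in ("U_R", "U_I", "b"):
            grp_r.create_dataset(k, data=getattr(state, k))
        grp_h = f.create_group("heads")
        for k in ("W_mu", "b_mu", "W_sigma", "b_sigma"):
            grp_h.create_dataset(k, data=getattr(state, k))
        grp_i = f.create_group("init_net")
        for k in ("A1", "c1", "A2", "c2", "A3", "c3", "h0"):
            grp_i.create_dataset(k, data=getattr(state, k))


def load_model(path) -> ModelState:
    with h5py.File(path, "r") as f:
        cfg = ModelConfig.from_json(f.attrs["config"])
        kw = {"W": f["W"][()]}
        for k in ("U_R", "U_I", "b"):
            kw[k] = f["recurrent"][k][()]
        for k in ("W_mu", "b_mu", "W_sigma", "b_sigma"):
            kw[k] = f["heads"][k][()]
        for k in ("A1", "c1", "A2", "c2", "A3", "c3", "h0"):
            kw[k] = f["init_net"][k][()]
    return ModelState(config=cfg, **kw)
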