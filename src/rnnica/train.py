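"""Mini-batch maximum-likelihood training of the unmixing matrix and
recurrent parameters (RMSProp), plus full-sequence evaluation.

Defaults follow the reference configuration this package validates against:
500 epochs, learning rate 1e-4, batches of 100 windows, L2 decay 0.002 on the
unmixing matrix only, window 20 / stride 1, 100 hidden units, 20% dropout in
the initial-state network.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict

import numpy as np

from . import model as M
from .preprocess import ReducedDataset, window_segments, make_batches


@dataclass
class TrainConfig:
    epochs: int = 500
    learning_rate: float = 1e-4
    batch_size: int = 100
    l2_decay: float = 0.002
    window: int = 20
    stride: int = 1
    hidden: int = 100
    init_width: int = 100
    dropout: float = 0.2
    seed: int = 0
    rmsprop_decay: float = 0.9
    rmsprop_eps: float = 1e-8
    grad_clip: float | None = None
    checkpoint_every: int = 25
    rnn_input: str = "data"
    init_mode: str = "network"
    freeze: tuple = ()   # parameter names excluded from updates (e.g. to fit W only)

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.l2_decay < 0:
            raise ValueError("l2_decay must be non-negative")

    def to_dict(self):
        return asdict(self)


@dataclass
class TrainLog:
    epochs: list = field(default_factory=list)
    loss: list = field(default_factory=list)          # mean loss (NLL + penalty)
    nll: list = field(default_factory=list)           # mean negative log-likelihood
    penalty: list = field(default_factory=list)       # L2 decay term
    grad_norm: list = field(default_factory=list)
    wall_clock: list = field(default_factory=list)
    checkpoints: list = field(default_factory=list)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "epoch": self.epochs, "loss": self.loss, "nll": self.nll,
            "penalty": self.penalty, "grad_norm": self.grad_norm,
            "wall_clock": self.wall_clock,
        })


@dataclass
class SourceOutputs:
    """Full-sequence evaluation outputs for one subject.

    Arrays cover frames 1..T-1 of the subject's sequence (frame 0 is the
    reserved initial-state input), so sources, predictive parameters and
    hidden states are index-aligned.
    """

    sources: np.ndarray   # (T-1, D)
    mu: np.ndarray        # (T-1, D)
    sigma: np.ndarray     # (T-1, D)
    hidden: np.ndarray    # (T-1, H)
    frame_offset: int = 1


def loss(state: M.ModelState, frames: np.ndarray, context: np.ndarray,
         l2_decay: float = 0.0) -> float:
    """Mean negative log-likelihood of a batch of windows plus the L2 decay
    on the unmixing matrix (evaluation mode)."""
    if frames.shape[0] == 0:
        raise ValueError("empty batch")
    val, _, _ = M.loss_and_grads(state, frames, context, l2_decay=l2_decay)
    return val


def _rmsprop_update(state, grads, cache, cfg):
    gn2 = 0.0
    for k, g in grads.items():
        if k in cfg.freeze:
            continue
        if cfg.grad_clip is not None:
            g = np.clip(g, -cfg.grad_clip, cfg.grad_clip)
        cache[k] = cfg.rmsprop_decay * cache[k] + (1 - cfg.rmsprop_decay) * g * g
        step = cfg.learning_rate * g / (np.sqrt(cache[k]) + cfg.rmsprop_eps)
        arr = getattr(state, k)
        arr -= step
        gn2 += float(np.sum(g * g))
    return np.sqrt(gn2)


def fit(dataset: ReducedDataset, config: TrainConfig,
        init_state: M.ModelState | None = None, checkpoint_dir=None,
        progress: bool = False):
    """Run RMSProp maximum-likelihood training.

    Each epoch reshuffles the window set with a seeded generator; the final
    short batch is used, not dropped. Fully reproducible given the seed.
    Returns ``(final ModelState, best-by-loss ModelState, TrainLog)``.
    """
    mcfg = M.ModelConfig(dim=dataset.dim, hidden=config.hidden,
                         init_width=config.init_width, dropout=config.dropout,
                         rnn_input=config.rnn_input, init_mode=config.init_mode)
    state = init_state.copy() if init_state is not None else M.initialize(mcfg, seed=config.seed)
    windows = window_segments(dataset, config.window, config.stride)

    shuffle_rng = np.random.default_rng(config.seed + 1)
    dropout_rng = np.random.default_rng(config.seed + 2)
    opt_cache = {k: np.zeros_like(v) for k, v in state.params().items()}
    log = TrainLog()
    best_loss, best_state = np.inf, state.copy()
    t0 = time.time()

    for epoch in range(config.epochs):
        batches = make_batches(windows, config.batch_size, shuffle_rng)
        epoch_loss, epoch_nll, n_win, gns = 0.0, 0.0, 0, []
        for idx in batches:
            frames, context = windows.gather(idx)
            try:
                val, grads, cache = M.loss_and_grads(
                    state, frames, context, l2_decay=config.l2_decay,
                    training=True, rng=dropout_rng)
            except FloatingPointError:
                _dump_diagnostics(checkpoint_dir, best_state, log, epoch)
                raise
            if not np.isfinite(val):
                _dump_diagnostics(checkpoint_dir, best_state, log, epoch)
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            gns.append(_rmsprop_update(state, grads, opt_cache, config))
            b = len(idx)
            epoch_loss += val * b
            epoch_nll += -cache["ll"].mean() * b
            n_win += b
        pen = config.l2_decay * float(np.sum(state.W ** 2))
        log.epochs.append(epoch)
        log.loss.append(epoch_loss / n_win)
        log.nll.append(epoch_nll / n_win)
        log.penalty.append(pen)
        log.grad_norm.append(float(np.mean(gns)))
        log.wall_clock.append(time.time() - t0)
        if log.loss[-1] < best_loss:
            best_loss = log.loss[-1]
            best_state = state.copy()
        if checkpoint_dir is not None and (epoch + 1) % config.checkpoint_every == 0:
            import os
            path = os.path.join(str(checkpoint_dir), f"epoch_{epoch + 1:04d}.h5")
            M.save_model(path, state)
            log.checkpoints.append(path)
        if progress and (epoch % max(1, config.epochs // 20) == 0 or epoch == config.epochs - 1):
            print(f"epoch {epoch:4d}  loss {log.loss[-1]:.4f}", flush=True)
    return state, best_state, log


def _dump_diagnostics(checkpoint_dir, best_state, log, epoch):
    if checkpoint_dir is not None:
        import os
        M.save_model(os.path.join(str(checkpoint_dir), "last_finite.h5"), best_state)


def evaluate(dataset: ReducedDataset, state: M.ModelState) -> list:
    """Deterministic full-sequence forward pass per subject (dropout off).

    Frame 0 of each sequence serves as the initial-state input; outputs cover
    frames 1..T-1.
    """
    if dataset.dim != state.config.dim:
        raise ValueError(f"data dimension {dataset.dim} != model dimension {state.config.dim}")
    seqs = dataset.sequences
    context = seqs[:, 0, :]
    frames = seqs[:, 1:, :]
    cache = M.forward(state, frames, context, training=False)
    return [SourceOutputs(sources=cache["S"][n], mu=cache["mu"][n],
                          sigma=cache["sigma"][n], hidden=cache["H"][n])
            for n in range(seqs.shape[0])]
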