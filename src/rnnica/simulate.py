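"""Synthetic cohort and toy-mixture generators with ground truth.

Two generators:

* ``generate_cohort`` — a dynamic-connectivity state-simulation cohort:
  each subject follows a group-specific first-order Markov chain over a small
  set of discrete connectivity states; at each TR the neural signal is drawn
  with the covariance pattern of the active state (with AR(1) smoothing so
  the dynamics are learnable), then convolved with a per-subject-jittered
  double-gamma HRF, plus Gaussian observation noise.  Ground-truth state
  vectors, group labels and HRF parameters are retained.

* ``generate_linear_ica_toy`` — plain linear mixtures of temporally filtered
  heavy-tailed (logistic) sources with a known well-conditioned mixing
  matrix, for unmixing-recovery tests scored by the Amari index.

The default cohort scale mirrors the validation protocol this package is
built around: 47 components, 5 states, 480 time points at TR 2 s, two groups
of 500 subjects with per-group transition matrices. The per-group transition
and initial probabilities used in the original study were derived from
unpublished clinical fits and are not public; the defaults here are
documented stand-ins (strong self-transition, group-asymmetric off-diagonal
mass).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def default_transition_matrices(n_states: int):
    """Stand-in per-group transition matrices: 0.9 self-transition for both
    groups. Group 0 spreads the remaining mass uniformly (uniform stationary
    occupancy); group 1 directs it preferentially toward the low-index
    (weakly-coupled, low-variance) states, skewing its stationary occupancy
    toward them — the dwell asymmetry reported for clinical groups in
    dynamic-connectivity studies."""
    off = 0.1
    t0 = np.full((n_states, n_states), off / (n_states - 1))
    np.fill_diagonal(t0, 0.9)
    pref = np.exp(-1.2 * np.arange(n_states))  # preference for early states
    t1 = np.zeros((n_states, n_states))
    for i in range(n_states):
        w = pref.copy()
        w[i] = 0.0
        t1[i] = off * w / w.sum()
        t1[i, i] = 0.9
    return [t0, t1]


def default_initial_probs(n_states: int):
    """Group 0 starts uniformly; group 1 starts mostly in state 0."""
    p0 = np.full(n_states, 1.0 / n_states)
    p1 = np.full(n_states, 0.4 / (n_states - 1))
    p1[0] = 0.6
    return [p0, p1]


def default_state_patterns(n_components: int, n_states: int, seed: int = 12345):
    """Block-structured state covariance patterns.

    Components are split into one block per state; state k is the regime in
    which block k is "active": its components have elevated variance (2.0 vs
    a 0.4 baseline) and strong within-block correlation (0.7), with a weak
    negative coupling to the following block. States are therefore
    identifiable from the second-order statistics of the signal — both from
    which components co-fluctuate and from their instantaneous scale — which
    is what a dynamic-connectivity state means here.
    """
    rng = np.random.default_rng(seed)
    blocks = np.array_split(np.arange(n_components), n_states)
    active_var, base_var = 2.0, 0.4
    patterns = []
    for s in range(n_states):
        C = base_var * np.eye(n_components)
        act = blocks[s]
        nxt = blocks[(s + 1) % n_states]
        for i in act:
            for j in act:
                C[i, j] = active_var if i == j else 0.7 * active_var
        for i in act:
            for j in nxt:
                C[i, j] = C[j, i] = -0.3 * np.sqrt(active_var * base_var)
        # mild random loading jitter; PSD repair below
        A = rng.standard_normal((n_components, n_components)) * 0.05
        C = C + A @ A.T
        w, V = np.linalg.eigh((C + C.T) / 2.0)
        w = np.clip(w, 1e-6, None)
        patterns.append((V * w) @ V.T)
    return patterns


@dataclass
class SimConfig:
    n_components: int = 47
    n_states: int = 5
    n_timepoints: int = 480
    tr: float = 2.0
    group_sizes: tuple = (500, 500)
    transition_matrices: list = None
    initial_probs: list = None
    state_patterns: list = None
    hrf_jitter: float = 0.10          # uniform +-10% on each HRF parameter
    noise_sd: float = 0.2             # relative to unit signal SD
    ar_coeff: float = 0.5             # AR(1) smoothing of neural time courses
    seed: int = 0

    def __post_init__(self):
        if self.transition_matrices is None:
            self.transition_matrices = default_transition_matrices(self.n_states)
        if self.initial_probs is None:
            self.initial_probs = default_initial_probs(self.n_states)
        if self.state_patterns is None:
            self.state_patterns = default_state_patterns(self.n_components, self.n_states)
        for g, tm in enumerate(self.transition_matrices):
            tm = np.asarray(tm, dtype=float)
            if not np.allclose(tm.sum(axis=1), 1.0, atol=1e-12):
                raise ValueError(f"transition matrix for group {g} is not row-stochastic")
        if any(g < 1 for g in self.group_sizes):
            raise ValueError("group sizes must be >= 1")


@dataclass
class SimCohort:
    sequences: np.ndarray          # (N, T, C) observed time courses
    states: np.ndarray             # (N, T) ground-truth state vectors, 1..n_states
    group_labels: np.ndarray       # (N,)
    hrf_params: list = field(default_factory=list)
    mixing: np.ndarray | None = None
    tr: float = 2.0


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


def sample_state_sequence(transition, initial, T: int, rng) -> np.ndarray:
    """Length-T first-order Markov chain over states 1..K."""
    transition = np.asarray(transition, dtype=float)
    initial = np.asarray(initial, dtype=float)
    if not np.allclose(transition.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError("transition matrix rows must sum to 1")
    if not np.isclose(initial.sum(), 1.0, atol=1e-12) or np.any(initial < 0):
        raise ValueError("invalid initial distribution")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    K = transition.shape[0]
    states = np.empty(T, dtype=int)
    states[0] = rng.choice(K, p=initial)
    # draw all uniforms up front: reproducible and fast
    u = rng.random(T - 1)
    cum = np.cumsum(transition, axis=1)
    for t in range(1, T):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t - 1], side="right")
    return states + 1


def generate_neural_timecourses(states: np.ndarray, patterns: list, rng,
                                ar_coeff: float = 0.5) -> np.ndarray:
    """State-conditioned zero-mean draws with AR(1) temporal smoothing.

    The innovation at time t uses the covariance pattern of the active state;
    the AR(1) recursion y_t = a y_{t-1} + sqrt(1-a^2) e_t keeps the marginal
    covariance at the state pattern during long dwells.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    chols = []
    for k, P in enumerate(patterns):
        P = np.asarray(P, dtype=float)
        try:
            chols.append(np.linalg.cholesky(P + 1e-10 * np.eye(P.shape[0])))
        except np.linalg.LinAlgError as e:
            raise ValueError(f"state pattern {k + 1} is not positive semi-definite") from e
    T, C = len(states), patterns[0].shape[0]
    eps = rng.standard_normal((T, C))
    innov = np.empty((T, C))
    for k in range(len(patterns)):
        mask = states == k + 1
        if mask.any():
            innov[mask] = eps[mask] @ chols[k].T
    y = np.empty((T, C))
    y[0] = innov[0]
    a, s = ar_coeff, np.sqrt(1.0 - ar_coeff ** 2)
    for t in range(1, T):
        y[t] = a * y[t - 1] + s * innov[t]
    return y


def double_gamma_hrf(tr: float, delay: float = 6.0, undershoot_delay: float = 16.0,
                     dispersion: float = 1.0, undershoot_dispersion: float = 1.0,
                     ratio: float = 1.0 / 6.0, length: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at the TR grid, truncated at
    ``length`` seconds, peak normalized to 1."""
    if dispersion <= 0 or undershoot_dispersion <= 0:
        raise ValueError("HRF dispersions must be positive")
    if tr <= 0:
        raise ValueError("TR must be positive")
    t = np.arange(0, length + tr / 2, tr)

    def gpdf(x, shape, scale):
        x = np.maximum(x, 1e-12)
        return np.exp((shape - 1) * np.log(x) - x / scale
                      - gammaln(shape) - shape * np.log(scale))

    k1, th1 = delay / dispersion, dispersion
    k2, th2 = undershoot_delay / undershoot_dispersion, undershoot_dispersion
    h = gpdf(t, k1, th1) - ratio * gpdf(t, k2, th2)
    return h / np.max(np.abs(h))


def hrf_convolve(tc: np.ndarray, hrf_params: dict | None = None, tr: float = 2.0) -> np.ndarray:
    """Causal convolution with the double-gamma HRF; output length preserved."""
    tc = np.asarray(tc, dtype=float)
    kernel = double_gamma_hrf(tr, **(hrf_params or {}))
    if tc.ndim == 1:
        return np.convolve(tc, kernel)[: tc.shape[0]]
    from scipy.signal import fftconvolve
    return fftconvolve(tc, kernel[:, None], axes=0)[: tc.shape[0]]


# ---------------------------------------------------------------------------
# cohort / toy generators
# ---------------------------------------------------------------------------


def generate_cohort(config: SimConfig) -> SimCohort:
    """Full cohort: group-specific chains -> state-conditioned neural signal
    -> subject-jittered HRF -> additive Gaussian noise. Deterministic given
    ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    seqs, states_all, groups, hrfs = [], [], [], []
    base = {"delay": 6.0, "undershoot_delay": 16.0, "dispersion": 1.0,
            "undershoot_dispersion": 1.0, "ratio": 1.0 / 6.0}
    for g, size in enumerate(config.group_sizes):
        tm = config.transition_matrices[g]
        p0 = config.initial_probs[g]
        for _ in range(size):
            st = sample_state_sequence(tm, p0, config.n_timepoints, rng)
            neural = generate_neural_timecourses(st, config.state_patterns, rng,
                                                 ar_coeff=config.ar_coeff)
            jit = {k: v * (1.0 + config.hrf_jitter * rng.uniform(-1, 1))
                   for k, v in base.items()}
            bold = hrf_convolve(neural, jit, tr=config.tr)
            bold = bold + config.noise_sd * rng.standard_normal(bold.shape)
            seqs.append(bold)
            states_all.append(st)
            groups.append(g)
            hrfs.append(jit)
    return SimCohort(sequences=np.stack(seqs), states=np.stack(states_all),
                     group_labels=np.array(groups), hrf_params=hrfs, tr=config.tr)


def generate_linear_ica_toy(D: int, T: int, N: int, seed: int = 0, *,
                            ar_coeff: float = 0.5, noise_sd: float = 0.0,
                            cond_max: float = 20.0, return_sources: bool = False):
    """Linear mixtures of temporally filtered, heavy-tailed independent
    sources with a known mixing matrix.

    Sources are iid standard-logistic draws passed through an AR(1) filter
    (excess kurtosis stays positive); observations are ``x_t = M s_t`` with a
    random mixing matrix of condition number below ``cond_max``.

    Returns ``(sequences (N,T,D), M_true)``.
    """
    if D < 2:
        raise ValueError("need at least 2 components")
    rng = np.random.default_rng(seed)
    # well-conditioned random mixing via SVD surgery
    A = rng.standard_normal((D, D))
    U, _, Vt = np.linalg.svd(A)
    svals = np.linspace(1.0, max(cond_max / 4.0, 2.0), D)
    M = U @ np.diag(svals) @ Vt
    a, s = ar_coeff, np.sqrt(1.0 - ar_coeff ** 2)
    seqs = np.empty((N, T, D))
    sources = np.empty((N, T, D))
    for n in range(N):
        innov = rng.logistic(0.0, np.sqrt(3.0) / np.pi, size=(T, D))  # unit variance
        src = np.empty((T, D))
        src[0] = innov[0]
        for t in range(1, T):
            src[t] = a * src[t - 1] + s * innov[t]
        x = src @ M.T
        if noise_sd > 0:
            x = x + noise_sd * rng.standard_normal(x.shape)
        seqs[n] = x
        sources[n] = src
    if return_sources:
        return seqs, M, sources
    return seqs, M


def amari_index(P: np.ndarray) -> float:
    """Amari permutation error of a (typically W @ M_true) matrix.

    Row and column terms sum(|p|/max|p|) - 1, averaged over the 2D rows and
    columns: 0 iff P is a scaled permutation, (D-1) for the all-ones matrix
    (3.0 at D=4). Invariant to row/column rescaling and permutation.
    """
    P = np.abs(np.asarray(P, dtype=float))
    D = P.shape[0]
    row_max = P.max(axis=1)
    col_max = P.max(axis=0)
    if np.any(row_max == 0) or np.any(col_max == 0):
        raise ValueError("matrix has an all-zero row or column")
    rows = (P / row_max[:, None]).sum(axis=1) - 1.0
    cols = (P / col_max[None, :]).sum(axis=0) - 1.0
    return float((rows.sum() + cols.sum()) / (2.0 * D))
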