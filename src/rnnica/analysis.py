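"""Post-hoc analytics: spatial maps, functional network connectivity with
community structure, stimulus statistics, Jacobian-based directed
connectivity, and state-tracking diagnostics.

Directed connectivity is read off the trained model itself: the Jacobian of
the predicted next-step mean of each component with respect to every
component's current source value,

    d mu_{i,t} / d s_{j,t-1} = [W_mu diag(1 - h_t^2) U_I M]_{ij},

evaluated analytically along each subject's sequence (only next-time terms
are considered).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import model as M
from .simulate import hrf_convolve
from .train import SourceOutputs


# ---------------------------------------------------------------------------
# spatial maps
# ---------------------------------------------------------------------------


@dataclass
class SpatialMapSet:
    """Back-reconstructed voxel maps; raw values are retained so thresholds
    always refer to the unthresholded statistics."""

    maps: np.ndarray                      # (V, D) raw values
    flips: np.ndarray = None              # +-1 per component
    threshold: float = 0.0                # in SD units; 0 = unthresholded
    labels: list = field(default_factory=list)

    def __post_init__(self):
        if self.flips is None:
            self.flips = np.ones(self.maps.shape[1])
        if not self.labels:
            self.labels = [f"IC{i + 1}" for i in range(self.maps.shape[1])]

    def thresholded(self) -> np.ndarray:
        """Voxels within ``threshold`` SDs of each component's mean set to 0
        (statistics computed on the raw map)."""
        if self.threshold <= 0:
            return self.maps.copy()
        mean = self.maps.mean(axis=0)
        sd = self.maps.std(axis=0, ddof=1)
        out = self.maps.copy()
        zero_sd = sd == 0
        if zero_sd.any():
            warnings.warn(f"{int(zero_sd.sum())} constant maps thresholded to all zeros")
            sd = np.where(zero_sd, 1.0, sd)
        out[np.abs(self.maps - mean) < self.threshold * sd] = 0.0
        out[:, zero_sd] = 0.0
        return out


def back_reconstruct_maps(W: np.ndarray, spatial_basis: np.ndarray) -> SpatialMapSet:
    """Map model components back to voxel space: map_i = spatial_basis @ m_i
    where m_i is column i of the mixing matrix M = W^-1."""
    if spatial_basis.shape[1] != W.shape[0]:
        raise ValueError("spatial basis / unmixing dimension mismatch")
    mix = M.mixing_matrix(W)
    return SpatialMapSet(maps=spatial_basis @ mix)


def sign_flip_by_skew(mapset: SpatialMapSet, outputs: list | None = None):
    """Negate any component whose voxel-value skewness is negative, jointly
    with its source and predicted-mean time courses; exactly-zero skew is
    left untouched. Involutive: applying twice is the identity."""
    skews = stats.skew(mapset.maps, axis=0, bias=False)
    flips = np.where(skews < 0, -1.0, 1.0)
    new_maps = mapset.maps * flips
    flipped_outputs = None
    if outputs is not None:
        flipped_outputs = [
            SourceOutputs(sources=o.sources * flips, mu=o.mu * flips,
                          sigma=o.sigma.copy(), hidden=o.hidden.copy(),
                          frame_offset=o.frame_offset)
            for o in outputs
        ]
    new_set = SpatialMapSet(maps=new_maps, flips=mapset.flips * flips,
                            threshold=mapset.threshold, labels=list(mapset.labels))
    return (new_set, flipped_outputs) if outputs is not None else (new_set, None)


def threshold_maps(mapset: SpatialMapSet, z: float = 2.0) -> SpatialMapSet:
    """Set the reporting threshold (SD units) on a map set; composition of
    thresholds keeps only the strictest one."""
    if z < 0:
        raise ValueError("threshold must be non-negative")
    return SpatialMapSet(maps=mapset.maps.copy(), flips=mapset.flips.copy(),
                         threshold=max(z, mapset.threshold), labels=list(mapset.labels))


# ---------------------------------------------------------------------------
# FNC and communities
# ---------------------------------------------------------------------------


@dataclass
class FNCMatrix:
    matrix: np.ndarray          # (D, D) subject-averaged cross-correlations
    communities: np.ndarray = None


def fnc_matrix(outputs: list) -> FNCMatrix:
    """Subject-averaged Pearson cross-correlation of source time courses."""
    if not outputs:
        raise ValueError("need at least one subject")
    mats = []
    for o in outputs:
        src = o.sources
        sd = src.std(axis=0)
        if np.any(sd == 0):
            warnings.warn("constant component time course: correlation row set to NaN")
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(src.T)
        c[np.diag_indices_from(c)] = 1.0
        mats.append(c)
    avg = np.nanmean(np.stack(mats), axis=0) if len(mats) > 1 else mats[0]
    avg = (avg + avg.T) / 2.0
    return FNCMatrix(matrix=avg)


def community_grouping(similarity: np.ndarray, seed: int = 0) -> np.ndarray:
    """Louvain modularity communities on the graph whose edge weights are the
    non-negative part of the similarity matrix (self-loops excluded); labels
    are canonicalized by each community's smallest member index."""
    S = np.asarray(similarity, dtype=float)
    if not np.allclose(S, S.T, atol=1e-8, equal_nan=True):
        raise ValueError("similarity matrix must be symmetric")
    D = S.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(D))
    for i in range(D):
        for j in range(i + 1, D):
            w = S[i, j]
            if np.isfinite(w) and w > 0:
                G.add_edge(i, j, weight=float(w))
    comms = nx.community.louvain_communities(G, weight="weight", seed=seed)
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    labels = np.empty(D, dtype=int)
    for lab, members in enumerate(comms):
        for m in members:
            labels[m] = lab
    return labels


# ---------------------------------------------------------------------------
# stimulus statistics
# ---------------------------------------------------------------------------


@dataclass
class StimulusStats:
    betas: np.ndarray          # (N, D, S signals, C regressors)
    signal_names: tuple        # ("s", "mu", "sigma")
    regressor_names: list
    t_one: np.ndarray          # (D, S, C) one-sample t
    p_one: np.ndarray
    t_group: np.ndarray = None  # (D, S, C) two-sample t between groups
    p_group: np.ndarray = None
    threshold: float = 1e-7


def _design_matrix(design: np.ndarray, tr: float, convolve: bool):
    design = np.atleast_2d(np.asarray(design, dtype=float))
    if design.shape[0] < design.shape[1]:
        design = design.T
    X = hrf_convolve(design, tr=tr) if convolve else design
    full = np.column_stack([np.ones(X.shape[0]), X])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        grams = np.abs(np.corrcoef(full[:, 1:].T))
        np.fill_diagonal(grams, 0)
        bad = np.argwhere(grams > 1 - 1e-10)
        raise ValueError(f"collinear design columns: {sorted({tuple(b) for b in bad})}")
    return full


def _ols_betas(Y: np.ndarray, Xfull: np.ndarray) -> np.ndarray:
    """OLS of every column of Y on the full design; intercept dropped from
    the returned betas."""
    coef, *_ = np.linalg.lstsq(Xfull, Y, rcond=None)
    return coef[1:]


def stimulus_regression(outputs: list, design: np.ndarray, groups=None, *,
                        tr: float = 2.0, convolve_hrf: bool = True,
                        regressor_names=None, threshold: float = 1e-7) -> StimulusStats:
    """Per subject/component, OLS of the sources, predicted means and
    predicted scales on the stimulus regressors (plus intercept); one-sample
    t-tests of each beta across subjects and, if groups are given, two-sample
    t-tests between groups.

    ``design`` has one column per condition on the full TR grid; it is
    trimmed to the frames the outputs cover and, by default, convolved with
    the canonical HRF first.
    """
    Xfull = _design_matrix(design, tr, convolve_hrf)
    off = outputs[0].frame_offset
    T = outputs[0].sources.shape[0]
    if Xfull.shape[0] < off + T:
        raise ValueError(f"design length {Xfull.shape[0]} shorter than sequence {off + T}")
    Xfull = Xfull[off:off + T]
    C = Xfull.shape[1] - 1
    N, D = len(outputs), outputs[0].sources.shape[1]
    signals = ("s", "mu", "sigma")
    betas = np.empty((N, D, 3, C))
    for n, o in enumerate(outputs):
        for si, sig in enumerate((o.sources, o.mu, o.sigma)):
            betas[n, :, si, :] = _ols_betas(sig, Xfull).T
    t_one, p_one = stats.ttest_1samp(betas, 0.0, axis=0)
    t_group = p_group = None
    if groups is not None:
        groups = np.asarray(groups)
        uniq = np.unique(groups)
        if len(uniq) != 2:
            raise ValueError("group tests need exactly 2 groups")
        g0, g1 = betas[groups == uniq[0]], betas[groups == uniq[1]]
        if min(len(g0), len(g1)) < 2:
            raise ValueError("need >= 2 subjects per group")
        t_group, p_group = stats.ttest_ind(g0, g1, axis=0)
    names = regressor_names or [f"cond{c + 1}" for c in range(C)]
    return StimulusStats(betas=betas, signal_names=signals, regressor_names=names,
                         t_one=t_one, p_one=p_one, t_group=t_group, p_group=p_group,
                         threshold=threshold)


# ---------------------------------------------------------------------------
# Jacobian directed connectivity
# ---------------------------------------------------------------------------


@dataclass
class DirectedConnectivity:
    averaged_abs: np.ndarray    # (D, D) mean |J| over time and subjects
    nu_bar: np.ndarray          # (D, D) signed time/subject average; column j = nu_bar_j
    rho: np.ndarray             # (D, D) Pearson similarity between nu_bar columns
    communities: np.ndarray = None


def next_step_jacobian(state: M.ModelState, X: np.ndarray) -> np.ndarray:
    """Next-time Jacobians along a sequence, by exact differentiation of the
    forward pass.

    ``X`` is one subject's full (T, D) sequence (frame 0 is the initial-state
    input). Entry ``J[k, i, j]`` is d mu_{i} at frame k+2 w.r.t. source j at
    frame k+1, i.e. the next-step influence of component j on component i.
    Since h_t = tanh(U_R h_{t-1} + U_I x_{t-1} + b) and mu_t = W_mu h_t, the
    exact chain rule gives J_t = W_mu diag(1 - h_t^2) U_I M (the M factor
    converts d/dx to d/ds; it is absent when the recurrence consumes sources
    directly).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 frames")
    cache = M.forward(state, X[None, 1:], X[None, 0])
    H = cache["H"][0]                       # (T-1, hidden)
    sens = 1.0 - H[1:] ** 2                 # recurrence applied for eval steps >= 1
    J = np.einsum("ih,th,hj->tij", state.W_mu, sens, state.U_I)
    if state.config.rnn_input != "sources":
        J = J @ M.mixing_matrix(state.W)
    return J


def connectivity_summary(jacobians: list, seed: int = 0) -> DirectedConnectivity:
    """Aggregate per-subject Jacobian stacks into the averaged |J| matrix,
    the signed time-averages nu_bar, their Pearson similarity rho, and
    Louvain communities of the non-negative part of rho."""
    if not jacobians:
        raise ValueError("need at least one subject")
    stack = np.concatenate([np.asarray(j) for j in jacobians], axis=0)  # (sum_T, D, D)
    averaged_abs = np.abs(stack).mean(axis=0)
    nu_bar = stack.mean(axis=0)
    sd = nu_bar.std(axis=0)
    D = nu_bar.shape[0]
    rho = np.full((D, D), np.nan)
    ok = sd > 0
    if ok.any():
        with np.errstate(invalid="ignore"):
            rho_ok = np.corrcoef(nu_bar[:, ok].T)
        rho[np.ix_(ok, ok)] = rho_ok
    if (~ok).any():
        warnings.warn("zero-variance nu_bar column(s): rho entries set to NaN")
    np.fill_diagonal(rho, 1.0)
    sim = np.where(np.isfinite(rho), rho, 0.0)
    comms = community_grouping(np.maximum(sim, 0.0), seed=seed)
    return DirectedConnectivity(averaged_abs=averaged_abs, nu_bar=nu_bar,
                                rho=rho, communities=comms)


def export_graphml(conn: DirectedConnectivity, path, labels=None, *,
                   weight_threshold: float = 0.0) -> None:
    """Write the directed-connectivity graph (edges weighted by the averaged
    |Jacobian|, nodes annotated with community labels) as GraphML."""
    D = conn.averaged_abs.shape[0]
    labels = labels or [f"IC{i + 1}" for i in range(D)]
    G = nx.DiGraph()
    for i in range(D):
        G.add_node(labels[i], community=int(conn.communities[i])
                   if conn.communities is not None else 0)
    for i in range(D):
        for j in range(D):
            if i != j and conn.averaged_abs[i, j] > weight_threshold:
                # edge j -> i: influence of component j on i's next-step mean
                G.add_edge(labels[j], labels[i],
                           weight=float(conn.averaged_abs[i, j]))
    nx.write_graphml(G, str(path))


def jacobian_stimulus_tests(jacobians: list, design: np.ndarray, groups=None, *,
                            tr: float = 2.0, convolve_hrf: bool = True,
                            frame_offset: int = 2):
    """Treat every next-step Jacobian edge (i, j) as a time course and regress
    it on the stimulus design per subject; one-sample t-tests across subjects
    and two-sample t-tests between groups, per edge and regressor.

    Returns ``(betas (N,D,D,C), p_one (D,D,C), p_group (D,D,C) or None)``.
    """
    Xfull = _design_matrix(design, tr, convolve_hrf)
    Tj = np.asarray(jacobians[0]).shape[0]
    if Xfull.shape[0] < frame_offset + Tj:
        raise ValueError("design shorter than Jacobian time courses")
    Xfull = Xfull[frame_offset:frame_offset + Tj]
    C = Xfull.shape[1] - 1
    N = len(jacobians)
    D = np.asarray(jacobians[0]).shape[1]
    betas = np.empty((N, D, D, C))
    for n, J in enumerate(jacobians):
        flat = np.asarray(J).reshape(Tj, D * D)
        betas[n] = _ols_betas(flat, Xfull).T.reshape(D, D, C)
    _, p_one = stats.ttest_1samp(betas, 0.0, axis=0)
    p_group = None
    if groups is not None:
        groups = np.asarray(groups)
        uniq = np.unique(groups)
        _, p_group = stats.ttest_ind(betas[groups == uniq[0]],
                                     betas[groups == uniq[1]], axis=0)
    return betas, p_one, p_group


# ---------------------------------------------------------------------------
# state tracking
# ---------------------------------------------------------------------------


def resample_states(state_vector: np.ndarray, epoch_length: float, tr: float,
                    n_timepoints: int) -> np.ndarray:
    """Nearest-neighbour resampling of an epoch-based state vector (e.g.
    30 s sleep-staging epochs) onto the TR grid."""
    state_vector = np.asarray(state_vector)
    idx = np.minimum((np.arange(n_timepoints) * tr / epoch_length).astype(int),
                     len(state_vector) - 1)
    return state_vector[idx]


def state_correlation(traces: np.ndarray, state_vector: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column of ``traces`` with the numeric
    state vector; flat (zero-variance) traces yield NaN, never 0."""
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if traces.shape[0] != len(state_vector):
        raise ValueError(f"trace length {traces.shape[0]} != state vector length {len(state_vector)}")
    sv = np.asarray(state_vector, dtype=float)
    sv_c = sv - sv.mean()
    sv_sd = sv_c.std()
    tc = traces - traces.mean(axis=0)
    sd = tc.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (tc * sv_c[:, None]).mean(axis=0) / (sd * sv_sd)
    r[sd == 0] = np.nan
    if sv_sd == 0:
        r[:] = np.nan
    return r


def state_level_statistics(hidden: np.ndarray, state_vector: np.ndarray, *,
                           alpha: float = 0.05):
    """Per-state absolute mean and SD of hidden activity with omnibus and
    pairwise tests.

    For each time point the absolute mean and the SD of hidden activity
    across units are computed; these per-timepoint values are grouped by
    state, compared across states with one-way ANOVA, and pairwise with
    Bonferroni-corrected t-tests. States with fewer than 2 time points are
    excluded with a warning.
    """
    hidden = np.asarray(hidden, dtype=float)
    sv = np.asarray(state_vector)
    if hidden.shape[0] != len(sv):
        raise ValueError("hidden activity and state vector lengths differ")
    abs_mean_t = np.abs(hidden).mean(axis=1)
    sd_t = hidden.std(axis=1)
    states = [s for s in np.unique(sv) if (sv == s).sum() >= 2]
    dropped = set(np.unique(sv)) - set(states)
    if dropped:
        warnings.warn(f"states with < 2 samples excluded: {sorted(dropped)}")
    if len(states) < 2:
        raise ValueError("need at least 2 states with >= 2 samples")
    groups_abs = [abs_mean_t[sv == s] for s in states]
    groups_sd = [sd_t[sv == s] for s in states]
    res = {
        "states": states,
        "abs_mean": np.array([g.mean() for g in groups_abs]),
        "sd": np.array([g.mean() for g in groups_sd]),
        "anova_p_abs_mean": stats.f_oneway(*groups_abs).pvalue,
        "anova_p_sd": stats.f_oneway(*groups_sd).pvalue,
    }
    n_pairs = len(states) * (len(states) - 1) // 2
    pairwise = {}
    for a in range(len(states)):
        for b in range(a + 1, len(states)):
            p_abs = stats.ttest_ind(groups_abs[a], groups_abs[b]).pvalue
            p_sd = stats.ttest_ind(groups_sd[a], groups_sd[b]).pvalue
            pairwise[(states[a], states[b])] = {
                "p_abs_mean": min(1.0, p_abs * n_pairs),   # Bonferroni
                "p_sd": min(1.0, p_sd * n_pairs),
            }
    res["pairwise"] = pairwise
    return res


def group_difference_screen(values: np.ndarray, groups: np.ndarray, *,
                            fdr_q: float = 0.001):
    """Unit-wise two-sample t-test of per-subject values between two groups
    with Benjamini-Hochberg screening.

    ``values`` is (subjects, units), e.g. per-subject correlations of each
    hidden unit to the ground-truth state vector. NaN units (flat traces) are
    excluded from testing. Returns a dict with t, p, -log10(p), and the BH
    rejection mask at ``fdr_q``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise ValueError("need exactly 2 groups")
    ok = ~np.any(np.isnan(values), axis=0)
    t = np.full(values.shape[1], np.nan)
    p = np.full(values.shape[1], np.nan)
    tt = stats.ttest_ind(values[groups == uniq[0]][:, ok],
                         values[groups == uniq[1]][:, ok], axis=0)
    t[ok], p[ok] = tt.statistic, tt.pvalue
    rejected = np.zeros(values.shape[1], dtype=bool)
    if ok.any():
        rejected[ok] = multipletests(p[ok], alpha=fdr_q, method="fdr_bh")[0]
    with np.errstate(divide="ignore"):
        neglog = -np.log10(p)
    return {"t": t, "p": p, "neglog10_p": neglog, "rejected": rejected}
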