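# Methods

## Model

`rnnica` performs blind source separation of multivariate time series under a
conditional-independence assumption. The observed (dimensionality-reduced)
data frame at time `t` is `x_t ∈ R^D`; a single square unmixing matrix `W`,
shared across subjects and time, maps data to sources `s_t = W x_t`. Sources
are modeled as conditionally independent across components given the sequence
history, with a factorized logistic density whose per-step location `μ_t` and
scale `σ_t` are read out linearly from the hidden state of a vanilla tanh
recurrent network driven by the previous data frames. The sequence
log-likelihood follows from the change of variables through the linear map:
`T log|det W|` plus the sum of logistic log-densities of the sources under
their predictive parameters. The logistic choice keeps the source prior
heavy-tailed (excess kurtosis 1.2), which is what makes the factorization an
independence-seeking objective; in the limit of constant predictive
parameters the objective *is* static maximum-likelihood ICA, equivalent to
infomax with a logistic prior (verified in the tests against an independent
natural-gradient infomax implementation).

Assumptions worth stating plainly: generation is noiseless (sources have the
same dimension as the reduced data and the map is invertible), `W` is square
so the determinant and inverse are tractable, and one parameterization is
shared by all subjects — inter-subject variability is carried by the time
courses and the predictive distributions, not by subject-specific maps.

### Windows and the first frame

Training operates on sliding windows. Each window reserves the frame
immediately preceding it: a two-layer softplus feed-forward network (100
units per layer, 20% dropout in training mode, tanh output) maps that context
frame to the hidden state that generates the window's first frame. Each
window also carries one following target frame — the last prediction the
recurrence makes. A sequence of `T` frames therefore yields `T - w - 1`
stride-1 windows of size `w`; at the reference setting (249 frames, `w` = 20)
that is 228 windows. A sliding count without the two reserved frames would
give 230; the convention here is the mechanistically sensible rule that
reproduces the reference count, and is applied uniformly.

### Numerical choices

- `σ` is produced by a softplus readout plus a floor of 1e-4. A plain linear
  scale readout can go negative, for which the density is undefined;
  softplus is the minimal smooth repair. Both output heads carry biases.
- `log|det W|` is computed by sign-aware LU decomposition (`slogdet`), never
  by taking `log(det)`.
- The logistic log-density is evaluated as `-z - 2·log1p(exp(-z)) - log σ`
  through log-add-exp, stable to standardized residuals of ~1e3.
- All gradients are analytic (backpropagation through time, hand-derived) and
  are checked against central finite differences at relative error < 1e-4;
  the whole package is NumPy in float64.
- Weight initialization: orthogonal recurrent matrix, scaled-uniform input
  and head weights, `W` = identity + N(0, 0.01²) noise, zero biases.
- Training uses RMSProp (decay 0.9, epsilon 1e-8 — unremarkable defaults),
  learning rate 1e-4, batches of 100 windows, 500 epochs, and an L2 decay
  `λ Σ W_ij²` with λ = 0.002 applied to the unmixing matrix only. The final
  short batch of each epoch is used, not dropped. Seeded shuffling makes runs
  bitwise reproducible.
- The recurrence consumes the *data* frames `x_{t-1}` (a config flag switches
  to source inputs `s_{t-1}`, default off; with source inputs the unmixing
  matrix acquires an extra gradient path, which is implemented).

## Preprocessing

For voxel-level input: mask voxels whose mean over subjects and time falls
below the overall mean of the mean image (the threshold is the scalar mean of
the mean image); divide each voxel by its sample SD (ddof 1, no recentering);
remove a 4th-degree polynomial trend over the time index; PCA on the
subject-concatenated matrix, keeping the top `k` spatial directions *without
whitening* (component variances are not equalized); remove each component
time course's per-subject mean. Zero-variance voxels are dropped with a
warning. The sign of each principal direction is fixed so its
largest-magnitude weight is positive, for determinism.

## Analytics

- **Spatial maps**: component `i`'s map is `spatial_basis · m_i` with `m_i`
  the i-th column of `M = W⁻¹`. Components with negative voxel-value skewness
  (adjusted Fisher–Pearson estimator) are sign-flipped jointly with their
  source and `μ` time courses; maps are reported thresholded at 2 SD
  (statistics always computed on the raw map, so composed thresholds keep the
  strictest one).
- **FNC**: subject-averaged Pearson cross-correlation of source time courses.
- **Communities**: Louvain modularity on the graph weighted by the
  non-negative part of the similarity matrix (negative similarities dropped,
  resolution 1, fixed seed), labels canonicalized by smallest member index.
- **Directed connectivity**: the next-step Jacobian
  `∂μ_{i,t}/∂s_{j,t-1} = [W_μ diag(1-h_t²) U_I M]_{ij}`, evaluated
  analytically along each subject's sequence (only next-time terms). Reported
  as the time/subject average of `|J|`; component grouping uses the Pearson
  similarity of the signed time-averaged influence columns.
- **Stimulus statistics**: per subject and component, OLS of the sources,
  `μ`, and `σ` on the stimulus regressors plus intercept; one-sample t-tests
  of the betas across subjects and two-sample t-tests between groups.
  Stimulus event trains are convolved with the canonical double-gamma HRF
  before regression by default (flag to disable; whether the original
  analyses used convolved regressors is not documented). The same regression
  applied to each Jacobian edge's time course gives edge-level task and group
  statistics.
- **State tracking**: Pearson correlation of each hidden unit / `σ` / `s` /
  `μ` trace with a numeric per-frame state vector; flat traces give missing
  values, never 0. Epoch-based state vectors (e.g. 30-s sleep-staging epochs)
  are resampled to the TR grid by nearest neighbour and treated as ordinal
  integers. Per-state summaries of hidden activity (absolute mean and SD per
  time point, grouped by state) are compared by one-way ANOVA with
  Bonferroni-corrected pairwise t-tests. Group screens over units use
  two-sample t-tests on Fisher-z-transformed correlations with
  Benjamini–Hochberg control (q = 0.001 by default); Fisher's z is the
  standard variance-stabilizer for comparing correlation distributions.

## Synthetic cohort generator

The generator emulates a dynamic-connectivity study: each subject follows a
group-specific first-order Markov chain over `K` discrete connectivity
states; the neural signal at each TR is drawn with the covariance pattern of
the active state, AR(1)-smoothed (coefficient 0.5, innovation-scaled so the
stationary covariance equals the pattern) so the dynamics are learnable;
convolved with a per-subject double-gamma HRF (delay 6 s, undershoot delay
16 s, dispersions 1 s, undershoot ratio 1/6, each jittered ±10% per subject);
plus Gaussian observation noise (SD 0.2 against unit signal). Defaults: 47
components, 5 states, 480 time points at TR 2 s, two groups of 500.

The per-group transition and initial-state probabilities of the study this
emulates came from unpublished clinical fits and are not public; the defaults
here are **stand-ins**: both groups have 0.9 self-transition; group 0 spreads
the remaining mass uniformly (uniform stationary occupancy ≈ 0.2 each), while
group 1 directs it preferentially toward the low-index states (stationary
occupancy ≈ 0.46/0.36/0.13/0.04/0.01) — the dwell asymmetry reported for
clinical groups in dynamic-connectivity work. The state covariance patterns
are likewise constructed, not fitted: components are split into one block per
state, and state `k` elevates block `k`'s variance (2.0 vs 0.4 baseline) with
strong within-block correlation (0.7) and weak negative coupling to the next
block. This makes states identifiable from second-order statistics — which is
what a connectivity "state" means, and the property the validation protocol
probes. A plain linear-mixture toy (logistic sources, AR(1) filter, random
mixing with condition number < 20) supports unmixing-recovery tests scored by
the Amari index (normalized by 2D; 0 for scaled permutations, D-1 for the
all-ones matrix).

What the generator does *not* emulate: voxel-level spatial structure
(component-space only, with an optional random spatial basis), scanner drift
and motion, event-related task structure inside the neural signal, and any
bit-level compatibility with external simulation toolboxes. Passing the
synthetic protocol therefore shows that the estimator recovers mixing
matrices, tracks latent state dynamics, and calibrates its statistics under
the stated generative assumptions — not that it does so under real-scanner
artifacts.

## Problem sizes used in the shipped validation

The full-scale protocol (1,000 subjects × 480 frames × 47 components, 500
epochs) is supported but the shipped tests and the acceptance script run a
reduced protocol chosen to keep a complete validation run in the tens of
minutes on one CPU: unmixing recovery on D=8, T=200, N=100 mixtures (learning
rate 2e-4 and 16 hidden units for this small instance; 200 epochs); the
cohort protocol at 10 components, 240 frames, 2 groups × (50 train + 25
test), 100 hidden units, 500 epochs in the test suite (300 in the acceptance
script) with stride-2 windows — overlapping stride-1 windows are largely
redundant at this scale; and a 40-subject demo pipeline. At this scale the
scale-factor (σ) group-difference pattern re-identifies across train/test
(top-5 overlap ≥ 3) and hidden-unit rejections reproduce in train with
attenuated test strength; the precise top-5 membership among the 100
redundant hidden units is rank-unstable at 25 test subjects per group, which
is a sample-size limitation of the reduced protocol, not of the estimator.

## Known limitations

- Vanilla tanh recurrence only: no gated units, no deep or dilated
  architectures, no stochastic latent states.
- Square `W` only; over/under-complete separation is out of scope.
- The Jacobian analysis is restricted to next-time terms `t' = t-1`; the
  machinery extends to longer lags but none are computed.
- Anatomical labeling of spatial maps is manual and out of scope.
- The per-epoch cost is dominated by dense BPTT in NumPy; it is adequate for
  hundreds of subjects at reduced dimension, not for voxel-space models.
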