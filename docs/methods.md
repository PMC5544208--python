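# Methods

## Problem setting

In a rapid event-related fMRI experiment, stimuli from two classes are
presented every few seconds with jittered fixation intervals, so the
hemodynamic response to each trial overlaps the responses to its
neighbours. Classifying the class of a *single* trial (or a small set of
trials) from such data is hard: the BOLD spatial pattern at any time
point mixes several events, trial-to-trial amplitudes vary strongly, and
the number of voxels far exceeds the number of scans. `mvbdecode`
implements a decoding framework for this setting: many trials with known
labels are used to build a multivariate Bayesian (MVB) model of the
voxel time series, and the label of the unknown trial(s) is inferred by
Bayesian model comparison.

## The two-level decoding model

Let `Y` be the M x N matrix of voxel time series inside a feature mask,
`G` a confound matrix (intercept plus discrete-cosine drift terms), and
`R = orth(I - G G+)^t` the residual-forming matrix whose orthonormal
rows span the complement of the confound space. A label hypothesis for
the unknown trials yields a design matrix `X` (one HRF-convolved
regressor per class) and, through the discriminative contrast
`c = (+1, -1)`, a target variable `X c`. After confound removal the
model is

    v = R X c = L eta + zeta,          L = R Y,
    zeta ~ N(0, exp(lam_0) R V R'),    V = AR(1) serial correlations,
    eta  ~ N(0, Sigma_eta),            Sigma_eta = sum_k exp(lam_k) I^(k),

so the design-derived target is regressed *on the data* through voxel
weights `beta = U eta` with `U = I` (the sparse spatial constraint: each
pattern is a voxel). The `I^(k)` are diagonal 0/1 covariance components
over patterns; expressing `Sigma_eta` as a small sum of scaled
indicators is what makes the otherwise ill-posed estimation tractable:
only the `m + 1` log-scales `lam` are estimated.

### Free energy

Hyperparameters maximize the Laplace free energy

    F = -1/2 [ v' S(lam)^-1 v + ln|S(lam)| + w ln 2pi ]
        -1/2 [ (lam - pi)' Pi (lam - pi) - ln|Pi S_lam| ],

with `S(lam) = sum_k exp(lam_k) Q_k`, `Q = {R V R', L I^(k) L', ...}`,
`w = rank(R)` the residual dimension, hyperprior `N(pi, Pi^-1)`, and
`S_lam` the posterior covariance of `lam` (inverse curvature at the
mode). F is both the optimization objective and the approximation to
the log model evidence used for classification.

### Optimization

Fisher scoring on `lam` with step-halving: a step is accepted only if F
does not decrease, so the free-energy trace is non-decreasing by
construction; optimization stops when the improvement falls below `tol`
(default 1e-2) or after `max_iter` (64) iterations. For problems with at
most two hyperparameters the result is polished with a Nelder-Mead local
search on the same objective, which makes the optimum coincide with an
exhaustive grid scan to well under 0.01 free-energy units. Two
numerically equivalent evaluation paths exist: a dense one over explicit
`Q_k` (used when voxels outnumber scans and as the reference in tests)
and a Woodbury path that works entirely in pattern space through
`G = L'C^-1 L` (used everywhere else; the two agree to ~1e-12 and are
cross-checked in the test suite). Hyperparameters are clamped to
[-32, 32] (log scale) to keep exponentials in a usable dynamic range;
degenerate noise-free problems otherwise push the noise log-variance to
minus infinity.

### Sparse empirical prior

How exactly a sparse prior's covariance components should be carved out
of thousands of voxels is a genuinely open design choice; this package
uses a simple declared scheme. Patterns are ranked by the magnitude of their regularized minimum-norm
weight `|L'(L L' + eps I)^-1 v|` with `eps = 1e-6 tr(L L')`, and
component k covers the top `ceil(p / 2^(k-1))` patterns (nested dyadic
subsets, up to `m_max = 8`). Components are added greedily while the
free energy improves by more than 1/16; each enlarged model is
warm-started from the previous optimum. This reproduces the qualitative
sparsity profile — many patterns with tiny prior variance, few with
large — without claiming to replicate the original search. The
hyperprior is `pi = -4`, `Pi = I/256`: weakly informative shrinkage
toward small variances, which is what prunes unneeded components.

The number of "retained features" is counted as the voxels whose prior
variance `sum_k exp(lam_k) [voxel in subset k]` exceeds `tau = 1e-3`
times the maximum such variance.

### Posterior over voxel weights

Given the hyperparameter mode, standard Gaussian conditioning gives

    Sigma_eta_post = (L' Sigma_zeta^-1 L + Sigma_eta^-1)^-1,
    eta_post       = Sigma_eta_post L' Sigma_zeta^-1 v,

computed in the active pattern space (patterns with zero prior variance
have exactly zero posterior weight).

## Classifiers

* **Two-model (primary).** Build `X_A` (targets labeled A) and `X_B`
  (targets labeled B), invert both models, predict the label whose model
  has the larger free energy. With several targets, all share one
  hypothesized label per model. Exact ties go to the lexicographically
  first class and are flagged.
* **One-model.** Build the design with targets omitted (as if no event
  occurred), invert once, form the prediction signal `s = R Y beta`, and
  correlate it with the confound-removed contrast regressors of the two
  full hypothesis designs; the larger Pearson correlation wins. The
  correlation is computed over the full series — the two regressors
  differ only near the targets, so the difference localizes itself; a
  peristimulus-window variant is deliberately not implemented.
* **GLM T-weighted.** Weight each voxel's series by its T statistic for
  the class contrast, sum over voxels, and correlate the (confound-
  removed) signal with the two hypothesis regressors. In cross-
  validation the T map is recomputed per fold from a design that omits
  the held-out trial, so no fold sees its own label.
* **SVM on trial-wise betas.** Per-trial coefficients are estimated in
  the "least-squares separate" style: for each trial, regressors are
  [that trial's convolved stick, all other trials combined, confounds],
  keeping the trial's own coefficient (an all-separate variant is
  available as `method="ls_a"`). A linear soft-margin SVM (C = 1)
  optionally preceded by recursive feature elimination (halve the
  features with smallest |weight| until at most the target count, 2,000
  by default) classifies the held-out beta by the sign of its decision
  value; exactly zero goes to the second class. Several target betas are
  scored by their mean decision value.

## Feature masks

Voxel-wise OLS with confounds appended gives T contrast maps; masks are
one-sided supra-threshold clusters (default p < 0.001 uncorrected,
minimum 35 connected voxels, 18-connectivity in 3D with 6/26 available).
The union of the two class-activation masks plays the role of the
"either class" mask, while the between-class contrast map thresholded
the same way gives the "difference" mask. Mask stability is quantified
by the overlap rate, 100 |a and b| / |a or b| — defined over the union
so identical masks score 100%.

## Evaluation protocols

Leave-one-out cross-validation flags each trial in turn as the unknown
target; a failing fold is recorded as incorrect and the run continues.
For multi-trial classification, the same-class trial with the longest
TOTAL-ISI (preceding onset to following onset, over all trials; first
and last trials are not rankable and are excluded) is the reference:
with two targets it is paired with each remaining same-class trial in
turn (39 runs per class of 40); with three, the reference plus the two
next-longest-ISI trials form one fixed triple per class, scored once —
the protocol's description for the triple case is by analogy, and this
is the declared interpretation. The ISI analysis correlates the
per-trial free-energy difference, `F(true-label model) - F(other
model)` (configurable to the absolute difference), with PRE-, POST- and
TOTAL-ISI via Pearson correlation.

As a deliberate computational shortcut, feature masks are built once
from the full time series rather than per fold (their stability under
single-trial deletion is what the overlap-rate diagnostic quantifies); trial-wise
betas likewise ignore labels entirely and are shared across folds. The
GLM classifier's T-weighting, which does depend on labels, is always
recomputed per fold.

## Synthetic data generator

The simulator emulates the target experiment: two classes of 2-s
stimuli, 40 trials per class, fixation jittered uniformly on 1-10 s,
TR 2 s, with a 24-s rest tail. Each class has a sparse spatial pattern
(default: 25% of voxels active per class, 25% of each support shared,
weights N(0,1)); per-trial amplitudes are N(1, 0.25) to emulate the
strong trial-by-trial variability of real data; responses are the
events convolved with the canonical HRF, so neighbouring trials overlap
exactly as the linear model assumes. Confounds are random low-frequency
cosines (periods > 128 s, matching the analysis cut-off) and noise is
AR(1) Gaussian (rho 0.2). SNR is defined as the standard deviation of
the noiseless signal in pattern-carrying voxels divided by the marginal
noise standard deviation, averaged over those voxels; the default is 1.
The default voxel count is 96 — a desk-scale stand-in for the ~40,000-
voxel masks of a real study, chosen so that full 20-seed benchmark
protocols run in minutes. All randomness flows from one seed;
regenerating with the same configuration reproduces the dataset
bit-for-bit.

What the simulator does *not* emulate: spatially structured (cluster-
shaped) activations, physiological noise and motion, HRF variability
across voxels, and nonlinear BOLD saturation. Passing the simulation
benchmarks therefore demonstrates correctness of the machinery and the
directional claims under the model's own assumptions, not performance
on real data.

## The HRF

Canonical double-gamma: each lobe is an unnormalized gamma density
written as `(t/d)^(d/s) exp(-(t-d)/s)` so its mode sits exactly at the
stated delay (peak 6 s, undershoot 16 s, unit dispersions, undershoot
ratio 1/6, 32-s support), and the difference is rescaled to peak at 1 so
simulated amplitudes are interpretable. Events are placed on a 0.1-s
microtime grid before convolution (onsets are jittered off the TR grid);
zero-duration events are unit-mass impulses whose regressor equals the
sampled HRF exactly, and boxcars use trapezoid edge weights so the
Riemann convolution is second-order accurate in the grid step.

## Numerical choices and degenerate inputs

* Pseudo-inverses and `orth(.)` use SVD with a 1e-10 relative singular
  value cut-off; projector eigenvectors are kept at singular value >
  0.5.
* Covariance factorizations retry with escalating logged jitter before
  failing.
* Singular or duplicate covariance components (tiny pattern counts) are
  deduplicated with a logged notice.
* An exact free-energy tie between hypotheses breaks to the
  lexicographically first label and is flagged, preferring determinism
  over abstention in evaluation pipelines.
* All-zero contrasts, empty masks, all-zero T maps and zero-variance
  prediction signals raise immediately rather than propagating NaNs.

## Known limitations

* Binary classification only; multiclass model comparison and posterior
  class probabilities from evidence differences are natural extensions,
  not implemented.
* Spatial priors other than the identity (smooth, compact, support
  patterns) are out of scope.
* Under the generator's idealized assumptions (exactly matched HRF,
  linear superposition, spatially unstructured patterns) the one-model
  and two-model classifiers perform equivalently: at the default SNR
  both sit at ceiling, and at very low SNR the one-model correlation
  variant is marginally more accurate in simulation. The two-model
  approach's advantage on real data therefore reflects features of real
  data (HRF mismatch, nonstationarity, structured noise) that this
  simulator deliberately omits; the simulation benchmarks test
  correctness, not that superiority.
* Recovery of the *individual* voxel weights at low SNR is information-
  limited: with ~150 confound-removed scans, hundreds of voxels and
  noise on the order of the signal, no support-blind estimator
  identifies the active set reliably (oracle-penalty ridge and lasso
  plateau near correlation 0.4-0.6 with the truth in our benchmarks,
  while an estimator given the true support reaches ~0.85). The
  classifiers remain accurate in this regime because model comparison
  integrates over the weights rather than requiring them pointwise.
  Weight recovery becomes near-perfect as noise vanishes (tested).
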