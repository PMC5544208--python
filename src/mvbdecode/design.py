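"""Construction of the decoding model's right-hand side.

Everything the generative model needs before any data are touched lives
here: the canonical hemodynamic response function (HRF), event/trial
tables, HRF-convolved design matrices for competing label hypotheses,
the design-derived target variable, confound models with their
residual-forming projector, and the AR(1) serial-correlation model.

Conventions
-----------
* All times are in seconds; time 0 is the acquisition midpoint of the
  first retained scan (dummy scans are assumed discarded upstream).
* Events are placed on a fine "microtime" grid (default 0.1 s) before
  convolution, because jittered onsets do not align with the TR grid.
* A zero-duration event is a unit-mass impulse: its convolved regressor
  equals the HRF sampled at scan times. Events with positive duration
  are unit-height neural boxcars (Riemann-sum convolution).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import toeplitz

logger = logging.getLogger("mvbdecode")

#: label used in a hypothesis map to drop a target trial from the design
OMIT = "omit"

DEFAULT_MICROTIME_DT = 0.1
DEFAULT_DRIFT_CUTOFF_S = 128.0


# ---------------------------------------------------------------------------
# Hemodynamic response function
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HRFModel:
    """Canonical double-gamma HRF.

    Each lobe is an unnormalized gamma density written so that its mode
    falls exactly at the stated delay: ``(t/d)**(d/s) * exp(-(t-d)/s)``.
    The undershoot is subtracted with weight ``undershoot_ratio`` and the
    resulting curve is rescaled so its peak value is 1, which makes
    simulated response amplitudes directly interpretable.

    Parameters are the field-standard defaults: 6 s peak, 16 s
    undershoot, unit dispersions, 1/6 undershoot ratio, 32 s support.
    """

    kind: str = "canonical-double-gamma"
    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    duration: float = 32.0

    def __post_init__(self) -> None:
        for name in ("peak_delay", "undershoot_delay",
                     "peak_dispersion", "undershoot_dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"HRFModel.{name} must be > 0")
        if self.duration < self.undershoot_delay:
            raise ValueError("HRF support must cover the undershoot delay")


def _gamma_lobe(t: np.ndarray, delay: float, dispersion: float) -> np.ndarray:
    """Gamma-shaped lobe with mode at `delay` and peak value 1."""
    out = np.zeros_like(t, dtype=float)
    pos = t > 0
    tp = t[pos]
    a = delay / dispersion
    out[pos] = np.exp(a * np.log(tp / delay) - (tp - delay) / dispersion)
    return out


def canonical_hrf(times: np.ndarray, hrf: HRFModel | None = None) -> np.ndarray:
    """Sample the canonical HRF at the given time points (seconds).

    Returns the difference-of-gammas curve, peak-normalized to 1.
    Times beyond the HRF support evaluate to the (tiny) tail of the
    closed form rather than being hard-clipped.
    """
    hrf = hrf or HRFModel()
    times = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(times)):
        raise ValueError("HRF time points must be finite")
    if np.any(times < 0):
        raise ValueError("HRF time points must be non-negative")
    curve = (_gamma_lobe(times, hrf.peak_delay, hrf.peak_dispersion)
             - hrf.undershoot_ratio
             * _gamma_lobe(times, hrf.undershoot_delay, hrf.undershoot_dispersion))
    # normalize by the analytic peak of the same expression on a dense grid
    ref_t = np.arange(0.0, hrf.duration + 1e-9, 0.001)
    ref = (_gamma_lobe(ref_t, hrf.peak_delay, hrf.peak_dispersion)
           - hrf.undershoot_ratio
           * _gamma_lobe(ref_t, hrf.undershoot_delay, hrf.undershoot_dispersion))
    peak = float(ref.max())
    return curve / peak


def hrf_kernel(hrf: HRFModel, dt: float) -> np.ndarray:
    """HRF sampled on the microtime grid [0, duration] with step `dt`."""
    return canonical_hrf(np.arange(0.0, hrf.duration + dt / 2, dt), hrf)


def place_event(neural: np.ndarray, onset: float, duration: float, dt: float,
                amplitude: float = 1.0) -> bool:
    """Add one event to a microtime neural signal, in place.

    Zero-duration events are unit-mass impulses (height 1/dt), so their
    convolved regressor equals the HRF sampled at scan times exactly.
    Boxcars use trapezoid edge weights (half weight at the two edge
    bins), making the Riemann convolution second-order accurate in dt.
    Returns True when the event had to be truncated at the last scan.
    """
    n = len(neural)
    start = int(round(onset / dt))
    if start >= n:
        return True
    if duration <= 0:
        neural[start] += amplitude / dt
        return False
    stop = int(round((onset + duration) / dt))
    truncated = stop >= n
    stop = min(stop, n - 1)
    neural[start:stop + 1] += amplitude
    neural[start] -= 0.5 * amplitude
    neural[stop] -= 0.5 * amplitude
    return truncated


# ---------------------------------------------------------------------------
# Trials
# ---------------------------------------------------------------------------

@dataclass
class TrialTable:
    """Event sequence: onsets, durations, class labels, target flags.

    Target trials are the ones whose label is treated as unknown by the
    classifiers; their ``labels`` entry records the ground truth (used
    only for scoring, never for model building).
    """

    onsets: np.ndarray
    durations: np.ndarray
    labels: np.ndarray
    target_flags: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.target_flags = np.asarray(self.target_flags, dtype=bool)
        n = len(self.onsets)
        if not (len(self.durations) == len(self.labels)
                == len(self.target_flags) == n):
            raise ValueError("TrialTable fields must have equal length")
        if n and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if np.any(self.durations < 0):
            raise ValueError("durations must be non-negative")
        known = self.labels[~self.target_flags]
        if n and not self.target_flags.all() and len(set(known)) < 2:
            logger.warning("fewer than two classes among known trials")

    def __len__(self) -> int:
        return len(self.onsets)

    @property
    def n_trials(self) -> int:
        return len(self.onsets)

    @property
    def target_indices(self) -> np.ndarray:
        return np.flatnonzero(self.target_flags)

    @property
    def classes(self) -> list[str]:
        """Sorted class labels present among known (non-target) trials."""
        return sorted(set(self.labels[~self.target_flags]))

    def with_targets(self, indices) -> "TrialTable":
        """Copy of the table with exactly `indices` flagged as targets."""
        flags = np.zeros(len(self), dtype=bool)
        flags[np.asarray(indices, dtype=int)] = True
        return TrialTable(self.onsets.copy(), self.durations.copy(),
                          self.labels.copy(), flags)


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """M-scan x J-regressor design with HRF convolution metadata."""

    X: np.ndarray
    regressor_names: list[str]
    TR: float
    convolved: bool = True
    hrf: HRFModel = field(default_factory=HRFModel)
    contrast: np.ndarray | None = None

    @property
    def n_scans(self) -> int:
        return self.X.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.X.shape[1]

    def temporal_operator(self) -> np.ndarray:
        """M x M convolution operator T at scan resolution.

        Lower-triangular Toeplitz matrix of the HRF sampled at the TR;
        metadata only — the regressors themselves are convolved on the
        microtime grid, not through this matrix.
        """
        M = self.n_scans
        h = canonical_hrf(np.arange(M) * self.TR, self.hrf)
        return toeplitz(h, np.zeros(M))


def build_design_matrix(trials: TrialTable,
                        label_hypothesis: dict[int, str] | None,
                        TR: float,
                        M: int,
                        hrf: HRFModel | None = None,
                        dt: float = DEFAULT_MICROTIME_DT) -> DesignMatrix:
    """One HRF-convolved regressor per class under a label hypothesis.

    ``label_hypothesis`` maps target-trial index -> class label (or
    ``OMIT`` to drop the trial from every regressor, the one-model
    construction). Known trials keep their own label. Stick functions
    are placed on the microtime grid, convolved with the HRF, and
    resampled at scan onsets ``0, TR, 2 TR, ...``.
    """
    hrf = hrf or HRFModel()
    label_hypothesis = dict(label_hypothesis or {})
    target_set = set(trials.target_indices.tolist())
    for idx in label_hypothesis:
        if idx not in target_set:
            raise ValueError(f"hypothesis references non-target trial {idx}")
    missing = target_set - set(label_hypothesis)
    if missing:
        raise ValueError(f"target trials without hypothesized label: {sorted(missing)}")

    # effective label per trial under the hypothesis
    eff = []
    for i in range(len(trials)):
        if trials.target_flags[i]:
            eff.append(label_hypothesis[i])
        else:
            eff.append(trials.labels[i])

    classes = sorted({lab for lab in eff if lab != OMIT})
    total_s = M * TR
    n_fine = int(round(total_s / dt))
    kernel = hrf_kernel(hrf, dt)
    scan_idx = np.round(np.arange(M) * TR / dt).astype(int)

    X = np.zeros((M, len(classes)))
    for j, cls in enumerate(classes):
        neural = np.zeros(n_fine)
        for i in range(len(trials)):
            if eff[i] != cls:
                continue
            if place_event(neural, trials.onsets[i], trials.durations[i], dt):
                logger.warning("trial %d extends past the last scan; truncated", i)
        conv = np.convolve(neural, kernel)[:n_fine] * dt
        X[:, j] = conv[scan_idx]
    return DesignMatrix(X=X, regressor_names=classes, TR=TR, convolved=True, hrf=hrf)


def single_trial_regressors(trials: TrialTable, TR: float, M: int,
                            hrf: HRFModel | None = None,
                            dt: float = DEFAULT_MICROTIME_DT) -> np.ndarray:
    """M x n_trials matrix: one HRF-convolved stick column per trial,
    irrespective of class (used by trial-wise beta estimation)."""
    hrf = hrf or HRFModel()
    n_fine = int(round(M * TR / dt))
    kernel = hrf_kernel(hrf, dt)
    scan_idx = np.round(np.arange(M) * TR / dt).astype(int)
    out = np.zeros((M, len(trials)))
    for i in range(len(trials)):
        neural = np.zeros(n_fine)
        if place_event(neural, trials.onsets[i], trials.durations[i], dt):
            logger.warning("trial %d extends past the last scan; truncated", i)
        out[:, i] = (np.convolve(neural, kernel)[:n_fine] * dt)[scan_idx]
    return out


def discriminative_contrast(design: DesignMatrix, classes: list[str]) -> np.ndarray:
    """Contrast +1 on the first class regressor, -1 on the second."""
    c = np.zeros(design.n_regressors)
    for name, w in zip(classes, (1.0, -1.0)):
        c[design.regressor_names.index(name)] = w
    return c


# ---------------------------------------------------------------------------
# Confounds and the residual-forming matrix
# ---------------------------------------------------------------------------

@dataclass
class ConfoundModel:
    """Confound matrix G and the residual-forming projector R.

    R has orthonormal rows spanning the orthogonal complement of
    col(G); applying it removes the confound subspace from data and
    regressors alike, so the confound coefficients are never estimated.
    """

    G: np.ndarray
    R: np.ndarray

    @property
    def gamma_dim(self) -> int:
        return self.G.shape[1]

    @property
    def w_dim(self) -> int:
        return self.R.shape[0]


def dct_drift_basis(M: int, TR: float,
                    cutoff_s: float = DEFAULT_DRIFT_CUTOFF_S) -> np.ndarray:
    """Discrete-cosine low-frequency drift regressors (no constant term).

    Includes cosines with period longer than ``cutoff_s``, i.e. orders
    k = 1 .. floor(2 M TR / cutoff_s).
    """
    K = int(np.floor(2.0 * M * TR / cutoff_s))
    m = np.arange(M)
    cols = [np.cos(np.pi * k * (2 * m + 1) / (2 * M)) for k in range(1, K + 1)]
    if not cols:
        return np.zeros((M, 0))
    return np.column_stack(cols)


def default_confounds(M: int, TR: float,
                      cutoff_s: float = DEFAULT_DRIFT_CUTOFF_S) -> "ConfoundModel":
    """Intercept plus discrete-cosine drift basis with the given cut-off."""
    G = np.column_stack([np.ones(M), dct_drift_basis(M, TR, cutoff_s)])
    return residual_forming(G)


def residual_forming(G: np.ndarray | None, M: int | None = None) -> ConfoundModel:
    """Residual-forming matrix R = orth(I - G G+)^t for confounds G.

    With no confounds R is the identity. The generalized inverse uses an
    SVD pseudo-inverse (cut-off 1e-10 x max singular value); orth(.)
    keeps the left singular vectors of the projector with singular value
    > 0.5 (projector eigenvalues are 0/1).
    """
    if G is None or G.size == 0:
        if M is None and G is not None:
            M = G.shape[0]
        if M is None:
            raise ValueError("scan count M required when G is empty")
        return ConfoundModel(G=np.zeros((M, 0)), R=np.eye(M))
    G = np.asarray(G, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    M_ = G.shape[0]
    if G.shape[1] > M_:
        raise ValueError("more confound columns than scans")
    P = np.eye(M_) - G @ np.linalg.pinv(G, rcond=1e-10)
    U, s, _ = np.linalg.svd(P)
    R = U[:, s > 0.5].T
    return ConfoundModel(G=G, R=R)


# ---------------------------------------------------------------------------
# Target variable
# ---------------------------------------------------------------------------

@dataclass
class TargetVariable:
    """The design-derived scalar target variable and its projections.

    ``X_vec`` is the contrast combination X c of the hypothesis design;
    ``v`` is its confound-removed version R (X c), the quantity the
    Bayesian inversion regresses on the voxel data; ``w_dim`` is the
    dimension of the residual space (rows of R).
    """

    X_vec: np.ndarray
    v: np.ndarray
    w_dim: int
    contrast: np.ndarray
    W: np.ndarray | None = None  # weighting matrix mapping X_vec to v
                                 # (R itself: X_vec is already convolved)


def make_target_variable(design: DesignMatrix, c: np.ndarray,
                         conf: ConfoundModel) -> TargetVariable:
    c = np.asarray(c, dtype=float)
    if c.shape != (design.n_regressors,):
        raise ValueError("contrast length must match the number of regressors")
    if not np.any(c != 0):
        raise ValueError("contrast must have at least one nonzero entry")
    x_vec = design.X @ c
    v = conf.R @ x_vec
    return TargetVariable(X_vec=x_vec, v=v, w_dim=conf.R.shape[0], contrast=c,
                          W=conf.R)


# ---------------------------------------------------------------------------
# Serial correlations
# ---------------------------------------------------------------------------

@dataclass
class NoiseModel:
    """AR(1) serial-correlation matrix V (unit diagonal)."""

    V: np.ndarray
    ar1_rho: float


def ar1_covariance(M: int, rho: float) -> NoiseModel:
    """V[i, j] = rho**|i-j|; symmetric positive definite for 0 <= rho < 1."""
    if not 0.0 <= rho < 1.0:
        raise ValueError("AR(1) rho must lie in [0, 1)")
    V = toeplitz(rho ** np.arange(M))
    return NoiseModel(V=V, ar1_rho=rho)
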