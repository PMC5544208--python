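"""Trial classification procedures.

Four ways of assigning a class label to the unknown target trial(s):

* ``mvb2`` (two-model, the primary method): build one design matrix per
  hypothesized label for the targets, invert each multivariate Bayesian
  model, and pick the label whose model attains the higher free energy
  (approximate log evidence).
* ``mvb1`` (one-model): omit the targets from the design as if no event
  occurred, invert once, project the data through the posterior voxel
  weights, and pick the hypothesis regressor with the higher Pearson
  correlation against that prediction signal.
* ``glm``: weight each voxel's time series by its T statistic for the
  class contrast, sum, and correlate the resulting signal with the two
  hypothesis regressors.
* ``svm``: linear soft-margin SVM on trial-wise GLM betas (one-vs-rest
  "least-squares separate" estimates), optionally preceded by recursive
  feature elimination; sign of the decision value picks the class.

Ties are broken to the lexicographically first class label and flagged.
All correlations use the confound-removed (residual-formed) series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .design import (OMIT, ConfoundModel, DesignMatrix, HRFModel, NoiseModel,
                     TrialTable, build_design_matrix, discriminative_contrast,
                     make_target_variable, single_trial_regressors,
                     DEFAULT_MICROTIME_DT)
from .mvb import (HyperPriors, MVBFit, MVBOperator, build_sparse_components,
                  mvb_invert, DEFAULT_TOL, DEFAULT_MAX_ITER, DEFAULT_M_MAX)
from .simulate import BoldDataset

logger = logging.getLogger("mvbdecode")

DEFAULT_SVM_C = 1.0
DEFAULT_RFE_TARGET = 2000


@dataclass
class MVBSettings:
    """Knobs of the Bayesian inversion exposed to the classifiers."""

    tol: float = DEFAULT_TOL
    max_iter: int = DEFAULT_MAX_ITER
    m_max: int = DEFAULT_M_MAX
    hyper: HyperPriors = field(default_factory=HyperPriors)
    hrf: HRFModel = field(default_factory=HRFModel)
    microtime_dt: float = DEFAULT_MICROTIME_DT


@dataclass
class ClassificationResult:
    predicted: str
    evidence: dict[str, float]
    margin: float
    method: str
    tie_broken: bool = False
    diagnostics: dict = field(default_factory=dict)


@dataclass
class TrialBetaSet:
    """Per-trial regression coefficients (trials x voxels) with labels."""

    betas: np.ndarray
    labels: np.ndarray
    trial_indices: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.betas)):
            raise ValueError("non-finite trial-wise betas")


def _decide(evidence: dict[str, float], method: str,
            diagnostics: dict | None = None) -> ClassificationResult:
    classes = sorted(evidence)
    scores = np.array([evidence[c] for c in classes])
    best = int(np.argmax(scores))  # argmax takes the first (lexicographic) tie
    order = np.sort(scores)[::-1]
    margin = float(order[0] - order[1]) if len(order) > 1 else 0.0
    tie = bool(len(order) > 1 and order[0] == order[1])
    return ClassificationResult(predicted=classes[best], evidence=dict(evidence),
                                margin=margin, method=method, tie_broken=tie,
                                diagnostics=diagnostics or {})


def _two_classes(trials: TrialTable) -> list[str]:
    classes = trials.classes
    if len(classes) != 2:
        raise ValueError("model comparison requires known trials of exactly "
                         f"two classes; found {classes}")
    return classes


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xs, ys = x - x.mean(), y - y.mean()
    nx, ny = np.linalg.norm(xs), np.linalg.norm(ys)
    if nx == 0 or ny == 0:
        raise ValueError("zero-variance series in correlation")
    return float(xs @ ys / (nx * ny))


def _hypothesis_target(trials: TrialTable, label: str, conf: ConfoundModel,
                       classes: list[str], TR: float, M: int,
                       cfg: MVBSettings) -> tuple[DesignMatrix, np.ndarray]:
    """Design under one label hypothesis and its confound-removed
    contrast regressor R (X c)."""
    hyp = {int(t): label for t in trials.target_indices}
    X = build_design_matrix(trials, hyp, TR, M, cfg.hrf, cfg.microtime_dt)
    c = discriminative_contrast(X, classes)
    return X, conf.R @ (X.X @ c)


# ---------------------------------------------------------------------------
# MVB classifiers
# ---------------------------------------------------------------------------

def classify_two_model(trials: TrialTable, Y: BoldDataset,
                       conf: ConfoundModel, noise: NoiseModel,
                       cfg: MVBSettings | None = None,
                       *, operator: MVBOperator | None = None,
                       keep_fits: bool = False) -> ClassificationResult:
    """Bayesian model comparison between label assignments for the targets.

    All targets are hypothesized to share one label per model; the
    model with the higher free energy wins.
    """
    cfg = cfg or MVBSettings()
    classes = _two_classes(trials)
    targets = trials.target_indices
    if len(targets) == 0:
        raise ValueError("no target trial flagged")
    op = operator or MVBOperator(Y.data, conf.R, noise.V)
    M = Y.n_scans

    # one sparse component family shared by both hypotheses, built from a
    # label-neutral target variable (targets omitted) so the evidence
    # comparison reflects the data, not prior-construction asymmetry
    hyp0 = {int(t): OMIT for t in targets}
    X0 = build_design_matrix(trials, hyp0, Y.TR, M, cfg.hrf, cfg.microtime_dt)
    tv0 = make_target_variable(X0, discriminative_contrast(X0, classes), conf)
    prior = build_sparse_components(op.L, tv0.v, cfg.m_max)

    evidence: dict[str, float] = {}
    fits: dict[str, MVBFit] = {}
    for label in classes:
        X, _ = _hypothesis_target(trials, label, conf, classes, Y.TR, M, cfg)
        c = discriminative_contrast(X, classes)
        tv = make_target_variable(X, c, conf)
        fit = mvb_invert(tv, operator=op, prior=prior, greedy=True,
                         hyper=cfg.hyper, tol=cfg.tol, max_iter=cfg.max_iter)
        evidence[label] = fit.F
        fits[label] = fit
    diag = {"fits": fits} if keep_fits else {}
    return _decide(evidence, "mvb2", diag)


def classify_one_model(trials: TrialTable, Y: BoldDataset,
                       conf: ConfoundModel, noise: NoiseModel,
                       cfg: MVBSettings | None = None,
                       *, operator: MVBOperator | None = None) -> ClassificationResult:
    """One-model MVB: targets omitted from the design, correlation of the
    weighted data projection with each hypothesis regressor decides."""
    cfg = cfg or MVBSettings()
    classes = _two_classes(trials)
    targets = trials.target_indices
    if len(targets) == 0:
        raise ValueError("no target trial flagged")
    op = operator or MVBOperator(Y.data, conf.R, noise.V)
    M = Y.n_scans
    hyp = {int(t): OMIT for t in targets}
    X0 = build_design_matrix(trials, hyp, Y.TR, M, cfg.hrf, cfg.microtime_dt)
    c0 = discriminative_contrast(X0, classes)
    tv0 = make_target_variable(X0, c0, conf)
    fit = mvb_invert(tv0, operator=op, hyper=cfg.hyper, tol=cfg.tol,
                     max_iter=cfg.max_iter, m_max=cfg.m_max)
    s = op.L @ fit.beta_mean  # R Y beta: confound-removed prediction signal
    if np.allclose(s.std(), 0.0):
        raise ValueError("zero-variance prediction signal; cannot correlate")
    evidence = {}
    for label in classes:
        _, reg = _hypothesis_target(trials, label, conf, classes, Y.TR, M, cfg)
        evidence[label] = _pearson(s, reg)
    return _decide(evidence, "mvb1", {"fit": fit})


# ---------------------------------------------------------------------------
# GLM T-weighted correlation classifier
# ---------------------------------------------------------------------------

def classify_glm_weighted(trials: TrialTable, Y: BoldDataset,
                          tmap: np.ndarray, conf: ConfoundModel,
                          cfg: MVBSettings | None = None) -> ClassificationResult:
    """T-value-weighted voxel sum correlated against the hypothesis
    regressors (both confound-removed)."""
    cfg = cfg or MVBSettings()
    classes = _two_classes(trials)
    tmap = np.asarray(tmap, dtype=float).ravel()
    if Y.n_voxels == 0 or tmap.size == 0:
        raise ValueError("empty feature mask")
    if tmap.shape[0] != Y.n_voxels:
        raise ValueError("T map is not aligned with the data voxels")
    if not np.any(tmap != 0):
        raise ValueError("degenerate weighting: all T values are zero")
    u = conf.R @ (Y.data @ tmap)
    evidence = {}
    for label in classes:
        _, reg = _hypothesis_target(trials, label, conf, classes,
                                    Y.TR, Y.n_scans, cfg)
        evidence[label] = _pearson(u, reg)
    return _decide(evidence, "glm")


# ---------------------------------------------------------------------------
# Trial-wise betas + SVM
# ---------------------------------------------------------------------------

def estimate_trialwise_betas(trials: TrialTable, Y: BoldDataset,
                             conf: ConfoundModel,
                             hrf: HRFModel | None = None,
                             dt: float = DEFAULT_MICROTIME_DT,
                             method: str = "ls_s") -> TrialBetaSet:
    """Per-trial GLM coefficients for every non-target trial.

    ``ls_s`` (default): for each trial, regressors are [that trial's
    convolved stick, all other trials combined, confounds] and the
    trial's own coefficient is kept. ``ls_a``: all trials get separate
    regressors in a single model. Rank-deficient per-trial designs drop
    the trial with a warning.
    """
    if len(trials) < 2:
        raise ValueError("need at least two trials")
    if method not in ("ls_s", "ls_a"):
        raise ValueError(f"unknown trial-wise beta method: {method}")
    cols = single_trial_regressors(trials, Y.TR, Y.n_scans, hrf, dt)
    keep = np.flatnonzero(~trials.target_flags)
    G = conf.G

    if method == "ls_a":
        D = np.column_stack([cols, G])
        if np.linalg.matrix_rank(D) < D.shape[1]:
            raise ValueError("rank-deficient all-separate design")
        coef = np.linalg.lstsq(D, Y.data, rcond=None)[0]
        return TrialBetaSet(betas=coef[keep], labels=trials.labels[keep],
                            trial_indices=keep)

    total = cols.sum(axis=1)
    rows, labels, idx = [], [], []
    for i in keep:
        D = np.column_stack([cols[:, i], total - cols[:, i], G])
        if np.linalg.matrix_rank(D) < D.shape[1]:
            logger.warning("rank-deficient design for trial %d; dropped", i)
            continue
        coef = np.linalg.lstsq(D, Y.data, rcond=None)[0]
        rows.append(coef[0])
        labels.append(trials.labels[i])
        idx.append(i)
    return TrialBetaSet(betas=np.asarray(rows), labels=np.asarray(labels, object),
                        trial_indices=np.asarray(idx, dtype=int))


def _fit_linear_svm(X: np.ndarray, labels: np.ndarray, classes: list[str],
                    C: float) -> SVC:
    y = np.where(labels == classes[0], 1, -1)
    svm = SVC(kernel="linear", C=C)
    svm.fit(X, y)
    return svm


def rfe_select(betas: TrialBetaSet, target_count: int = DEFAULT_RFE_TARGET,
               C: float = DEFAULT_SVM_C) -> np.ndarray:
    """Recursive feature elimination with a linear soft-margin SVM.

    Repeatedly keeps the ceil(count/2) features with the largest
    absolute weights until the count is at or below ``target_count``.
    Returns the sorted surviving voxel indices.
    """
    classes = sorted(set(betas.labels))
    if len(classes) < 2:
        raise ValueError("RFE needs two classes in the training labels")
    n = betas.betas.shape[1]
    if target_count > n:
        raise ValueError("target_count exceeds current feature count")
    active = np.arange(n)
    while len(active) > target_count:
        svm = _fit_linear_svm(betas.betas[:, active], betas.labels, classes, C)
        w = np.abs(np.asarray(svm.coef_).ravel())
        keep = int(np.ceil(len(active) / 2))
        order = np.argsort(-w, kind="stable")[:keep]
        active = np.sort(active[order])
    return active


def classify_svm(train: TrialBetaSet, test_beta: np.ndarray,
                 C: float = DEFAULT_SVM_C) -> ClassificationResult:
    """Sign of the linear SVM decision value: first (sorted) class if
    > 0, otherwise the second — the declared 'otherwise' rule covers an
    exact zero. Multiple test rows are scored by their mean decision
    value (joint labeling of several targets)."""
    classes = sorted(set(train.labels))
    if len(classes) < 2:
        raise ValueError("training set must contain two classes")
    svm = _fit_linear_svm(train.betas, train.labels, classes, C)
    test = np.atleast_2d(np.asarray(test_beta, dtype=float))
    val = float(np.mean(svm.decision_function(test)))
    predicted = classes[0] if val > 0 else classes[1]
    return ClassificationResult(
        predicted=predicted,
        evidence={classes[0]: val, classes[1]: -val},
        margin=abs(2 * val), method="svm", tie_broken=(val == 0.0),
        diagnostics={"decision_value": val})
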