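"""Inversion of the two-level multivariate Bayesian decoding model.

The model regresses a confound-removed, design-derived target variable
``v = R X c`` on the voxel data through unknown voxel weights:

    v = L eta + zeta,     L = R Y U,
    zeta ~ N(0, exp(lam_0) R V R^T),
    eta  ~ N(0, Sigma_eta),  Sigma_eta = sum_k exp(lam_k) I^(k),

where the I^(k) are diagonal 0/1 indicator components over patterns
(U = I here, so patterns are voxels). Only the hyperparameters ``lam``
are estimated, by maximizing the Laplace free energy

    F = -1/2 [ v' S(lam)^-1 v + ln|S(lam)| + w ln 2pi ]
        -1/2 [ (lam - pi)' Pi (lam - pi) - ln|Pi S_lam| ],

with S(lam) = sum_k exp(lam_k) Q_k the induced covariance of v and
S_lam the posterior covariance of lam (inverse curvature). F serves
both as the optimization objective and as the log-evidence
approximation compared across label hypotheses by the classifiers.

Optimization is Fisher scoring on lam with step-halving, so the free
energy trace is non-decreasing by construction; for problems with at
most two hyperparameters the optimum is polished by a derivative-free
local search so it coincides with an exhaustive scan of the objective.

Two numerically equivalent evaluation paths are provided: a dense one
that forms S(lam) explicitly, and a Woodbury path that exploits the
diagonal prior (cost cubic in the number of patterns instead of scans).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

logger = logging.getLogger("mvbdecode")

DEFAULT_TOL = 1e-2
DEFAULT_MAX_ITER = 64
DEFAULT_M_MAX = 8
DEFAULT_TAU_FEATURES = 1e-3
DEFAULT_HYPERPRIOR_MEAN = -4.0
DEFAULT_HYPERPRIOR_PRECISION = 1.0 / 256.0
GROW_MIN_IMPROVEMENT = 1.0 / 16.0
_MAX_STEP_NORM = 8.0
_N_HALVINGS = 10
_LAM_BOUND = 32.0  # exp() dynamic range guard; hyperparameters are log-variances


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

@dataclass
class PriorSpec:
    """Sparse empirical prior: nested pattern subsets over U = I patterns.

    ``subsets[k]`` holds the pattern indices covered by covariance
    component k; component k contributes exp(lam_k) to the prior
    variance of every pattern it covers.
    """

    p: int
    subsets: list[np.ndarray]
    U: np.ndarray | None = None  # None means identity (sparse constraint)

    def __post_init__(self) -> None:
        if not self.subsets:
            raise ValueError("PriorSpec needs at least one component")
        for s in self.subsets:
            if len(s) == 0:
                raise ValueError("empty covariance component")
            if np.any(s < 0) or np.any(s >= self.p):
                raise ValueError("component indices out of range")

    @property
    def n_components(self) -> int:
        return len(self.subsets)

    def indicators(self) -> np.ndarray:
        """p x m 0/1 matrix; column k marks the patterns of component k."""
        ind = np.zeros((self.p, len(self.subsets)))
        for k, s in enumerate(self.subsets):
            ind[s, k] = 1.0
        return ind


@dataclass
class HyperPriors:
    """Gaussian hyperprior on lam: N(pi, Pi^-1), weakly shrinking toward
    small variances so unneeded components are pruned."""

    mean: float = DEFAULT_HYPERPRIOR_MEAN
    precision: float = DEFAULT_HYPERPRIOR_PRECISION

    def vectors(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        return np.full(n, self.mean), np.eye(n) * self.precision


def build_sparse_components(L: np.ndarray, v: np.ndarray,
                            m_max: int = DEFAULT_M_MAX) -> PriorSpec:
    """Nested dyadic covariance components ranked by pattern relevance.

    Patterns are scored by the magnitude of their regularized
    least-squares weight |L'(L L' + eps I)^-1 v| and ranked (ties fall
    back to pattern index order). Component k covers the top
    ceil(p / 2^(k-1)) patterns, producing the characteristic sparse
    profile: many patterns with small prior variance, few with large.
    """
    if m_max < 1:
        raise ValueError("m_max must be >= 1")
    L = np.asarray(L, dtype=float)
    if L.ndim != 2 or L.shape[1] < 1:
        raise ValueError("operating matrix must have at least one column")
    w, p = L.shape
    LLt = L @ L.T
    eps = 1e-6 * np.trace(LLt)
    if eps <= 0:
        eps = 1e-12
    x = np.linalg.solve(LLt + eps * np.eye(w), v)
    scores = np.abs(L.T @ x)
    order = np.argsort(-scores, kind="stable")

    subsets: list[np.ndarray] = []
    seen_sizes: set[int] = set()
    for k in range(m_max):
        size = int(np.ceil(p / 2 ** k))
        if size in seen_sizes:
            logger.debug("dropping duplicate component of size %d", size)
            continue
        seen_sizes.add(size)
        subsets.append(np.sort(order[:size]))
        if size == 1:
            break
    return PriorSpec(p=p, subsets=subsets)


# ---------------------------------------------------------------------------
# Operating space shared across inversions on one dataset
# ---------------------------------------------------------------------------

class MVBOperator:
    """Precomputed quantities fixed by (Y, R, V): reused across folds
    and label hypotheses, where only the target variable changes."""

    def __init__(self, Y: np.ndarray, R: np.ndarray, V: np.ndarray,
                 U: np.ndarray | None = None) -> None:
        Y = np.asarray(Y, dtype=float)
        if not np.all(np.isfinite(Y)):
            raise ValueError("non-finite values in the data matrix")
        self.L = R @ (Y if U is None else Y @ U)
        self.w, self.p = self.L.shape
        C = R @ V @ R.T
        self.C = 0.5 * (C + C.T)
        self.C_chol = _chol(self.C)
        self.logdet_C = 2.0 * np.sum(np.log(np.diag(self.C_chol[0])))
        self.K = cho_solve(self.C_chol, self.L)   # C^-1 L
        self.G = self.L.T @ self.K                # L' C^-1 L


def _chol(A: np.ndarray, what: str = "covariance"):
    """Cholesky with escalating jitter on failure (logged)."""
    jitter = 0.0
    scale = np.mean(np.diag(A)) or 1.0
    for _ in range(8):
        try:
            return cho_factor(A + jitter * np.eye(A.shape[0]), lower=True,
                              check_finite=False)
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10, 1e-12 * scale)
            logger.warning("%s matrix singular; adding jitter %.3e", what, jitter)
    raise np.linalg.LinAlgError(f"{what} matrix not positive definite")


# ---------------------------------------------------------------------------
# Free-energy engines
# ---------------------------------------------------------------------------

class _Stats:
    __slots__ = ("F", "grad", "fisher", "loglik")

    def __init__(self, F, grad, fisher, loglik):
        self.F, self.grad, self.fisher, self.loglik = F, grad, fisher, loglik


def _assemble_F(loglik: float, lam: np.ndarray, pi: np.ndarray,
                Pi: np.ndarray, fisher: np.ndarray) -> float:
    dl = lam - pi
    Hpost = fisher + Pi
    sign, logdet_H = np.linalg.slogdet(Hpost)
    if sign <= 0:  # indefinite curvature far from optimum; clamp
        logdet_H = np.inf
    sign_p, logdet_Pi = np.linalg.slogdet(Pi)
    return loglik - 0.5 * (dl @ Pi @ dl) + 0.5 * (logdet_Pi - logdet_H)


class DenseEngine:
    """Direct evaluation from explicit covariance components Q_k."""

    def __init__(self, Qs: list[np.ndarray], v: np.ndarray,
                 pi: np.ndarray, Pi: np.ndarray) -> None:
        self.Qs, self.v, self.pi, self.Pi = Qs, np.asarray(v, float), pi, Pi
        self.w = len(self.v)

    def stats(self, lam: np.ndarray) -> _Stats:
        lam = np.clip(lam, -_LAM_BOUND, _LAM_BOUND)
        e = np.exp(lam)
        Sigma = sum(ek * Qk for ek, Qk in zip(e, self.Qs))
        cf = _chol(Sigma)
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        z = cho_solve(cf, self.v)
        vSv = float(self.v @ z)
        loglik = -0.5 * (vSv + logdet + self.w * np.log(2 * np.pi))
        m = len(lam)
        A = [cho_solve(cf, Qk) for Qk in self.Qs]
        g = np.array([
            -0.5 * e[k] * (np.trace(A[k]) - z @ self.Qs[k] @ z)
            for k in range(m)
        ]) - self.Pi @ (lam - self.pi)
        H = np.empty((m, m))
        for k in range(m):
            for j in range(k, m):
                H[k, j] = H[j, k] = 0.5 * e[k] * e[j] * np.sum(A[k] * A[j].T)
        F = _assemble_F(loglik, lam, self.pi, self.Pi, H)
        return _Stats(F, g, H, loglik)


class WoodburyEngine:
    """Evaluation in pattern space via the matrix-inversion lemma.

    S(lam) = s C + L D L' with s = exp(lam_0) and D the diagonal prior
    variance d_j = sum_k exp(lam_k) [j in subset k]; everything reduces
    to factorizations of the (active-)pattern-sized matrix
    M = D^-1 + L'C^-1 L / s.
    """

    def __init__(self, op: MVBOperator, indicators: np.ndarray,
                 v: np.ndarray, pi: np.ndarray, Pi: np.ndarray) -> None:
        self.op = op
        self.Ind = indicators              # p x m
        self.v = np.asarray(v, dtype=float)
        self.pi, self.Pi = pi, Pi
        civ = cho_solve(op.C_chol, self.v)
        self.kv = op.L.T @ civ             # L' C^-1 v
        self.vciv = float(self.v @ civ)
        self.diag_G = np.diag(op.G).copy()

    def stats(self, lam: np.ndarray) -> _Stats:
        # everything below lives in pattern space: the scan dimension w
        # enters only through the precomputed G = L'C^-1 L and kv
        op, Ind, G = self.op, self.Ind, self.op.G
        lam = np.clip(lam, -_LAM_BOUND, _LAM_BOUND)
        s = np.exp(lam[0])
        e = np.exp(lam[1:])
        d = Ind @ e                        # prior variance per pattern
        act = d > 0
        da = d[act]
        Gaa = G[np.ix_(act, act)]
        Mmat = np.diag(1.0 / da) + Gaa / s
        mf = _chol(Mmat, "pattern-space")
        logdet_M = 2.0 * np.sum(np.log(np.diag(mf[0])))
        logdet = (op.w * lam[0] + op.logdet_C
                  + np.sum(np.log(da)) + logdet_M)

        kva = self.kv[act]
        t = cho_solve(mf, kva, check_finite=False)             # M^-1 L_a' C^-1 v
        vSv = (self.vciv - (kva @ t) / s) / s
        loglik = -0.5 * (vSv + logdet + op.w * np.log(2 * np.pi))

        Gact = G[:, act]                   # p x pa
        MG = cho_solve(mf, Gact.T, check_finite=False)         # M^-1 G_a,.
        T1 = MG[:, act]                    # M^-1 G_aa
        GMG = Gact @ MG
        Hmat = (G - GMG / s) / s           # L' S^-1 L
        u = (self.kv - Gact @ t / s) / s   # L' S^-1 v

        m = len(e)
        grad = np.empty(m + 1)
        tr_T1 = np.trace(T1)
        tr_SC = op.w / s - tr_T1 / s ** 2
        # v' S^-1 C S^-1 v expanded in pattern space
        zCz = (self.vciv - 2.0 * (kva @ t) / s + (t @ Gaa @ t) / s ** 2) / s ** 2
        grad[0] = -0.5 * s * (tr_SC - zCz)
        grad[1:] = -0.5 * e * (Ind.T @ (np.diag(Hmat) - u ** 2))
        grad -= self.Pi @ (lam - self.pi)

        # Fisher information
        H = np.empty((m + 1, m + 1))
        tr_SC2 = (op.w - 2.0 * tr_T1 / s + np.sum(T1 * T1.T) / s ** 2) / s ** 2
        H[0, 0] = 0.5 * s ** 2 * tr_SC2
        # pattern blocks: tr(S^-1 Q_k S^-1 Q_j) = Ind_k' (Hmat o Hmat) Ind_j
        Hsq = Ind.T @ (Hmat * Hmat) @ Ind
        H[1:, 1:] = 0.5 * np.outer(e, e) * Hsq
        # noise-pattern: diag(L' S^-1 C S^-1 L), again only through G
        A = Gaa @ MG
        diag_third = np.einsum("ji,ji->i", MG, A)
        diag_cross = (self.diag_G - 2.0 * np.einsum("ij,ji->i", Gact, MG) / s
                      + diag_third / s ** 2) / s ** 2
        H[0, 1:] = H[1:, 0] = 0.5 * s * e * (Ind.T @ diag_cross)

        F = _assemble_F(loglik, lam, self.pi, self.Pi, H)
        return _Stats(F, grad, H, loglik)


def laplace_free_energy(lam: np.ndarray, Qs: list[np.ndarray], v: np.ndarray,
                        pi: np.ndarray, Pi: np.ndarray) -> float:
    """Laplace free energy at hyperparameters ``lam`` for explicit
    covariance components; the reference (dense) evaluation used by
    exhaustive-search oracles."""
    return DenseEngine(Qs, v, pi, Pi).stats(np.asarray(lam, float)).F


# ---------------------------------------------------------------------------
# Fit result
# ---------------------------------------------------------------------------

@dataclass
class MVBFit:
    """Posterior of an MVB inversion plus its evidence approximation."""

    mu_lambda: np.ndarray
    Sigma_lambda: np.ndarray
    eta_mean: np.ndarray
    eta_cov: np.ndarray
    beta_mean: np.ndarray
    F: float
    F_trace: np.ndarray
    prior: PriorSpec
    converged: bool
    n_iter: int
    w_dim: int
    L: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_features(self) -> int:
        return count_features(self)


def count_features(fit: MVBFit, tau: float = DEFAULT_TAU_FEATURES) -> int:
    """Number of voxels whose empirical prior variance exceeds ``tau``
    times the maximum prior variance (the MVB notion of a retained
    sparse feature)."""
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie in (0, 1)")
    var = fit.prior.indicators() @ np.exp(fit.mu_lambda[1:])
    return int(np.sum(var > tau * var.max()))


# ---------------------------------------------------------------------------
# Inversion
# ---------------------------------------------------------------------------

def _fit_fixed(engine, lam0: np.ndarray, pi: np.ndarray, Pi: np.ndarray,
               tol: float, max_iter: int,
               polish: bool = False) -> tuple[np.ndarray, _Stats, list, bool, int]:
    """Fisher-scoring ascent with step-halving on a fixed component set."""
    lam = np.asarray(lam0, dtype=float).copy()
    st = engine.stats(lam)
    trace = [st.F]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Hpost = st.fisher + Pi
        try:
            delta = np.linalg.solve(Hpost, st.grad)
        except np.linalg.LinAlgError:
            delta = st.grad
        norm = np.linalg.norm(delta)
        if norm > _MAX_STEP_NORM:
            delta *= _MAX_STEP_NORM / norm
        accepted = None
        step = 1.0
        for _ in range(_N_HALVINGS):
            cand = np.clip(lam + step * delta, -_LAM_BOUND, _LAM_BOUND)
            st_c = engine.stats(cand)
            if np.isfinite(st_c.F) and st_c.F >= st.F:
                accepted = (cand, st_c)
                break
            step *= 0.5
        if accepted is None:
            converged = True  # no ascent direction improves: local optimum
            break
        dF = accepted[1].F - st.F
        lam, st = accepted
        trace.append(st.F)
        if dF < tol:
            converged = True
            break

    # derivative-free polish for low-dimensional hyperparameter spaces,
    # so the optimum matches an exhaustive scan of the same objective
    if polish and len(lam) <= 2:
        res = minimize(lambda x: -engine.stats(x).F, lam,
                       method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400})
        if np.isfinite(res.fun) and -res.fun > st.F:
            lam = np.clip(res.x, -_LAM_BOUND, _LAM_BOUND)
            st = engine.stats(lam)
            trace.append(st.F)
    return lam, st, trace, converged, it


def _make_engine(op: MVBOperator, prior: PriorSpec, v: np.ndarray,
                 pi: np.ndarray, Pi: np.ndarray):
    if op.p <= op.w:
        return WoodburyEngine(op, prior.indicators(), v, pi, Pi)
    Ind = prior.indicators()
    Qs = [op.C] + [op.L[:, s] @ op.L[:, s].T for s in prior.subsets]
    return DenseEngine(Qs, v, pi, Pi)


def mvb_invert(v, Y=None, conf=None, noise=None,
               prior: PriorSpec | None = None,
               hyper: HyperPriors | None = None,
               tol: float = DEFAULT_TOL,
               max_iter: int = DEFAULT_MAX_ITER,
               *,
               operator: MVBOperator | None = None,
               m_max: int = DEFAULT_M_MAX,
               greedy: bool | None = None,
               grow_min_improvement: float = GROW_MIN_IMPROVEMENT) -> MVBFit:
    """Invert the two-level model for one target variable.

    Parameters
    ----------
    v : TargetVariable or array
        Confound-removed target variable (uses ``v.v`` when given a
        TargetVariable).
    Y, conf, noise : data matrix (M x N), ConfoundModel, NoiseModel
        Ignored when a precomputed ``operator`` is supplied.
    prior : PriorSpec, optional
        Covariance components. When omitted, nested dyadic sparse
        components are built from the operating matrix and grown
        greedily: components are added while the free energy improves by
        more than ``grow_min_improvement``. An explicit prior is fitted
        whole unless ``greedy=True``, which applies the same greedy
        growth to the given nested family (used by model comparison so
        competing hypotheses share one component family).
    """
    v_vec = np.asarray(getattr(v, "v", v), dtype=float)
    if not np.all(np.isfinite(v_vec)):
        raise ValueError("non-finite target variable")
    if operator is None:
        if Y is None or conf is None or noise is None:
            raise ValueError("either an operator or (Y, conf, noise) is required")
        Ymat = getattr(Y, "data", Y)
        operator = MVBOperator(Ymat, conf.R, noise.V,
                               None if prior is None else prior.U)
    op = operator
    if len(v_vec) != op.w:
        raise ValueError("target variable length does not match operating space")
    hyper = hyper or HyperPriors()

    full = prior or build_sparse_components(op.L, v_vec, m_max)
    if greedy is None:  # explicit priors are fitted whole by default
        greedy = prior is None
    grow = greedy and full.n_components > 1

    def fit_k(k: int, lam0=None, polish=False):
        sub = PriorSpec(p=full.p, subsets=full.subsets[:k], U=full.U)
        pi, Pi = hyper.vectors(k + 1)
        if lam0 is None:
            lam0 = pi
        engine = _make_engine(op, sub, v_vec, pi, Pi)
        lam, st, trace, conv, its = _fit_fixed(engine, lam0, pi, Pi, tol,
                                               max_iter, polish=polish)
        return sub, lam, st, trace, conv, its, Pi

    best = fit_k(1 if grow else full.n_components)
    trace_all = list(best[3])
    if grow:
        while best[0].n_components < full.n_components:
            k = best[0].n_components + 1
            lam0 = np.append(best[1], hyper.mean)
            cand = fit_k(k, lam0)
            if cand[2].F - best[2].F > grow_min_improvement:
                best = cand
                trace_all = list(cand[3])
            else:
                break
    if best[0].n_components == 1:
        # the returned low-dimensional optimum gets the derivative-free
        # polish (warm-started from the Fisher-scoring solution)
        best = fit_k(1, lam0=best[1], polish=True)
        trace_all.extend(best[3][1:])

    sub, lam, st, _, converged, n_iter, Pi = best
    if not converged:
        logger.warning("MVB inversion did not converge in %d iterations; "
                       "returning best iterate", max_iter)

    Sigma_lambda = np.linalg.inv(st.fisher + Pi)

    # conditional posterior over pattern weights given mu_lambda
    lam = np.clip(lam, -_LAM_BOUND, _LAM_BOUND)
    s = np.exp(lam[0])
    d = sub.indicators() @ np.exp(lam[1:])
    act = d > 0
    eta_mean = np.zeros(op.p)
    eta_cov = np.zeros((op.p, op.p))
    if act.any():
        Ga = op.G[np.ix_(act, act)]
        Ma = np.diag(1.0 / d[act]) + Ga / s
        mf = _chol(Ma, "posterior")
        kv = op.L.T @ cho_solve(op.C_chol, v_vec)
        eta_mean[act] = cho_solve(mf, kv[act]) / s
        cov_a = cho_solve(mf, np.eye(int(act.sum())))
        eta_cov[np.ix_(act, act)] = 0.5 * (cov_a + cov_a.T)
    beta_mean = eta_mean if full.U is None else full.U @ eta_mean

    return MVBFit(mu_lambda=lam, Sigma_lambda=Sigma_lambda,
                  eta_mean=eta_mean, eta_cov=eta_cov, beta_mean=beta_mean,
                  F=st.F, F_trace=np.asarray(trace_all), prior=sub,
                  converged=converged, n_iter=n_iter, w_dim=op.w, L=op.L)
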