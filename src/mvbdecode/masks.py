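"""Feature-mask construction from statistical parametric maps.

Voxel-wise ordinary least squares, T contrasts, uncorrected-p cluster
thresholding (default p < 0.001 with a 35-voxel minimum cluster
extent), set algebra over masks, and the overlap-rate diagnostic used
to justify reusing a mask across cross-validation folds.

"Consecutive voxels" are grouped by 18-connectivity in 3D (faces +
edges) by default; 6 and 26 are available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .design import ConfoundModel, DesignMatrix

DEFAULT_P_UNC = 0.001
DEFAULT_MIN_CLUSTER = 35
DEFAULT_CONNECTIVITY = 18

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class GLMFit:
    beta: np.ndarray          # (J + g) x N coefficients, confounds appended
    sigma2: np.ndarray        # residual variance per voxel
    dof: int
    xtx_inv: np.ndarray
    n_design: int             # columns belonging to the design proper


@dataclass
class StatMap:
    """T statistics on a voxel grid (any shape) with residual dof."""

    values: np.ndarray
    dof: int

    def __post_init__(self) -> None:
        if self.dof < 1:
            raise ValueError("dof must be >= 1")


@dataclass
class FeatureMask:
    """Boolean voxel-inclusion array with provenance tag."""

    mask: np.ndarray
    provenance: str = "custom"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def indices(self) -> np.ndarray:
        """Included voxels as ascending linear (C-order) indices."""
        return np.flatnonzero(self.mask)

    @property
    def size(self) -> int:
        return int(self.mask.sum())


def fit_voxelwise_glm(Y: np.ndarray, design: DesignMatrix,
                      conf: ConfoundModel) -> GLMFit:
    """OLS per voxel with confounds appended to the design.

    ``Y`` is the M x N data matrix (use the I/O layer to flatten 4D
    images). dof = M - rank([X G]).
    """
    Ymat = getattr(Y, "data", Y)
    X = np.column_stack([design.X, conf.G])
    M = Ymat.shape[0]
    if X.shape[0] != M:
        raise ValueError("scan counts of data and design differ")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient combined design (duplicate or "
                         "collinear regressors)")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Ymat
    resid = Ymat - X @ beta
    dof = M - rank
    sigma2 = np.sum(resid ** 2, axis=0) / dof
    return GLMFit(beta=beta, sigma2=sigma2, dof=dof, xtx_inv=xtx_inv,
                  n_design=design.n_regressors)


def t_contrast(fit: GLMFit, c: np.ndarray) -> StatMap:
    """T = c'beta / sqrt(sigma2 c'(X'X)^-1 c); ``c`` spans the design
    columns and is zero-padded over the confounds."""
    c = np.asarray(c, dtype=float)
    if len(c) == fit.n_design:
        c = np.concatenate([c, np.zeros(fit.beta.shape[0] - fit.n_design)])
    if len(c) != fit.beta.shape[0]:
        raise ValueError("contrast length does not match the design")
    if not np.any(c != 0):
        raise ValueError("all-zero contrast")
    var_scale = float(c @ fit.xtx_inv @ c)
    if var_scale <= 0:
        raise ValueError("zero contrast variance")
    num = c @ fit.beta
    den = np.sqrt(fit.sigma2 * var_scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(den > 0, num / den, 0.0)
    return StatMap(values=t, dof=fit.dof)


def cluster_threshold(statmap: StatMap, p_unc: float = DEFAULT_P_UNC,
                      min_cluster: int = DEFAULT_MIN_CLUSTER,
                      connectivity: int = DEFAULT_CONNECTIVITY) -> FeatureMask:
    """One-sided supra-threshold clusters with a minimum extent.

    Voxels with T above the (1 - p_unc) Student-t quantile are grouped
    by 3D connectivity; clusters smaller than ``min_cluster`` are
    removed. Threshold the negated contrast to get the opposite side.
    """
    if not 0.0 < p_unc < 1.0:
        raise ValueError("p_unc must lie in (0, 1)")
    if min_cluster < 1:
        raise ValueError("min_cluster must be >= 1")
    if statmap.values.ndim != 3:
        raise ValueError("cluster thresholding expects a 3D map")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be one of 6, 18, 26")
    t_crit = stats.t.ppf(1.0 - p_unc, statmap.dof)
    binary = statmap.values > t_crit
    labeled, n = ndimage.label(binary, structure=_STRUCTURES[connectivity])
    if n:
        sizes = np.bincount(labeled.ravel())
        small = np.flatnonzero(sizes < min_cluster)
        binary &= ~np.isin(labeled, small[small > 0])
    return FeatureMask(mask=binary, provenance="custom")


def combine_masks(a: FeatureMask, b: FeatureMask,
                  mode: str = "union") -> FeatureMask:
    """Union of two masks; ``difference-contrast`` only tags provenance
    (such masks are thresholded upstream from the between-class
    contrast map)."""
    if a.mask.shape != b.mask.shape:
        raise ValueError("masks live on different grids")
    if mode == "union":
        provenance = "VE&PE"
    elif mode == "difference-contrast":
        provenance = "VE-PE"
    else:
        raise ValueError(f"unknown combine mode: {mode}")
    return FeatureMask(mask=a.mask | b.mask, provenance=provenance)


def overlap_rate(a: FeatureMask, b: FeatureMask) -> float:
    """100 * |a intersect b| / |a union b| (percent)."""
    if a.mask.shape != b.mask.shape:
        raise ValueError("masks live on different grids")
    union = int((a.mask | b.mask).sum())
    if union == 0:
        raise ValueError("overlap rate undefined: both masks are empty")
    inter = int((a.mask & b.mask).sum())
    return 100.0 * inter / union
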