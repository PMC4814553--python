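"""General linear model fitting, F-contrasts, effects-of-interest adjustment,
and principal-eigenvariate extraction for region-of-interest time series."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design import DesignMatrix


@dataclass
class GLMFit:
    """Least-squares fit of a design matrix to one or more series."""

    beta: np.ndarray           # (K, V)
    resid_var: np.ndarray      # (V,) RSS / dof
    dof: float
    design: DesignMatrix

    @property
    def labels(self) -> tuple[str, ...]:
        return self.design.labels


@dataclass
class VoxelBlock:
    """Voxel series within one spherical ROI."""

    Y: np.ndarray              # (T, V)
    offsets_mm: np.ndarray     # (V, 3) offsets from the sphere center
    radius_mm: float = 8.0

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.offsets_mm = np.asarray(self.offsets_mm, dtype=float)
        if self.Y.ndim != 2 or self.Y.shape[1] < 1:
            raise ValueError("VoxelBlock needs at least one voxel")
        if self.offsets_mm.shape != (self.Y.shape[1], 3):
            raise ValueError("offsets must be (V, 3)")
        r = np.linalg.norm(self.offsets_mm, axis=1)
        if np.any(r > self.radius_mm + 1e-9):
            raise ValueError("voxel offsets exceed the sphere radius")


def fit_glm(Y: np.ndarray, design: DesignMatrix) -> GLMFit:
    """Ordinary least squares via a rank-revealing solve.

    Rank-deficient designs are handled with the pseudo-inverse (minimum-norm
    coefficients) and flagged with a warning.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = design.X
    if Y.shape[0] != X.shape[0]:
        raise ValueError("row counts of data and design must match")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("design matrix is rank deficient; using pseudo-inverse",
                      stacklevel=2)
    beta = np.linalg.pinv(X) @ Y
    resid = Y - X @ beta
    dof = Y.shape[0] - rank
    if dof <= 0:
        raise ValueError("non-positive residual degrees of freedom")
    resid_var = (resid ** 2).sum(axis=0) / dof
    return GLMFit(beta=beta, resid_var=resid_var, dof=float(dof), design=design)


def f_contrast(Y: np.ndarray, fit: GLMFit, contrast: np.ndarray):
    """Extra-sum-of-squares F test of ``contrast @ beta = 0`` per series.

    The reduced model is the full design projected onto the null space of the
    contrast; F = ((RSS0 - RSS1)/r) / (RSS1/dof) with r the contrast rank.
    Returns (F, p) arrays of length V.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    contrast = np.atleast_2d(np.asarray(contrast, dtype=float))
    X = fit.design.X
    if contrast.shape[1] != X.shape[1]:
        raise ValueError("contrast columns must match the design")
    if not contrast.any():
        raise ValueError("contrast must be nonzero")
    r = np.linalg.matrix_rank(contrast)
    # reduced design: columns of X restricted to the contrast's null space
    from scipy.linalg import null_space
    N = null_space(contrast)
    X0 = X @ N if N.size else np.zeros((X.shape[0], 0))
    rss1 = ((Y - X @ np.linalg.pinv(X) @ Y) ** 2).sum(axis=0)
    if X0.shape[1]:
        rss0 = ((Y - X0 @ np.linalg.pinv(X0) @ Y) ** 2).sum(axis=0)
    else:
        rss0 = (Y ** 2).sum(axis=0)
    F = np.where(rss1 > 0, (rss0 - rss1) / r / (rss1 / fit.dof), np.inf)
    F = np.maximum(F, 0.0)  # guard tiny negative round-off
    p = stats.f.sf(F, r, fit.dof)
    return F, p


def effects_of_interest_contrast(design: DesignMatrix, keep) -> np.ndarray:
    """Identity-row contrast spanning the kept regressors."""
    rows = []
    for label in keep:
        if label not in design.labels:
            raise KeyError(f"unknown regressor label: {label}")
        row = np.zeros(len(design.labels))
        row[design.labels.index(label)] = 1.0
        rows.append(row)
    return np.vstack(rows)


def adjust_effects_of_interest(Y: np.ndarray, fit: GLMFit, keep) -> np.ndarray:
    """Remove the variance attributable to all regressors NOT in ``keep``.

    The removed columns are projected out orthogonally, so the adjusted data
    retain the kept task effects and the residuals while being exactly
    orthogonal to motion, press, and other nuisance columns.
    """
    Y = np.asarray(Y, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    keep = set(keep)
    unknown = keep - set(fit.labels)
    if unknown:
        raise KeyError(f"unknown regressor labels: {sorted(unknown)}")
    removed = [l for l in fit.labels if l not in keep]
    if not removed:
        out = Y.copy()
    else:
        X0 = fit.design.columns(removed)
        out = Y - X0 @ (np.linalg.pinv(X0) @ Y)
    return out[:, 0] if squeeze else out


def select_voxels(block: VoxelBlock, fit: GLMFit, contrast: np.ndarray,
                  p_threshold: float = 0.05) -> VoxelBlock:
    """Restrict a sphere to voxels passing an F-test at ``p_threshold``.

    Mirrors defining the extraction cluster by an uncorrected
    effects-of-ambiguity threshold; the p-values play no further role in
    the DCM statistics.  Raises if no voxel survives.
    """
    _, p = f_contrast(block.Y, fit, contrast)
    keep = p < p_threshold
    if not keep.any():
        raise ValueError(f"no voxel passes p < {p_threshold}")
    return VoxelBlock(Y=block.Y[:, keep], offsets_mm=block.offsets_mm[keep],
                      radius_mm=block.radius_mm)


def principal_eigenvariate(block: VoxelBlock) -> tuple[np.ndarray, float]:
    """First singular component of the (centered) voxel block.

    The component is scaled to the root-mean-square amplitude of the block
    and signed to correlate positively with the voxel-mean series.  Returns
    (series, explained-variance fraction).
    """
    Yc = block.Y - block.Y.mean(axis=0, keepdims=True)
    total = (Yc ** 2).sum()
    if total == 0:
        raise ValueError("all-zero voxel block has no eigenvariate")
    U, s, _ = np.linalg.svd(Yc, full_matrices=False)
    e = U[:, 0] * s[0] / np.sqrt(Yc.shape[1])
    mean_series = Yc.mean(axis=1)
    if e @ mean_series < 0:
        e = -e
    explained = float(s[0] ** 2 / total)
    return e, explained
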