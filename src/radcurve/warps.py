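"""Thin-plate-spline bending energy, principal/partial warps and relative warps.

The bending energy matrix is the standard 2D TPS construction at the
consensus: kernel U(r) = r^2 log r^2 (with U(0) = 0) on inter-landmark
distances, L = [[K, Q], [Q', 0]] with Q = [1 | x | y], and the bending energy
matrix B is the upper-left k x k block of L^-1.  B is symmetric positive
semi-definite and annihilates the affine subspace (constant, x and y fields),
so exactly k - 3 eigenvalues are positive for a non-degenerate consensus;
the corresponding eigenvectors are the principal warps.

Partial warp scores are projections of the Procrustes residuals
(aligned - consensus) onto each principal warp, separately in x and y,
giving 2(k - 3) columns; the uniform (affine) component contributes two more
columns when enabled, computed against an orthonormal basis of the affine
deformation space at the consensus with the similarity directions (scaling
and rotation fields) projected out.

The relative warp analysis is a PCA (eigendecomposition of the covariance
matrix) of the column-centered partial warp scores, i.e. the alpha = 0
equal-weighting variant, under which relative warps of the warp scores and
principal components of the affine-free Procrustes residuals coincide.

The alternative kernel r^2 log r rescales every bending-energy eigenvalue by
1/2 but leaves the warp directions, and hence all scores up to that scalar,
unchanged; the r^2 log r^2 convention is used throughout.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .tps_io import LandmarkConfiguration

__all__ = [
    "bending_energy_matrix",
    "principal_warps",
    "uniform_basis",
    "partial_warp_scores",
    "relative_warps",
    "broken_stick",
    "shape_along_axis",
    "RelativeWarps",
]


def _pts(c) -> np.ndarray:
    if isinstance(c, LandmarkConfiguration):
        return c.points
    return np.asarray(c, dtype=float)


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    # U(r) = r^2 ln r^2, with U(0) = 0 by continuity.
    with np.errstate(divide="ignore", invalid="ignore"):
        out = r2 * np.log(r2)
    out[r2 == 0] = 0.0
    return out


def bending_energy_matrix(consensus) -> np.ndarray:
    """k x k thin-plate-spline bending energy matrix at the consensus."""
    c = _pts(consensus)
    k = c.shape[0]
    diff = c[:, None, :] - c[None, :, :]
    r2 = np.sum(diff**2, axis=-1)
    off = r2 + np.eye(k)  # keep diagonal out of the duplicate check
    if np.any(off < 1e-24):
        i, j = np.argwhere((off < 1e-24)).T
        raise ValueError(f"duplicate landmarks at indices ({i[0]}, {j[0]})")
    K = _tps_kernel(r2)
    Q = np.column_stack([np.ones(k), c[:, 0], c[:, 1]])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    try:
        Linv = np.linalg.inv(L)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular TPS system (collinear or duplicate landmarks)") from exc
    B = Linv[:k, :k]
    return 0.5 * (B + B.T)  # enforce exact symmetry


def principal_warps(B: np.ndarray, tol_factor: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
    """Positive-eigenvalue eigenpairs of the bending energy matrix.

    Returns ``(eigenvalues, warps)`` with eigenvalues ascending (largest-scale
    warp first) and warps as orthonormal columns.
    """
    vals, vecs = np.linalg.eigh(B)
    thresh = max(np.max(np.abs(vals)), 1.0) * tol_factor
    keep = vals > thresh
    return vals[keep], vecs[:, keep]


def uniform_basis(consensus) -> np.ndarray:
    """Orthonormal basis (2k x 2) of the uniform shape subspace at the consensus.

    The affine deformation fields (x,0), (y,0), (0,x), (0,y), evaluated at the
    centered unit-size consensus, span 4 dimensions; projecting out the
    similarity directions (the scaling field (x,y) and rotation field (-y,x))
    leaves the 2-dimensional uniform component.  Signs are fixed so the
    largest-magnitude entry of each basis vector is positive.
    """
    c = center_unit(_pts(consensus))
    x, y = c[:, 0], c[:, 1]
    k = c.shape[0]

    def flat(fx, fy):
        v = np.column_stack([fx, fy]).reshape(-1)
        return v

    scale = flat(x, y)
    rot = flat(-y, x)
    sim = np.column_stack([scale / np.linalg.norm(scale), rot / np.linalg.norm(rot)])
    affine = np.column_stack(
        [flat(x, np.zeros(k)), flat(y, np.zeros(k)), flat(np.zeros(k), x), flat(np.zeros(k), y)]
    )
    proj = affine - sim @ (sim.T @ affine)
    u, s, _ = np.linalg.svd(proj, full_matrices=False)
    basis = u[:, :2]
    for j in range(2):
        col = basis[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            basis[:, j] = -col
    return basis


def center_unit(pts: np.ndarray) -> np.ndarray:
    centered = pts - pts.mean(axis=0)
    return centered / np.sqrt(np.sum(centered**2))


def partial_warp_scores(
    aligned: np.ndarray,
    consensus,
    warps: np.ndarray | None = None,
    include_uniform: bool = True,
) -> np.ndarray:
    """Project Procrustes residuals onto the principal warps (x and y
    separately), appending the two uniform-component columns when enabled.

    Column layout: (warp_1 x, warp_1 y, warp_2 x, warp_2 y, ..., u1, u2).
    """
    c = _pts(consensus)
    X = np.asarray(aligned, dtype=float)
    if X.shape[1] != c.shape[0]:
        raise ValueError("basis/consensus landmark count mismatch with aligned data")
    if warps is None:
        _, warps = principal_warps(bending_energy_matrix(c))
    res = X - c[None]
    sx = np.einsum("nkd,kw->nwd", res, warps)  # (n, n_warps, 2)
    n, w = sx.shape[0], sx.shape[1]
    scores = sx.reshape(n, 2 * w)
    if include_uniform:
        ub = uniform_basis(c)
        flat = res.reshape(n, -1)
        scores = np.column_stack([scores, flat @ ub])
    return scores


def relative_warps(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of the column-centered score matrix via the covariance eigenproblem.

    Returns ``(rw_scores, loadings, variance_proportions)`` in descending
    eigenvalue order; each loading's largest-magnitude entry is positive so
    output is reproducible across eigensolvers.
    """
    S = np.asarray(scores, dtype=float)
    n = S.shape[0]
    if n < 3:
        raise ValueError("relative warp analysis needs at least 3 specimens")
    centered = S - S.mean(axis=0)
    cov = centered.T @ centered / (n - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    for j in range(vecs.shape[1]):
        col = vecs[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            vecs[:, j] = -col
    total = vals.sum()
    props = vals / total if total > 0 else vals
    return centered @ vecs, vecs, props


def broken_stick(S: int) -> np.ndarray:
    """Broken-stick expected variance proportions: E(p_k) = (1/S) sum_{i>=k} 1/i."""
    if S < 1:
        raise ValueError("S must be >= 1")
    inv = 1.0 / np.arange(1, S + 1)
    return np.cumsum(inv[::-1])[::-1] / S


def shape_along_axis(
    consensus,
    loadings: np.ndarray,
    axis: int,
    score_value: float,
    warps: np.ndarray | None = None,
    include_uniform: bool = True,
) -> np.ndarray:
    """Reconstruct the outline at a given score along one relative-warp axis.

    Maps the axis loading from partial-warp score space back to landmark
    coordinates through the (orthonormal) warp and uniform bases; linear in
    ``score_value`` and exactly the consensus at 0.
    """
    c = _pts(consensus)
    k = c.shape[0]
    if warps is None:
        _, warps = principal_warps(bending_energy_matrix(c))
    if not 0 <= axis < loadings.shape[1]:
        raise IndexError("axis out of range")
    load = loadings[:, axis]
    w = warps.shape[1]
    nonuni = load[: 2 * w].reshape(w, 2)
    disp = np.einsum("kw,wd->kd", warps, nonuni)
    if include_uniform:
        ub = uniform_basis(c)
        disp = disp + (ub @ load[2 * w :]).reshape(k, 2)
    return c + score_value * disp


class RelativeWarps(BaseEstimator, TransformerMixin):
    """Relative warp analysis as an sklearn-style decomposition.

    Fit on superimposed configurations (an (n, k, 2) array); the bending
    energy basis is computed at the supplied consensus (or the re-normalized
    mean of the input).  ``transform`` maps configurations to relative-warp
    scores; equal (alpha = 0) weighting of partial warps throughout.

    Parameters
    ----------
    include_uniform : bool — append the two uniform-component columns.

    Attributes
    ----------
    consensus_ : (k, 2); bending_energy_ : (k, k);
    eigenvalues_ : (k-3,) bending-energy eigenvalues (ascending);
    principal_warps_ : (k, k-3) orthonormal eigenvectors;
    partial_warp_scores_ : (n, 2(k-3) [+2]);
    mean_scores_ : column means used for centering;
    loadings_ : axis directions in score space (columns);
    scores_ : training relative-warp scores;
    explained_variance_ratio_ : per-axis variance proportions.
    """

    def __init__(self, include_uniform: bool = True):
        self.include_uniform = include_uniform

    def fit(self, X, y=None, consensus=None):
        X = np.asarray(X, dtype=float)
        if consensus is None:
            consensus = center_unit(X.mean(axis=0))
        else:
            consensus = _pts(consensus)
        self.consensus_ = consensus
        self.bending_energy_ = bending_energy_matrix(consensus)
        self.eigenvalues_, self.principal_warps_ = principal_warps(self.bending_energy_)
        pw = partial_warp_scores(
            X, consensus, warps=self.principal_warps_, include_uniform=self.include_uniform
        )
        self.partial_warp_scores_ = pw
        self.mean_scores_ = pw.mean(axis=0)
        self.scores_, self.loadings_, self.explained_variance_ratio_ = relative_warps(pw)
        return self

    def transform(self, X):
        if not hasattr(self, "loadings_"):
            raise RuntimeError("RelativeWarps is not fitted")
        pw = partial_warp_scores(
            np.asarray(X, dtype=float),
            self.consensus_,
            warps=self.principal_warps_,
            include_uniform=self.include_uniform,
        )
        return (pw - self.mean_scores_) @ self.loadings_

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, **fit_params).scores_

    def shape_along_axis(self, axis: int, score_value: float) -> np.ndarray:
        return shape_along_axis(
            self.consensus_,
            self.loadings_,
            axis,
            score_value,
            warps=self.principal_warps_,
            include_uniform=self.include_uniform,
        )

    def broken_stick_expectation(self) -> np.ndarray:
        """Broken-stick expectations over the non-trivial axes."""
        S = int(np.sum(self.explained_variance_ratio_ > 1e-12))
        exp = np.zeros_like(self.explained_variance_ratio_)
        exp[:S] = broken_stick(S)
        return exp
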