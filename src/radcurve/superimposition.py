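"""Partial Procrustes generalized superimposition with semi-landmark sliding.

Partial superimposition removes translation (centering at the origin),
isometric size (centroid size fixed at 1) and orientation (least-squares
rotation, no reflection).  The consensus is the mean shape minimizing the sum
of squared partial Procrustes distances; it is found by the usual iterative
scheme: align everything to the current consensus, recompute the consensus as
the re-normalized coordinate-wise mean, repeat until the consensus stops
moving.

Semi-landmarks are slid along their tangent directions so that the thin-plate
spline deformation from the consensus to each specimen has minimum bending
energy.  Tangents are cyclic central differences on the closed outline of the
specimen's current configuration; the fixed landmark participates as a
neighbor but never slides.  The sliding amounts solve a small linear system
(the bending-energy quadratic form is exactly quadratic in the amounts), so a
single pass reaches the tangent-space optimum.

Reflections are never allowed: sides are standardized by mirroring at load
time, so the rotation fit is a pure rotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .tps_io import LandmarkConfiguration

__all__ = [
    "centroid_size",
    "center_and_scale",
    "align_pair",
    "procrustes_distance",
    "gpa",
    "slide_semilandmarks",
    "GPAResult",
    "GeneralizedProcrustesAnalysis",
]


class DegenerateConfigurationError(ValueError):
    """All landmarks coincide: the configuration has no shape."""


def _as_points(c) -> np.ndarray:
    if isinstance(c, LandmarkConfiguration):
        return c.points
    return np.asarray(c, dtype=float)


def centroid_size(c) -> float:
    """Square root of the summed squared distances of landmarks from their centroid."""
    pts = _as_points(c)
    centered = pts - pts.mean(axis=0)
    return float(np.sqrt(np.sum(centered**2)))


def center_and_scale(c) -> np.ndarray:
    """Center at the origin and scale centroid size to 1."""
    pts = _as_points(c)
    centered = pts - pts.mean(axis=0)
    cs = np.sqrt(np.sum(centered**2))
    if cs == 0.0:
        raise DegenerateConfigurationError(
            "all landmarks coincide; configuration cannot be scaled"
        )
    return centered / cs


def _rotation_stats(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Sufficient statistics for the optimal rotation of b onto a.

    Rotating b by theta = atan2(S2, S1) maximizes the inner product with a.
    """
    s1 = float(np.sum(a * b))
    s2 = float(np.sum(a[:, 1] * b[:, 0] - a[:, 0] * b[:, 1]))
    return s1, s2


def _rotate(pts: np.ndarray, theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    return pts @ rot.T


def align_pair(a, b) -> tuple[float, np.ndarray, float]:
    """Optimally rotate the normalized ``b`` onto the normalized ``a``.

    Returns ``(theta, b_rotated, distance)`` where theta is the rotation
    applied to b (closed-form 2D orthogonal fit, rotation only) and distance
    the partial Procrustes distance sqrt(sum of squared differences).
    """
    a = _as_points(a)
    b = _as_points(b)
    if a.shape != b.shape:
        raise ValueError(f"landmark count mismatch: {a.shape} vs {b.shape}")
    a = center_and_scale(a)
    b = center_and_scale(b)
    s1, s2 = _rotation_stats(a, b)
    theta = float(np.arctan2(s2, s1))
    b_rot = _rotate(b, theta)
    # Direct difference norm: accurate for near-identical shapes, where the
    # chord form sqrt(2 - 2 cos) would lose half the working precision.
    dist = float(np.linalg.norm(a - b_rot))
    return theta, b_rot, dist


def procrustes_distance(a, b) -> float:
    """Partial Procrustes distance: normalize both, optimal rotation, RMS root."""
    return align_pair(a, b)[2]


def _normalize_stack(X: np.ndarray) -> np.ndarray:
    centered = X - X.mean(axis=1, keepdims=True)
    cs = np.sqrt(np.sum(centered**2, axis=(1, 2), keepdims=True))
    if np.any(cs == 0):
        raise DegenerateConfigurationError("degenerate configuration in input")
    return centered / cs


def _align_stack(X: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotate each normalized configuration in X onto the normalized target."""
    s1 = np.einsum("nkd,kd->n", X, target)
    s2 = np.einsum("nk,k->n", X[:, :, 0], target[:, 1]) - np.einsum(
        "nk,k->n", X[:, :, 1], target[:, 0]
    )
    theta = np.arctan2(s2, s1)
    c, s = np.cos(theta), np.sin(theta)
    out = np.empty_like(X)
    out[:, :, 0] = c[:, None] * X[:, :, 0] - s[:, None] * X[:, :, 1]
    out[:, :, 1] = s[:, None] * X[:, :, 0] + c[:, None] * X[:, :, 1]
    return out


def _distances_to(X: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Partial Procrustes distances of each (normalized) row to the target."""
    rotated = _align_stack(X, target)
    return np.sqrt(np.sum((rotated - target[None]) ** 2, axis=(1, 2)))


@dataclass
class GPAResult:
    consensus: np.ndarray  # (k, 2), centroid 0, centroid size 1
    aligned: np.ndarray  # (n, k, 2), each centroid 0 and size 1
    distances: np.ndarray  # (n,)
    iterations: int
    converged: bool
    slid: bool = False
    fixed_index: int = 0
    slide_energy_log: list = field(default_factory=list)  # (before, after) per pass


def _gpa_core(
    X: np.ndarray, tol: float, max_iter: int, consensus: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, int, bool]:
    X = _normalize_stack(X)
    if consensus is None:
        consensus = _normalize_stack(X.mean(axis=0)[None])[0]
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        X = _align_stack(X, consensus)
        new = _normalize_stack(X.mean(axis=0)[None])[0]
        rms = float(np.sqrt(np.mean((new - consensus) ** 2)))
        consensus = new
        if rms < tol:
            converged = True
            break
    X = _align_stack(X, consensus)
    return consensus, X, iterations, converged


def _canonicalize(consensus: np.ndarray, X: np.ndarray, fixed_index: int):
    """Rotate everything so the consensus fixed landmark lies on the +x axis.

    Makes the output invariant (not merely equivariant) under a common
    rotation of the raw data.
    """
    v = consensus[fixed_index]
    theta = -float(np.arctan2(v[1], v[0]))
    consensus = _rotate(consensus, theta)
    c, s = np.cos(theta), np.sin(theta)
    out = np.empty_like(X)
    out[:, :, 0] = c * X[:, :, 0] - s * X[:, :, 1]
    out[:, :, 1] = s * X[:, :, 0] + c * X[:, :, 1]
    return consensus, out


def gpa(
    records,
    slide: bool = False,
    tol: float = 1e-8,
    max_iter: int = 100,
    n_slide_cycles: int = 3,
    fixed_index: int = 0,
) -> GPAResult:
    """Generalized partial Procrustes analysis, optionally with semi-landmark
    sliding interleaved (``n_slide_cycles`` passes of slide -> re-GPA, then a
    final GPA).

    ``records`` may be an (n, k, 2) array or a sequence of configurations /
    SpecimenRecords.
    """
    X = _coerce_stack(records)
    n, k = X.shape[0], X.shape[1]
    if n < 2:
        raise ValueError("GPA needs at least 2 specimens")
    consensus, aligned, iterations, converged = _gpa_core(X, tol, max_iter)
    energy_log: list[tuple[float, float]] = []
    if slide:
        from .warps import bending_energy_matrix  # local import: no cycle at module load

        if k < 4:
            raise ValueError("sliding requires k >= 4 (bending energy nontrivial)")
        for _ in range(n_slide_cycles):
            B = bending_energy_matrix(consensus)
            slid, before, after = slide_semilandmarks(
                aligned, consensus, fixed_index=fixed_index, bending=B
            )
            energy_log.append((before, after))
            consensus, aligned, it2, conv2 = _gpa_core(
                slid, tol, max_iter, consensus=consensus
            )
            iterations += it2
            converged = conv2
    if not converged:
        warnings.warn(f"GPA did not converge within {max_iter} iterations")
    consensus, aligned = _canonicalize(consensus, aligned, fixed_index)
    distances = _distances_to(aligned, consensus)
    return GPAResult(
        consensus=consensus,
        aligned=aligned,
        distances=distances,
        iterations=iterations,
        converged=converged,
        slid=slide,
        fixed_index=fixed_index,
        slide_energy_log=energy_log,
    )


def _coerce_stack(records) -> np.ndarray:
    if isinstance(records, np.ndarray):
        return np.asarray(records, dtype=float)
    from .tps_io import SpecimenRecord, stack_configurations

    seq = list(records)
    if seq and isinstance(seq[0], SpecimenRecord):
        return stack_configurations(seq)
    return np.stack([_as_points(c) for c in seq], axis=0)


def _tangents(pts: np.ndarray) -> np.ndarray:
    """Unit tangents by cyclic central differences on the closed outline."""
    diff = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    norms = np.linalg.norm(diff, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return diff / norms


def bending_energy_of(residual: np.ndarray, B: np.ndarray) -> float:
    """Quadratic-form bending energy of a (k, 2) displacement field."""
    return float(residual[:, 0] @ B @ residual[:, 0] + residual[:, 1] @ B @ residual[:, 1])


def slide_semilandmarks(
    aligned: np.ndarray,
    consensus: np.ndarray,
    fixed_index: int = 0,
    bending: np.ndarray | None = None,
    renormalize: bool = True,
) -> tuple[np.ndarray, float, float]:
    """Slide every semi-landmark along its tangent to minimize the bending
    energy of the deformation from the consensus.

    For each specimen with configuration y, tangent matrix U (one column per
    semi-landmark, supported on that landmark's x/y rows), the sliding vector
    t minimizes (y + U t - c)' (B (x) I2) (y + U t - c); the normal equations
    are solved directly, with a ridge fallback (eps = 1e-10) when singular.
    The fixed landmark never moves.  Returns (slid, total energy before,
    total energy after), energies evaluated before any re-normalization.
    """
    X = np.asarray(aligned, dtype=float)
    consensus = np.asarray(consensus, dtype=float)
    n, k = X.shape[0], X.shape[1]
    if bending is None:
        from .warps import bending_energy_matrix

        bending = bending_energy_matrix(consensus)
    B = bending
    semi = np.array([j for j in range(k) if j != fixed_index])
    total_before = 0.0
    total_after = 0.0
    slid = np.empty_like(X)
    for i in range(n):
        y = X[i]
        res = y - consensus
        total_before += bending_energy_of(res, B)
        tan = _tangents(y)[semi]  # (k-1, 2) tangents of the current configuration
        # Normal equations assembled on the k x k form, exploiting the
        # block-diagonal (B (x) I2) structure: column j of U touches only
        # landmark semi[j], so U' B2 U = tan-weighted B sub-blocks.
        Bss = B[np.ix_(semi, semi)]
        A = (tan @ tan.T) * Bss  # actually sum over d of tan_jd tan_ld B_jl
        rhs = -(tan * (B[semi] @ res)).sum(axis=1)
        try:
            t = np.linalg.solve(A, rhs)
            if not np.all(np.isfinite(t)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            warnings.warn("singular sliding system; using ridge-regularized solve")
            t = np.linalg.solve(A + 1e-10 * np.eye(len(semi)), rhs)
        y_new = y.copy()
        y_new[semi] += t[:, None] * tan
        total_after += bending_energy_of(y_new - consensus, B)
        slid[i] = y_new
    if renormalize:
        slid = _normalize_stack(slid)
    return slid, total_before, total_after


class GeneralizedProcrustesAnalysis(BaseEstimator, TransformerMixin):
    """Partial Procrustes superimposition as an sklearn-style transformer.

    Parameters
    ----------
    slide : bool
        Interleave minimum-bending-energy sliding of semi-landmarks.
    tol : float
        RMS consensus-change convergence tolerance.
    max_iter : int
        Iteration cap per GPA phase.
    n_slide_cycles : int
        Number of slide -> re-GPA cycles when sliding.
    fixed_index : int
        Index of the fixed (non-sliding) landmark.

    Attributes
    ----------
    consensus_ : (k, 2) ndarray — mean shape, centroid size 1.
    aligned_ : (n, k, 2) ndarray — training configurations in superimposition.
    distances_ : (n,) ndarray — partial Procrustes distances to the consensus.
    n_iter_ : int;  converged_ : bool;  slide_energy_log_ : list of (pre, post).
    """

    def __init__(
        self,
        slide: bool = False,
        tol: float = 1e-8,
        max_iter: int = 100,
        n_slide_cycles: int = 3,
        fixed_index: int = 0,
    ):
        self.slide = slide
        self.tol = tol
        self.max_iter = max_iter
        self.n_slide_cycles = n_slide_cycles
        self.fixed_index = fixed_index

    def fit(self, X, y=None):
        result = gpa(
            X,
            slide=self.slide,
            tol=self.tol,
            max_iter=self.max_iter,
            n_slide_cycles=self.n_slide_cycles,
            fixed_index=self.fixed_index,
        )
        self.result_ = result
        self.consensus_ = result.consensus
        self.aligned_ = result.aligned
        self.distances_ = result.distances
        self.n_iter_ = result.iterations
        self.converged_ = result.converged
        self.slide_energy_log_ = result.slide_energy_log
        return self

    def transform(self, X):
        """Align new configurations to the fitted consensus (no re-sliding)."""
        if not hasattr(self, "consensus_"):
            raise RuntimeError("GeneralizedProcrustesAnalysis is not fitted")
        stack = _normalize_stack(_coerce_stack(X))
        return _align_stack(stack, self.consensus_)

    def fit_transform(self, X, y=None):
        return self.fit(X).aligned_
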