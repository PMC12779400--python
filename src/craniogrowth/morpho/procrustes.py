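"""Generalized Procrustes analysis (GPA).

Superimposition follows the convention of standard geometric-morphometrics
software: configurations are centred, scaled to unit centroid size, and
iteratively rotated to the evolving consensus until the consensus stabilises;
aligned coordinates are then projected orthogonally onto the tangent space at
the consensus.  Rotations are proper (determinant +1); reflections are never
introduced by the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import LandmarkConfiguration, stack_coords

__all__ = [
    "centroid_size",
    "optimal_rotation",
    "tangent_project",
    "ProcrustesModel",
    "gpa",
]


def centroid_size(coords: np.ndarray | LandmarkConfiguration) -> float:
    """Centroid size: sqrt of summed squared distances of landmarks from their centroid.

    This is the standard size measure of geometric morphometrics; it scales
    linearly under uniform scaling and is invariant to rotation/translation.

    Raises
    ------
    ValueError
        If fewer than two distinct points (size would be 0, which breaks
        unit-size normalisation downstream).
    """
    if isinstance(coords, LandmarkConfiguration):
        coords = coords.coords
    x = np.asarray(coords, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least two landmarks")
    centred = x - x.mean(axis=0)
    cs = float(np.sqrt((centred**2).sum()))
    if cs == 0.0:
        raise ValueError("all landmarks coincide; centroid size is zero")
    return cs


def optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R minimising ||source @ R - target||_F.

    Solved by SVD of ``source.T @ target`` with a determinant correction so
    that R is always a rotation (no reflection), as required when landmark
    configurations have a fixed handedness.
    """
    u, _, vt = np.linalg.svd(source.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    if d < 0:
        u = u.copy()
        u[:, -1] *= -1.0
    return u @ vt


def _centre_scale(x: np.ndarray) -> tuple[np.ndarray, float]:
    centred = x - x.mean(axis=0)
    cs = np.sqrt((centred**2).sum())
    if cs == 0.0:
        raise ValueError("zero centroid size")
    return centred / cs, float(cs)


def tangent_project(aligned: np.ndarray, mean_shape: np.ndarray) -> np.ndarray:
    """Orthogonal projection of aligned shapes onto the tangent space at the mean.

    ``aligned`` is (n, k, 3); the mean has unit centroid size so its flattened
    vector has unit norm.  The projection is affine-idempotent:
    ``y = x - (x . m - 1) m``.
    """
    m = mean_shape.ravel()
    m = m / np.linalg.norm(m)
    flat = aligned.reshape(aligned.shape[0], -1)
    coeff = flat @ m - 1.0
    return (flat - np.outer(coeff, m)).reshape(aligned.shape)


@dataclass
class ProcrustesModel:
    """Fitted GPA superimposition.

    Attributes
    ----------
    mean_shape : (k, 3) array
        Consensus, unit centroid size.
    aligned : (n, k, 3) array
        Tangent-projected aligned coordinates.
    centroid_sizes : (n,) array, mm
    log_cs : (n,) array
    n_iterations : int
    mean_change : float
        Final change in consensus between iterations.
    """

    mean_shape: np.ndarray
    aligned: np.ndarray
    centroid_sizes: np.ndarray
    log_cs: np.ndarray
    n_iterations: int
    mean_change: float
    #: aligned coordinates before tangent projection (unit centroid size)
    rotated: np.ndarray | None = None

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    def flat_aligned(self) -> np.ndarray:
        return self.aligned.reshape(self.n_specimens, -1)


def _gpa_arrays(
    shapes: np.ndarray, tol: float = 1e-10, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, float]:
    """Core GPA on an (n, k, 3) stack. Returns (mean, aligned, cs, iters, change)."""
    n = shapes.shape[0]
    scaled = np.empty_like(shapes, dtype=float)
    sizes = np.empty(n)
    for i in range(n):
        scaled[i], sizes[i] = _centre_scale(shapes[i])
        if np.linalg.matrix_rank(scaled[i], tol=1e-9) < 3:
            raise ValueError(f"configuration {i} is degenerate (rank < 3)")
    mean = scaled[0].copy()
    change = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(n):
            scaled[i] = scaled[i] @ optimal_rotation(scaled[i], mean)
        new_mean = scaled.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        new_mean /= np.sqrt((new_mean**2).sum())
        change = float(np.sqrt(((new_mean - mean) ** 2).sum()))
        mean = new_mean
        if change < tol:
            break
    else:
        raise RuntimeError(
            f"GPA did not converge in {max_iter} iterations (last change {change:.3e})"
        )
    return mean, scaled, sizes, it, change


def canonical_frame(mean: np.ndarray) -> np.ndarray:
    """Deterministic principal-axes rotation for a centred configuration.

    Axes are ordered by decreasing variance; each of the first two axes has
    its sign fixed by the third moment of the coordinates along it (falling
    back to the largest-coordinate rule when the skew is negligible); the
    third completes a right-handed frame.  Rotating the consensus into this
    frame makes aligned coordinates invariant under rigid motions of the
    whole input sample.
    """
    cov = mean.T @ mean
    w, vecs = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    axes = vecs[:, order]
    cols = []
    for j in range(2):
        a = axes[:, j]
        proj = mean @ a
        skew = (proj**3).sum()
        if abs(skew) < 1e-12:
            k = int(np.argmax(np.abs(proj)))
            skew = proj[k]
        cols.append(a if skew >= 0 else -a)
    cols.append(np.cross(cols[0], cols[1]))
    return np.column_stack(cols)


def gpa(
    sample: list[LandmarkConfiguration] | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> ProcrustesModel:
    """Generalized Procrustes superimposition of a sample.

    Parameters
    ----------
    sample : list of LandmarkConfiguration or (n, k, 3) array
    tol : float
        Convergence threshold on the Frobenius change of the consensus.
    max_iter : int

    Returns
    -------
    ProcrustesModel
        With tangent-projected aligned coordinates.
    """
    shapes = sample if isinstance(sample, np.ndarray) else stack_coords(sample)
    if shapes.shape[0] < 2:
        raise ValueError("GPA needs at least two configurations")
    mean, scaled, sizes, it, change = _gpa_arrays(shapes, tol=tol, max_iter=max_iter)
    frame = canonical_frame(mean)
    mean = mean @ frame
    scaled = scaled @ frame
    aligned = tangent_project(scaled, mean)
    return ProcrustesModel(
        mean_shape=mean,
        aligned=aligned,
        centroid_sizes=sizes,
        log_cs=np.log(sizes),
        n_iterations=it,
        mean_change=change,
        rotated=scaled,
    )
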