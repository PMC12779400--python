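"""Object-symmetry decomposition of bilaterally symmetric configurations.

A configuration with object symmetry (midline plus left/right pairs) is
decomposed by joining the sample with its reflected, pair-relabelled copies in
one GPA, then splitting each aligned specimen into a reflection-invariant
(symmetric) component and an asymmetry remainder.  The decomposition is exact
at the coordinate level: the consensus is placed in a frame where the
reflection/relabel operator Q fixes it, making the symmetric and antisymmetric
subspaces orthogonal complements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..scheme import LandmarkScheme
from .config import LandmarkConfiguration, stack_coords
from .procrustes import _gpa_arrays, optimal_rotation, tangent_project

__all__ = ["reflect_relabel", "align_midsagittal", "SymmetricShapeModel", "symmetric_gpa"]

_REFLECT = np.diag([-1.0, 1.0, 1.0])


def reflect_relabel(coords: np.ndarray, scheme: LandmarkScheme) -> np.ndarray:
    """Reflect across the plane x = 0 and swap paired-landmark labels.

    An orthogonal involution on configuration space; applying it twice
    returns the input.
    """
    perm = scheme.relabel_permutation()
    out = coords[..., perm, :] @ _REFLECT
    return out


def _rotation_to_x(normal: np.ndarray) -> np.ndarray:
    """Proper rotation taking ``normal`` to the +x axis."""
    n = normal / np.linalg.norm(normal)
    x = np.array([1.0, 0.0, 0.0])
    v = np.cross(n, x)
    c = float(n @ x)
    s = np.linalg.norm(v)
    if s < 1e-15:
        if c > 0:
            return np.eye(3)
        # 180 degrees about z
        return np.diag([-1.0, -1.0, 1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def align_midsagittal(coords: np.ndarray, scheme: LandmarkScheme) -> np.ndarray:
    """Rotate/translate so the best-fit midline plane maps to x = 0.

    The plane is a total-least-squares fit through the midline landmarks; the
    configuration is rotated so the plane normal lies along x and shifted so
    the plane passes through x = 0.  The sign is fixed so left-labelled
    landmarks have negative mean x.
    """
    mid = coords[list(scheme.midline)]
    c = mid.mean(axis=0)
    _, _, vt = np.linalg.svd(mid - c)
    normal = vt[-1]
    rot = _rotation_to_x(normal)
    left = [l for l, _ in scheme.pairing]
    if ((coords[left] - c) @ rot.T)[:, 0].mean() > 0:
        rot = np.diag([-1.0, -1.0, 1.0]) @ rot  # proper flip about z
    shift = c @ rot.T
    shift[0] = 0.0
    return (coords - c) @ rot.T + shift


@dataclass
class SymmetricShapeModel:
    """GPA of a bilaterally symmetric sample with symmetry decomposition.

    Attributes
    ----------
    mean_shape : (k, 3)
        Consensus of the reflection-doubled sample, exactly invariant under
        reflect/relabel, unit centroid size.
    aligned : (n, k, 3)
        Tangent-projected aligned original configurations.
    symmetric : (n, k, 3)
        Reflection-invariant component per specimen.
    asymmetric : (n, k, 3)
        Remainder; ``symmetric + asymmetric == aligned`` exactly.
    centroid_sizes, log_cs : (n,)
    """

    mean_shape: np.ndarray
    aligned: np.ndarray
    symmetric: np.ndarray
    asymmetric: np.ndarray
    centroid_sizes: np.ndarray
    log_cs: np.ndarray
    scheme: LandmarkScheme
    n_iterations: int
    mean_change: float

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    def flat_symmetric(self) -> np.ndarray:
        return self.symmetric.reshape(self.n_specimens, -1)


def _symmetrize_consensus(mean: np.ndarray, scheme: LandmarkScheme) -> tuple[np.ndarray, np.ndarray]:
    """Rotate the consensus into the midsagittal frame and make it exactly
    Q-invariant.  Returns (symmetric consensus, frame rotation G) with
    ``mean @ G approx consensus``."""
    framed = align_midsagittal(mean, scheme)
    framed = framed - framed.mean(axis=0)
    # recover the rotation actually applied (centring removed any shift)
    g = optimal_rotation(mean - mean.mean(axis=0), framed)
    framed = (mean - mean.mean(axis=0)) @ g
    sym = 0.5 * (framed + reflect_relabel(framed, scheme))
    sym = sym - sym.mean(axis=0)
    sym /= np.sqrt((sym**2).sum())
    # canonicalise the remaining in-plane orientation: rotate about x so the
    # major principal axis of the consensus' (y, z) spread lies along +y
    # (sign fixed by the third moment); rotations about x commute with the
    # reflection/relabel operator, so Q-invariance is preserved
    yz = sym[:, 1:]
    w, vecs = np.linalg.eigh(yz.T @ yz)
    d = vecs[:, -1]
    theta = np.arctan2(d[1], d[0])
    c, s = np.cos(-theta), np.sin(-theta)
    r_x = np.array([[1.0, 0, 0], [0, c, -s], [0, s, c]])
    sym = sym @ r_x.T
    g = g @ r_x.T
    skew = (sym[:, 1] ** 3).sum()
    if abs(skew) < 1e-12:
        skew = sym[int(np.argmax(np.abs(sym[:, 1]))), 1]
    if skew < 0:
        flip = np.diag([1.0, -1.0, -1.0])  # half-turn about x
        sym = sym @ flip
        g = g @ flip
    return sym, g


def symmetric_gpa(
    sample: list[LandmarkConfiguration] | np.ndarray,
    scheme: LandmarkScheme | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> SymmetricShapeModel:
    """GPA with object-symmetry decomposition.

    The sample is doubled with reflected/relabelled copies, superimposed
    jointly, and each aligned original is split into symmetric and asymmetric
    components about the symmetrized consensus.
    """
    if isinstance(sample, np.ndarray):
        shapes = sample
        if scheme is None:
            raise ValueError("scheme required when passing a raw array")
    else:
        shapes = stack_coords(sample)
        if scheme is None:
            scheme = sample[0].scheme
    perm = scheme.relabel_permutation()
    if [perm[i] for i in perm] != list(range(scheme.n_landmarks)):
        raise ValueError("landmark pairing is not involutive")
    n = shapes.shape[0]
    doubled = np.concatenate([shapes, reflect_relabel(shapes, scheme)])
    mean, scaled, sizes, it, change = _gpa_arrays(doubled, tol=tol, max_iter=max_iter)
    mean_s, g = _symmetrize_consensus(mean, scheme)
    # move the whole aligned sample into the symmetric frame, then re-align
    # each original to the (fixed) symmetric consensus
    originals = scaled[:n] @ g
    for i in range(n):
        originals[i] = originals[i] @ optimal_rotation(originals[i], mean_s)
    aligned = tangent_project(originals, mean_s)
    mirrored = reflect_relabel(aligned, scheme)
    symmetric = 0.5 * (aligned + mirrored)
    asymmetric = 0.5 * (aligned - mirrored)
    return SymmetricShapeModel(
        mean_shape=mean_s,
        aligned=aligned,
        symmetric=symmetric,
        asymmetric=asymmetric,
        centroid_sizes=sizes[:n],
        log_cs=np.log(sizes[:n]),
        scheme=scheme,
        n_iterations=it,
        mean_change=change,
    )
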