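"""Multivariate regression of shape on a scalar covariate.

The statistic reported is the "percent predicted": 100 x (sum of squared
fitted values) / (total sum of squares), pooled over all shape coordinates —
the figure standard geometric-morphometrics software prints for a shape-on-
size regression.  Significance is assessed by permuting the covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AllometricRegression", "regress_shape", "nonallometric_residuals", "form_space"]


def _flatten(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 3:
        return coords.reshape(coords.shape[0], -1)
    if coords.ndim == 2:
        return coords
    raise ValueError("coords must be (n, d) or (n, k, 3)")


@dataclass
class AllometricRegression:
    """Fitted multivariate shape-on-covariate regression.

    Attributes
    ----------
    coefficients : (d,) array
        Shape change per unit covariate.
    percent_predicted : float
        100 * SS_fitted / SS_total, in [0, 100].
    permutation_p : float
        (1 + #{permuted >= observed}) / (1 + n_permutations).
    residuals : (n, d) array
        Centered residual shape coordinates.
    regression_scores : (n,) array
        Projection of each centered specimen onto the unit regression vector
        (the univariate score plotted against size).
    mean_ : (d,) array
        Column means of the input coordinates (used to score new specimens).
    covariate_mean : float
    """

    coefficients: np.ndarray
    percent_predicted: float
    permutation_p: float
    n_permutations: int
    seed: int
    residuals: np.ndarray
    regression_scores: np.ndarray
    mean_: np.ndarray
    covariate_mean: float

    @property
    def unit_vector(self) -> np.ndarray:
        norm = np.linalg.norm(self.coefficients)
        if norm == 0:
            return np.zeros_like(self.coefficients)
        return self.coefficients / norm

    def score(self, coords: np.ndarray) -> float:
        """Regression score of a new specimen (flattened to match the fit)."""
        y = np.asarray(coords, dtype=float).ravel()
        if y.shape != self.mean_.shape:
            raise ValueError("specimen dimension does not match regression")
        return float((y - self.mean_) @ self.unit_vector)


def regress_shape(
    coords: np.ndarray,
    covariate: np.ndarray,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> AllometricRegression:
    """Multivariate least squares of shape coordinates on one covariate.

    Parameters
    ----------
    coords : (n, d) or (n, k, 3) array
        Per-specimen shape coordinates (e.g. symmetric Procrustes coords).
    covariate : (n,) array
        E.g. log centroid size or age in days.
    n_permutations : int
        Covariate permutations for the significance test (>= 1).
    seed : int
    """
    y = _flatten(coords)
    x = np.asarray(covariate, dtype=float)
    n = y.shape[0]
    if x.shape != (n,):
        raise ValueError("covariate length must match number of specimens")
    if n < 3:
        raise ValueError("need at least three specimens")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")

    ymean = y.mean(axis=0)
    yc = y - ymean
    xc = x - x.mean()
    sxx = float(xc @ xc)
    beta = (xc @ yc) / sxx
    fitted = np.outer(xc, beta)
    ss_fit = float((fitted**2).sum())
    ss_tot = float((yc**2).sum())
    if ss_tot == 0:
        raise ValueError("shape coordinates have zero variance")
    percent = 100.0 * ss_fit / ss_tot
    residuals = yc - fitted

    # permutation test: percent_predicted is monotone in ||Y'x_p||^2 / Sxx,
    # so permute the covariate and recompute the fitted SS, vectorised
    rng = np.random.default_rng(seed)
    perms = np.empty((n, n_permutations))
    for j in range(n_permutations):
        perms[:, j] = xc[rng.permutation(n)]
    proj = yc.T @ perms  # (d, n_permutations)
    ss_fit_perm = (proj**2).sum(axis=0) / sxx
    n_ge = int(np.count_nonzero(ss_fit_perm >= ss_fit))
    p = (1.0 + n_ge) / (1.0 + n_permutations)

    norm = np.linalg.norm(beta)
    scores = yc @ (beta / norm) if norm > 0 else np.zeros(n)
    return AllometricRegression(
        coefficients=beta,
        percent_predicted=percent,
        permutation_p=p,
        n_permutations=n_permutations,
        seed=seed,
        residuals=residuals,
        regression_scores=scores,
        mean_=ymean,
        covariate_mean=float(x.mean()),
    )


def nonallometric_residuals(reg: AllometricRegression) -> np.ndarray:
    """Residual (non-allometric) shape coordinates of a fitted regression.

    Regress these on age to quantify shape variation not aligned with size;
    the percent predicted of that second regression is computed on the
    residual total sum of squares automatically.
    """
    return reg.residuals


def form_space(shape_coords: np.ndarray, log_cs: np.ndarray) -> np.ndarray:
    """Augment tangent-space shape coordinates with centered log centroid size.

    In form space, size and shape vary jointly; a regression on log CS then
    predicts the size coordinate exactly, so its percent predicted is at
    least the shape-space value.
    """
    flat = _flatten(shape_coords)
    lcs = np.asarray(log_cs, dtype=float)
    if lcs.shape != (flat.shape[0],):
        raise ValueError("log_cs length must match number of specimens")
    return np.column_stack([flat, lcs - lcs.mean()])
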