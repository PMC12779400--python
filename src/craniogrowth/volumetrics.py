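"""Cavalieri (point-counting) stereological volume estimation.

The estimator overlays a square point grid with a uniform random offset on
every k-th section of a label image and counts grid points falling on the
label:

    V_hat = (points counted) x (grid spacing)^2 x (slice step x section thickness)

The estimate is unbiased over grid offsets.  Points are voxel-centre tests:
a grid point counts if the voxel containing it carries the label, which is
exact on label images and needs no interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic.images import LABELS, LabelImage

__all__ = [
    "StereologyParams",
    "VolumeEstimate",
    "cavalieri_volume",
    "default_params_for",
    "window_average",
    "percent_change",
]


@dataclass(frozen=True)
class StereologyParams:
    """Sampling design of the point-counting estimator.

    grid_spacing : mm between grid points in-plane
    slice_step : use every k-th section along ``axis``
    axis : slicing axis (0, 1 or 2)
    seed : stream for the uniform random grid/section offsets
    """

    grid_spacing: float
    slice_step: int = 1
    axis: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        if self.slice_step < 1:
            raise ValueError("slice_step must be >= 1")
        if self.axis not in (0, 1, 2):
            raise ValueError("axis must be 0, 1 or 2")


@dataclass
class VolumeEstimate:
    """One Cavalieri estimate; volume = points x area-per-point x depth."""

    label: str
    volume: float
    points_counted: int
    sections_used: int
    params: StereologyParams
    age_days: float | None = None


def default_params_for(
    image: LabelImage, label: str | None = None, seed: int = 0
) -> StereologyParams:
    """Operating-range defaults: grid pitch 4x the in-plane voxel pitch and a
    slice step sampling >= 10 sections through the structure of interest
    (the whole stack if no label is given)."""
    inplane = [s for a, s in enumerate(image.spacing) if a != 2]
    grid = 4.0 * max(inplane)
    if label is None:
        n_sections = image.data.shape[2]
    else:
        mask = image.data == LABELS[label]
        hit = np.flatnonzero(mask.any(axis=(0, 1)))
        n_sections = int(hit.size) if hit.size else image.data.shape[2]
        # keep the coefficient of error in the few-percent operating range
        # for small structures: do not let the grid be coarser than 1/8 of
        # the structure's in-plane extent
        if hit.size:
            ext_u = np.ptp(np.flatnonzero(mask.any(axis=(1, 2)))) * image.spacing[0]
            ext_v = np.ptp(np.flatnonzero(mask.any(axis=(0, 2)))) * image.spacing[1]
            grid = max(max(inplane), min(grid, min(ext_u, ext_v) / 8.0))
    return StereologyParams(
        grid_spacing=grid,
        slice_step=max(1, n_sections // 10),
        axis=2,
        seed=seed,
    )


def cavalieri_volume(
    image: LabelImage, label: str, params: StereologyParams
) -> VolumeEstimate:
    """Point-counting volume estimate of one label.

    Raises
    ------
    ValueError
        If the label is unknown, or the grid is coarser than the image
        extent (no grid point can land inside).
    """
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}")
    code = LABELS[label]
    ax = params.axis
    inplane_axes = [a for a in range(3) if a != ax]
    sp = np.asarray(image.spacing, float)
    extent = sp * np.asarray(image.data.shape)
    if any(params.grid_spacing > extent[a] for a in inplane_axes):
        raise ValueError("grid_spacing is coarser than the image extent")

    rng = np.random.default_rng(params.seed)
    # uniform random offsets: grid in-plane, and the starting section
    off_u = rng.uniform(0.0, params.grid_spacing)
    off_v = rng.uniform(0.0, params.grid_spacing)
    sec0 = int(rng.integers(0, params.slice_step))

    au, av = inplane_axes
    us = np.arange(off_u, extent[au], params.grid_spacing)
    vs = np.arange(off_v, extent[av], params.grid_spacing)
    iu = np.floor(us / sp[au]).astype(int)
    iv = np.floor(vs / sp[av]).astype(int)
    iu = iu[iu < image.data.shape[au]]
    iv = iv[iv < image.data.shape[av]]
    sections = np.arange(sec0, image.data.shape[ax], params.slice_step)

    # (u, v, section) view; au < av so relative order is preserved
    vol = np.moveaxis(image.data, ax, 2)
    hits = vol[np.ix_(iu, iv, sections)] == code
    points = int(np.count_nonzero(hits))
    a_p = params.grid_spacing**2
    d = params.slice_step * sp[ax]
    return VolumeEstimate(
        label=label,
        volume=points * a_p * d,
        points_counted=points,
        sections_used=len(sections),
        params=params,
        age_days=image.age_days,
    )


def window_average(estimates: list[VolumeEstimate], window: tuple[float, float]) -> float:
    """Mean volume over estimates whose age lies in the closed day window.

    Raises ``ValueError`` if no estimate falls in the window.
    """
    lo, hi = window
    vals = [e.volume for e in estimates if e.age_days is not None and lo <= e.age_days <= hi]
    if not vals:
        raise ValueError(f"no estimates with age in [{lo}, {hi}] days")
    return float(np.mean(vals))


def percent_change(v0: float, v1: float) -> float:
    """100 x (v1 - v0) / v0; raises for non-positive baseline."""
    if v0 <= 0:
        raise ValueError("baseline volume must be positive")
    return 100.0 * (v1 - v0) / v0
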