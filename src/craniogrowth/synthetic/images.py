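"""Synthetic 3D label images with analytically known volumes.

Two label images ("14-day" and "90-day") containing a brain and a masseter
rendered as voxelized ellipsoids whose analytic volumes equal requested
values; the defaults grow the brain by +60 % and the masseter by +35 %
between the two ages, the measured changes the growth simulations target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LabelImage", "LabelImagePair", "generate_label_images", "LABELS"]

LABELS = {"background": 0, "brain": 1, "masseter": 2}

#: Fixed ellipsoid axis ratios (a : b : c) per structure.
_AXIS_RATIOS = {"brain": (1.0, 1.35, 1.1), "masseter": (1.0, 1.6, 2.4)}


@dataclass
class LabelImage:
    """A labelled voxel volume.

    Attributes
    ----------
    data : (nx, ny, nz) uint8 array of label codes
    spacing : mm per voxel along each axis (anisotropy allowed)
    age_days : nominal age of the synthetic scan
    ground_truth : analytic mm^3 per label name
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    age_days: float
    ground_truth: dict[str, float] = field(default_factory=dict)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_count_volume(self, label: str) -> float:
        return float(np.count_nonzero(self.data == LABELS[label]) * self.voxel_volume)


@dataclass
class LabelImagePair:
    """The younger/older image pair with shared geometry rules."""

    young: LabelImage
    old: LabelImage

    def ground_truth_ratio(self, label: str) -> float:
        return self.old.ground_truth[label] / self.young.ground_truth[label]


def _semiaxes_for_volume(volume: float, ratios: tuple[float, float, float]) -> np.ndarray:
    """Solve 4/3 pi a b c = volume with fixed axis ratios."""
    r = np.asarray(ratios, float)
    scale = (volume / (4.0 / 3.0 * np.pi * np.prod(r))) ** (1.0 / 3.0)
    return scale * r


def _render_ellipsoid(
    data: np.ndarray, spacing: np.ndarray, center: np.ndarray, semi: np.ndarray, code: int
) -> None:
    """Voxel-centre rasterisation of an ellipsoid into the label array."""
    lo = np.maximum(((center - semi) / spacing - 1).astype(int), 0)
    hi = np.minimum(((center + semi) / spacing + 2).astype(int), data.shape)
    if np.any(lo >= hi):
        raise ValueError("ellipsoid does not intersect the image")
    ax = [(np.arange(lo[d], hi[d]) + 0.5) * spacing[d] for d in range(3)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    q = (
        ((gx - center[0]) / semi[0]) ** 2
        + ((gy - center[1]) / semi[1]) ** 2
        + ((gz - center[2]) / semi[2]) ** 2
    )
    sub = data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub[q <= 1.0] = code


def generate_label_images(
    volumes_14d: tuple[float, float] = (400_000.0, 3_000.0),
    volumes_90d: tuple[float, float] = (640_000.0, 4_050.0),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    seed: int = 0,
) -> LabelImagePair:
    """Build the paired label images.

    Parameters
    ----------
    volumes_14d, volumes_90d : (brain mm^3, masseter mm^3)
        Defaults: neonatal endocranial volume ~400 cm^3 growing +60 %, a
        ~3 cm^3 masseter growing +35 %.
    spacing : mm per voxel
    seed : jitters the structure centres by a fraction of a voxel so grid
        alignment artefacts differ between images.

    Raises
    ------
    ValueError
        For non-positive volumes or spacing, or structures that would not
        fit in the image.
    """
    if any(v <= 0 for v in (*volumes_14d, *volumes_90d)):
        raise ValueError("requested volumes must be positive")
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be positive")
    sp = np.asarray(spacing, float)
    rng = np.random.default_rng(seed)

    images = []
    for age, (v_brain, v_mass) in ((14.0, volumes_14d), (90.0, volumes_90d)):
        semi_b = _semiaxes_for_volume(v_brain, _AXIS_RATIOS["brain"])
        semi_m = _semiaxes_for_volume(v_mass, _AXIS_RATIOS["masseter"])
        margin = 3.0 * sp
        # brain centred; masseter beside it along x
        size = 2 * semi_b + 2 * margin + np.array([2 * semi_m[0] + 2 * margin[0], 0, 0])
        shape = np.ceil(size / sp).astype(int)
        if np.any(shape > 1200):
            raise ValueError("requested volumes do not fit a reasonable image")
        data = np.zeros(tuple(shape), dtype=np.uint8)
        jitter = rng.uniform(-0.45, 0.45, 3) * sp
        c_brain = margin + semi_b + jitter
        c_mass = c_brain + np.array([semi_b[0] + semi_m[0] + margin[0], 0.0, 0.0])
        _render_ellipsoid(data, sp, c_brain, semi_b, LABELS["brain"])
        _render_ellipsoid(data, sp, c_mass, semi_m, LABELS["masseter"])
        images.append(
            LabelImage(
                data=data,
                spacing=tuple(sp),
                age_days=age,
                ground_truth={"brain": v_brain, "masseter": v_mass},
            )
        )
    return LabelImagePair(young=images[0], old=images[1])
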