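"""Label images and Cavalieri point-counting estimation."""

from __future__ import annotations

import numpy as np
import pytest

from craniogrowth.synthetic.images import LabelImage, generate_label_images
from craniogrowth.volumetrics import (
    StereologyParams,
    cavalieri_volume,
    default_params_for,
    percent_change,
    window_average,
)


class TestLabelImages:
    def test_requested_volumes_achieved_within_voxelization_error(self, label_pair):
        for im in (label_pair.young, label_pair.old):
            for lab in ("brain", "masseter"):
                vc = im.voxel_count_volume(lab)
                assert vc == pytest.approx(im.ground_truth[lab], rel=0.01)

    def test_default_growth_ratios(self, label_pair):
        assert label_pair.ground_truth_ratio("brain") == pytest.approx(1.60)
        assert label_pair.ground_truth_ratio("masseter") == pytest.approx(1.35)

    def test_semiaxes_solved_from_volume(self):
        from craniogrowth.synthetic.images import _AXIS_RATIOS, _semiaxes_for_volume

        semi = _semiaxes_for_volume(350_000.0, _AXIS_RATIOS["brain"])
        assert 4.0 / 3.0 * np.pi * np.prod(semi) == pytest.approx(350_000.0)
        ratios = semi / semi[0]
        assert ratios == pytest.approx(np.array(_AXIS_RATIOS["brain"]))

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            generate_label_images(volumes_14d=(0.0, 3000.0))

    def test_oversized_volume_rejected(self):
        with pytest.raises(ValueError):
            generate_label_images(volumes_14d=(1e12, 3000.0), volumes_90d=(2e12, 4000.0))


def _cube_image(n=32, spacing=1.0):
    data = np.ones((n, n, n), dtype=np.uint8)  # label 1 = brain everywhere
    return LabelImage(
        data=data, spacing=(spacing,) * 3, age_days=0.0, ground_truth={"brain": float(n**3)}
    )


class TestCavalieri:
    def test_filled_cube_aligned_grid_is_exact(self):
        im = _cube_image()
        params = StereologyParams(grid_spacing=1.0, slice_step=1, seed=0)
        est = cavalieri_volume(im, "brain", params)
        assert est.volume == pytest.approx(im.ground_truth["brain"])

    def test_empty_label_gives_zero(self):
        im = _cube_image()
        est = cavalieri_volume(im, "masseter", StereologyParams(grid_spacing=2.0))
        assert est.volume == 0.0
        assert est.points_counted == 0

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown label"):
            cavalieri_volume(_cube_image(), "liver", StereologyParams(grid_spacing=2.0))

    def test_grid_coarser_than_image_rejected(self):
        with pytest.raises(ValueError, match="coarser"):
            cavalieri_volume(_cube_image(8), "brain", StereologyParams(grid_spacing=100.0))

    def test_volume_identity(self, label_pair):
        est = cavalieri_volume(
            label_pair.young, "brain", default_params_for(label_pair.young, "brain", seed=3)
        )
        p = est.params
        assert est.volume == pytest.approx(
            est.points_counted * p.grid_spacing**2 * p.slice_step * label_pair.young.spacing[2]
        )

    def test_unbiased_on_voxelized_ellipsoid(self):
        """Mean over 200 random offsets within 1 % of the analytic volume of
        a (30, 25, 20) mm ellipsoid."""
        semi = np.array([30.0, 25.0, 20.0])
        n = (2 * semi + 6).astype(int)
        ax = [(np.arange(n[d]) + 0.5) - n[d] / 2 for d in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        inside = (gx / semi[0]) ** 2 + (gy / semi[1]) ** 2 + (gz / semi[2]) ** 2 <= 1
        im = LabelImage(
            data=inside.astype(np.uint8), spacing=(1.0, 1.0, 1.0), age_days=0.0,
            ground_truth={"brain": float(inside.sum())},
        )
        analytic = 4.0 / 3.0 * np.pi * np.prod(semi)
        ests = [
            cavalieri_volume(im, "brain", StereologyParams(grid_spacing=4.0, slice_step=4, seed=s)).volume
            for s in range(200)
        ]
        assert np.mean(ests) == pytest.approx(analytic, rel=0.01)

    def test_variance_decreases_with_grid_refinement(self):
        semi = np.array([30.0, 25.0, 20.0])
        n = (2 * semi + 6).astype(int)
        ax = [(np.arange(n[d]) + 0.5) - n[d] / 2 for d in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        inside = (gx / semi[0]) ** 2 + (gy / semi[1]) ** 2 + (gz / semi[2]) ** 2 <= 1
        im = LabelImage(
            data=inside.astype(np.uint8), spacing=(1.0, 1.0, 1.0), age_days=0.0,
            ground_truth={},
        )
        variances = []
        for pitch in (8.0, 4.0, 2.0):
            ests = [
                cavalieri_volume(im, "brain", StereologyParams(grid_spacing=pitch, slice_step=2, seed=s)).volume
                for s in range(120)
            ]
            variances.append(np.var(ests))
        assert variances[0] > variances[1] > variances[2]

    def test_consistency_with_voxel_count_at_native_resolution(self, label_pair):
        """Grid at the voxel pitch with step 1 and aligned offset recovers
        the voxel-count volume exactly."""
        im = label_pair.young
        params = StereologyParams(grid_spacing=im.spacing[0], slice_step=1, seed=12)
        est = cavalieri_volume(im, "brain", params)
        assert est.volume == pytest.approx(im.voxel_count_volume("brain"), rel=5e-3)


class TestAveragesAndChange:
    def _est(self, v, age):
        return type(
            "E", (), {"volume": v, "age_days": age}
        )()

    def test_single_estimate_window(self):
        assert window_average([self._est(10.0, 14)], (12, 16)) == 10.0

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            window_average([self._est(10.0, 50)], (12, 16))

    def test_window_is_closed(self):
        vals = [self._est(1.0, 12.0), self._est(3.0, 16.0), self._est(99.0, 16.01)]
        assert window_average(vals, (12, 16)) == 2.0

    @pytest.mark.parametrize(
        "v0, v1, expected", [(100, 160, 60.0), (100, 100, 0.0), (200, 270, 35.0)]
    )
    def test_percent_change(self, v0, v1, expected):
        assert percent_change(v0, v1) == pytest.approx(expected)

    def test_percent_change_needs_positive_baseline(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 10.0)
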