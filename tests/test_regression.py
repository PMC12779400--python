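"""Multivariate shape regression, residuals, form space, projection."""

from __future__ import annotations

import numpy as np
import pytest

from craniogrowth.morpho import (
    form_space,
    nonallometric_residuals,
    project_specimen,
    regress_shape,
    symmetric_gpa,
)

from conftest import random_rigid_motion


class TestRegressShape:
    def test_exact_linear_shapes_fully_predicted(self, rng):
        n, d = 20, 30
        x = rng.normal(size=n)
        v = rng.normal(size=d)
        y = np.outer(x, v)
        reg = regress_shape(y, x, n_permutations=199, seed=3)
        assert reg.percent_predicted == pytest.approx(100.0, abs=1e-9)
        assert reg.permutation_p == pytest.approx(1.0 / 200.0)

    def test_coefficients_match_normal_equations_oracle(self, rng):
        # 4 specimens x 3 landmarks, solved explicitly
        y = rng.normal(size=(4, 3, 3))
        x = np.array([0.1, 0.9, 1.4, 2.2])
        reg = regress_shape(y, x, n_permutations=9, seed=0)
        yc = y.reshape(4, -1) - y.reshape(4, -1).mean(axis=0)
        xc = x - x.mean()
        beta_oracle = np.linalg.solve(
            np.array([[xc @ xc]]), (xc @ yc)[None]
        )[0]
        assert reg.coefficients == pytest.approx(beta_oracle, rel=1e-12)

    def test_residuals_orthogonal_to_covariate_and_fit(self, rng):
        y = rng.normal(size=(15, 24))
        x = rng.normal(size=15)
        reg = regress_shape(y, x, n_permutations=9, seed=0)
        xc = x - x.mean()
        assert np.max(np.abs(xc @ reg.residuals)) < 1e-10
        fitted = np.outer(xc, reg.coefficients)
        assert abs((fitted * reg.residuals).sum()) < 1e-9

    def test_permutation_null_is_calibrated(self, rng):
        """Type-I error at alpha = 0.05 over many independent null datasets."""
        n, d, n_perm = 16, 9, 199
        rejections = 0
        trials = 400
        for i in range(trials):
            y = rng.normal(size=(n, d))
            x = rng.normal(size=n)
            reg = regress_shape(y, x, n_permutations=n_perm, seed=1000 + i)
            rejections += reg.permutation_p <= 0.05
        rate = rejections / trials
        assert 0.03 <= rate <= 0.07

    def test_constant_covariate_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            regress_shape(rng.normal(size=(5, 6)), np.ones(5))

    def test_zero_permutations_rejected(self, rng):
        with pytest.raises(ValueError):
            regress_shape(rng.normal(size=(5, 6)), np.arange(5.0), n_permutations=0)

    def test_regression_scores_are_projections(self, rng):
        y = rng.normal(size=(10, 12))
        x = rng.normal(size=10)
        reg = regress_shape(y, x, n_permutations=9, seed=0)
        yc = y - y.mean(axis=0)
        assert reg.regression_scores == pytest.approx(yc @ reg.unit_vector, rel=1e-12)


class TestResidualAnalysis:
    def test_pure_size_signal_leaves_null_level_age_percent(self, rng):
        """Shapes exactly linear in size: the residual regression on a
        correlated age covariate stays at its permutation-null level."""
        n, d = 40, 20
        size = rng.normal(size=n)
        age = 0.9 * size + np.sqrt(1 - 0.81) * rng.normal(size=n)
        y = np.outer(size, rng.normal(size=d)) + rng.normal(size=(n, d)) * 0.05
        reg = regress_shape(y, size, n_permutations=9, seed=0)
        resid = nonallometric_residuals(reg)
        reg2 = regress_shape(resid, age, n_permutations=9, seed=1)
        # null oracle: mean percent-predicted when age is permuted
        r = np.random.default_rng(5)
        null = []
        for _ in range(300):
            null.append(
                regress_shape(resid, r.permutation(age), n_permutations=1, seed=0).percent_predicted
            )
        null = np.array(null)
        assert reg2.percent_predicted < null.mean() + 3 * null.std()

    def test_orthogonal_age_effect_recovered(self, rng):
        """An age effect orthogonal to the size effect survives residualising
        and is recovered with high cosine at large n."""
        n, k = 500, 18
        d = 3 * k
        size = rng.normal(size=n)
        age = 0.9 * size + np.sqrt(1 - 0.81) * rng.normal(size=n)
        v = rng.normal(size=d)
        v /= np.linalg.norm(v)
        w = rng.normal(size=d)
        w -= (w @ v) * v
        w /= np.linalg.norm(w)
        xc = size - size.mean()
        ac = age - age.mean()
        a_perp = ac - xc * (xc @ ac) / (xc @ xc)
        y = np.outer(xc, v) + 0.5 * np.outer(a_perp, w) + rng.normal(size=(n, d)) * 0.05
        reg = regress_shape(y, size, n_permutations=1, seed=0)
        reg2 = regress_shape(nonallometric_residuals(reg), age, n_permutations=1, seed=0)
        cos = abs(reg2.unit_vector @ w)
        assert cos > 0.9


class TestFormSpace:
    def test_lncs_coordinate_distance(self, rng):
        shapes = np.stack([rng.normal(size=(6, 3))] * 2)
        lcs = np.array([1.0, 2.0])  # ratio e
        fs = form_space(shapes, lcs)
        assert fs[1, -1] - fs[0, -1] == pytest.approx(1.0)

    def test_degenerate_augmentation_equals_shape_space(self, rng):
        y = rng.normal(size=(10, 9))
        x = rng.normal(size=10)
        fs = form_space(y, np.zeros(10) + 3.7)
        r1 = regress_shape(y, x, n_permutations=9, seed=0)
        r2 = regress_shape(fs, x, n_permutations=9, seed=0)
        assert r2.percent_predicted == pytest.approx(r1.percent_predicted, rel=1e-12)

    def test_form_space_percent_at_least_shape_space(self, scheme, symmetric_base_shape, rng):
        sample = []
        lcs_spread = rng.normal(size=12) * 0.1
        for dl in lcs_spread:
            q, t = random_rigid_motion(rng, scale=float(np.exp(dl)))
            sample.append(
                (symmetric_base_shape + rng.normal(size=symmetric_base_shape.shape) * 0.5)
                @ q.T
                + t
            )
        model = symmetric_gpa(np.stack(sample), scheme)
        r_shape = regress_shape(model.flat_symmetric(), model.log_cs, 9, 0)
        fs = form_space(model.flat_symmetric(), model.log_cs)
        r_form = regress_shape(fs, model.log_cs, 9, 0)
        assert r_form.percent_predicted >= r_shape.percent_predicted


class TestProjection:
    @pytest.fixture()
    def fitted(self, scheme, symmetric_base_shape, rng):
        sample = []
        for _ in range(10):
            q, t = random_rigid_motion(rng, scale=rng.uniform(0.9, 1.2))
            sample.append(
                (symmetric_base_shape + rng.normal(size=symmetric_base_shape.shape) * 0.4)
                @ q.T
                + t
            )
        model = symmetric_gpa(np.stack(sample), scheme)
        reg = regress_shape(model.flat_symmetric(), model.log_cs, 9, 0)
        return np.stack(sample), model, reg

    def test_projecting_the_mean_gives_zero_deviation_and_score(self, fitted):
        sample, model, reg = fitted
        proj = project_specimen(model, model.mean_shape * 150.0, regression=reg)
        assert np.max(np.abs(proj.aligned - model.mean_shape)) < 1e-9
        mean_score = (model.mean_shape.ravel() - reg.mean_) @ reg.unit_vector
        assert proj.regression_score == pytest.approx(mean_score, abs=1e-9)

    def test_projecting_a_sample_member_matches_stored_coordinates(self, fitted):
        sample, model, reg = fitted
        proj = project_specimen(model, sample[4])
        assert np.max(np.abs(proj.aligned - model.symmetric[4])) < 1e-9

    def test_score_linear_along_regression_vector(self, fitted, scheme):
        sample, model, reg = fitted
        base = model.mean_shape.ravel()
        u = reg.unit_vector
        scores = []
        ts = np.array([-0.02, 0.0, 0.015, 0.03])
        for t in ts:
            coords = (base + t * u).reshape(-1, 3) * 200.0
            proj = project_specimen(model, coords, regression=reg)
            scores.append(proj.regression_score)
        scores = np.array(scores)
        slopes = np.diff(scores) / np.diff(ts)
        assert slopes == pytest.approx(np.ones(3), rel=1e-3)

    def test_scheme_mismatch_rejected(self, fitted):
        _, model, _ = fitted
        with pytest.raises(ValueError):
            project_specimen(model, np.zeros((5, 3)))
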