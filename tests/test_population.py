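"""Synthetic landmark population generator and its calibration."""

from __future__ import annotations

import numpy as np
import pytest

from craniogrowth.morpho import gpa, regress_shape, symmetric_gpa
from craniogrowth.morpho.workflow import analyze_population
from craniogrowth.scheme import default_scheme
from craniogrowth.synthetic.population import (
    PopulationParams,
    default_mean_shape,
    effect_vectors,
    generate_landmark_population,
    null_percent_predicted,
)


class TestStructure:
    def test_degenerate_population_is_rigid_copies(self, scheme):
        params = PopulationParams(
            n=5, allometric_fraction=0.0, age_fraction=0.0, cs_range_fraction=0.0,
            noise_sd=0.0, n_replicate_specimens=0, seed=1,
        )
        sample = generate_landmark_population(scheme, params)
        model = gpa(np.stack([c.coords for c in sample.configs]))
        assert np.max(np.abs(model.aligned - model.aligned[0])) < 1e-9

    def test_replicate_bookkeeping(self, scheme):
        params = PopulationParams(n=10, allometric_fraction=0.0, age_fraction=0.0, seed=2)
        sample = generate_landmark_population(scheme, params)
        assert len(sample.primary) == 10
        reps = [c for c in sample.configs if c.replicate > 0]
        assert len(reps) == 5 * 2  # 5 specimens, replicates 1 and 2

    def test_determinism(self, scheme):
        p = PopulationParams(n=8, allometric_fraction=0.0, age_fraction=0.0, seed=9)
        s1 = generate_landmark_population(scheme, p)
        s2 = generate_landmark_population(scheme, p)
        for a, b in zip(s1.configs, s2.configs):
            assert np.array_equal(a.coords, b.coords)

    def test_effect_vectors_structure(self, scheme):
        ms = default_mean_shape()
        v, w = effect_vectors(ms, scheme)
        from craniogrowth.morpho.symmetry import reflect_relabel

        for vec in (v, w):
            assert np.linalg.norm(vec) == pytest.approx(1.0)
            r = reflect_relabel(vec.reshape(-1, 3), scheme).ravel()
            assert np.max(np.abs(r - vec)) < 1e-12
        assert abs(v @ w) < 1e-10
        # orthogonal to similarity directions: translations and scaling
        k = scheme.n_landmarks
        mu = ms - ms.mean(axis=0)
        mu /= np.sqrt((mu**2).sum())
        for a in range(3):
            t = np.zeros((k, 3))
            t[:, a] = 1.0
            assert abs(v @ t.ravel()) < 1e-10
        assert abs(v @ mu.ravel()) < 1e-10

    def test_fraction_below_null_floor_rejected(self, scheme):
        params = PopulationParams(n=12, allometric_fraction=0.5, age_fraction=0.0, seed=0)
        with pytest.raises(ValueError, match="minimum achievable"):
            generate_landmark_population(scheme, params)


class TestRecovery:
    def test_null_population_percent_matches_permutation_oracle(self, scheme):
        """With no effects, the mean percent-predicted equals the permute-x
        oracle within Monte-Carlo error (the estimator's finite-n bias)."""
        params = PopulationParams(
            n=30, allometric_fraction=0.0, age_fraction=0.0, seed=0,
            n_replicate_specimens=0,
        )
        got = []
        oracle = []
        r = np.random.default_rng(8)
        for seed in range(40):
            sample = generate_landmark_population(
                scheme, PopulationParams(
                    n=30, allometric_fraction=0.0, age_fraction=0.0, seed=seed,
                    n_replicate_specimens=0,
                )
            )
            model = symmetric_gpa(np.stack([c.coords for c in sample.configs]), scheme)
            reg = regress_shape(model.flat_symmetric(), model.log_cs, 1, 0)
            got.append(reg.percent_predicted)
            perm = regress_shape(
                model.flat_symmetric(), r.permutation(model.log_cs), 1, 0
            )
            oracle.append(perm.percent_predicted)
        got, oracle = np.array(got), np.array(oracle)
        se = np.sqrt(got.var() / len(got) + oracle.var() / len(oracle))
        assert abs(got.mean() - oracle.mean()) < 4 * se

    @staticmethod
    def _truth_in_model_frame(sample, ana, vec):
        """Rotate a generator-frame effect direction into the fitted
        model's canonical frame before comparing."""
        from craniogrowth.morpho.procrustes import optimal_rotation

        mean = sample.mean_shape - sample.mean_shape.mean(axis=0)
        mean /= np.sqrt((mean**2).sum())
        r = optimal_rotation(mean, ana.model.mean_shape)
        return (vec.reshape(-1, 3) @ r).ravel()

    def test_allometric_direction_recovered_at_large_n(self, scheme):
        params = PopulationParams(n=500, seed=3, n_replicate_specimens=0)
        sample = generate_landmark_population(scheme, params)
        ana = analyze_population(sample.configs, scheme, n_permutations=1)
        truth = self._truth_in_model_frame(sample, ana, sample.allometric_vector)
        cos = abs(ana.size_regression.unit_vector @ truth)
        assert cos > 0.95

    def test_age_direction_recovered_in_residuals_at_large_n(self, scheme):
        params = PopulationParams(n=500, seed=4, n_replicate_specimens=0)
        sample = generate_landmark_population(scheme, params)
        ana = analyze_population(sample.configs, scheme, n_permutations=1)
        truth = self._truth_in_model_frame(sample, ana, sample.age_vector)
        cos = abs(ana.residual_age_regression.unit_vector @ truth)
        assert cos > 0.9

    def test_repeatability_overlay(self, scheme):
        """Replicate landmarkings scatter less than specimens do: the
        within-specimen regression-score variance is below the
        between-specimen variance on default generator settings."""
        from craniogrowth.morpho import project_specimen

        sample = generate_landmark_population(scheme, PopulationParams(seed=5))
        ana = analyze_population(sample.configs, scheme, n_permutations=1)
        scores = {}
        for c in sample.configs:
            s = project_specimen(ana.model, c, regression=ana.size_regression)
            scores.setdefault(c.specimen_id, {})[c.replicate] = s.regression_score
        within = []
        for sid, d in scores.items():
            if len(d) > 1:
                within.append(np.var(list(d.values())))
        between = np.var([d[0] for d in scores.values()])
        assert np.mean(within) < between


def test_null_percent_predicted_scaling(scheme):
    """The null floor of the size regression is near 100/(n-1) scaled by the
    effective share left after the symmetric decomposition."""
    p = PopulationParams(n=25, allometric_fraction=0.0, age_fraction=0.0)
    null1, null2 = null_percent_predicted(p, n_reps=40)
    assert 0.5 * 100 / 24 < null1 < 1.5 * 100 / 24
    assert null2 < null1  # age pre-orthogonalised against size
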