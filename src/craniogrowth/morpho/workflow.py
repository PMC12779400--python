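"""Standard normative analysis: symmetric GPA + allometric regressions.

One entry point used identically by the synthetic-population calibration,
the tests and the pipeline, so the statistic being calibrated is exactly the
statistic being reported: regression of the symmetric shape component on log
centroid size, and of its residuals (the non-allometric variation) on age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..scheme import LandmarkScheme
from .config import LandmarkConfiguration
from .regression import AllometricRegression, form_space, regress_shape
from .symmetry import SymmetricShapeModel, symmetric_gpa

__all__ = ["NormativeAnalysis", "analyze_population"]


@dataclass
class NormativeAnalysis:
    """Fitted shape model plus the allometric / non-allometric regressions."""

    model: SymmetricShapeModel
    size_regression: AllometricRegression  # symmetric shape ~ log CS
    residual_age_regression: AllometricRegression  # residuals ~ age (days)
    form_regression: AllometricRegression | None  # form space ~ log CS
    ages: np.ndarray

    @property
    def percent_allometric(self) -> float:
        return self.size_regression.percent_predicted

    @property
    def percent_residual_age(self) -> float:
        return self.residual_age_regression.percent_predicted


def analyze_population(
    configs: list[LandmarkConfiguration],
    scheme: LandmarkScheme | None = None,
    n_permutations: int = 10_000,
    seed: int = 0,
    include_form: bool = True,
) -> NormativeAnalysis:
    """Run the full normative shape analysis on a landmark sample.

    Replicate landmarkings (replicate != 0) are excluded from the model and
    regressions; they are used only for repeatability overlays.

    Parameters
    ----------
    configs : list of LandmarkConfiguration (with age covariates)
    n_permutations : permutations for both regressions' significance tests
    include_form : also fit the regression in Procrustes form space
    """
    primary = [c for c in configs if c.replicate == 0]
    if any(c.age is None for c in primary):
        raise ValueError("all primary configurations need an age covariate")
    scheme = scheme or primary[0].scheme
    model = symmetric_gpa(primary, scheme)
    ages = np.array([c.age for c in primary], dtype=float)
    nperm = max(1, n_permutations)
    size_reg = regress_shape(model.flat_symmetric(), model.log_cs, nperm, seed)
    resid_reg = regress_shape(size_reg.residuals, ages, nperm, seed + 1)
    form_reg = None
    if include_form:
        fs = form_space(model.flat_symmetric(), model.log_cs)
        form_reg = regress_shape(fs, model.log_cs, nperm, seed + 2)
    return NormativeAnalysis(
        model=model,
        size_regression=size_reg,
        residual_age_regression=resid_reg,
        form_regression=form_reg,
        ages=ages,
    )
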