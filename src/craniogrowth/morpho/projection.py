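"""Read-only projection of new specimens into a fitted shape space.

Simulation results are landmarked automatically (mesh-embedded anchors) and
placed into the normative sample's Procrustes space without refitting the
consensus or the regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import LandmarkConfiguration
from .procrustes import ProcrustesModel, optimal_rotation, tangent_project
from .regression import AllometricRegression
from .symmetry import SymmetricShapeModel, reflect_relabel

__all__ = ["ProjectedSpecimen", "project_specimen"]


@dataclass
class ProjectedSpecimen:
    """A specimen expressed in a fitted model's coordinates."""

    aligned: np.ndarray  # (k, 3) tangent-projected (symmetric if model is)
    centroid_size: float
    log_cs: float
    regression_score: float | None = None

    def flat(self) -> np.ndarray:
        return self.aligned.ravel()


def project_specimen(
    model: ProcrustesModel | SymmetricShapeModel,
    config: LandmarkConfiguration | np.ndarray,
    regression: AllometricRegression | None = None,
    form_log_cs_mean: float | None = None,
) -> ProjectedSpecimen:
    """Center, scale, rotate and (if applicable) symmetrize a specimen into
    the model's tangent space; optionally compute its regression score.

    Parameters
    ----------
    model : ProcrustesModel or SymmetricShapeModel
        Fitted superimposition; not modified.
    config : LandmarkConfiguration or (k, 3) array
    regression : AllometricRegression, optional
        If given, the specimen's regression score is computed with the
        stored sample mean and regression vector (no refit).
    form_log_cs_mean : float, optional
        If the regression was fitted in form space, the training-sample mean
        log CS used to center the size coordinate.
    """
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    if coords.shape != model.mean_shape.shape:
        raise ValueError("specimen does not match the model's landmark scheme")
    centred = coords - coords.mean(axis=0)
    cs = float(np.sqrt((centred**2).sum()))
    if cs == 0:
        raise ValueError("zero centroid size")
    z = centred / cs
    z = z @ optimal_rotation(z, model.mean_shape)
    z = tangent_project(z[None], model.mean_shape)[0]
    if isinstance(model, SymmetricShapeModel):
        # the consensus is Q-invariant, so the reflected/relabelled copy is
        # already aligned; averaging with it gives the symmetric component
        # exactly as in the fitted model
        z = 0.5 * (z + reflect_relabel(z, model.scheme))
    score = None
    if regression is not None:
        vec = z.ravel()
        if regression.mean_.shape[0] == vec.shape[0] + 1:
            if form_log_cs_mean is None:
                raise ValueError("form-space regression requires form_log_cs_mean")
            vec = np.append(vec, np.log(cs) - form_log_cs_mean)
        score = regression.score(vec)
    return ProjectedSpecimen(
        aligned=z, centroid_size=cs, log_cs=float(np.log(cs)), regression_score=score
    )
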