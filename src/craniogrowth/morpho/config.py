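"""Single-specimen landmark configuration."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..scheme import LandmarkScheme


@dataclass
class LandmarkConfiguration:
    """One specimen's landmark coordinates plus covariates.

    Parameters
    ----------
    coords : (k, 3) float array, mm
    scheme : LandmarkScheme
    specimen_id : str
    age : float or None
        Age in days.
    replicate : int
        Replicate-landmarking index; 0 is the primary placement.
    """

    coords: np.ndarray
    scheme: LandmarkScheme
    specimen_id: str = ""
    age: float | None = None
    replicate: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.scheme.n_landmarks, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match scheme "
                f"({self.scheme.n_landmarks} landmarks x 3)"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("landmark coordinates must be finite")

    def copy(self) -> "LandmarkConfiguration":
        return LandmarkConfiguration(
            self.coords.copy(), self.scheme, self.specimen_id, self.age, self.replicate
        )


def stack_coords(configs: list[LandmarkConfiguration]) -> np.ndarray:
    """Stack configurations into an (n, k, 3) array, checking scheme identity."""
    if not configs:
        raise ValueError("empty sample")
    scheme = configs[0].scheme
    for c in configs:
        if c.scheme is not scheme and c.scheme != scheme:
            raise ValueError("all configurations must share one landmark scheme")
    return np.stack([c.coords for c in configs])
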