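"""Min-max scaling between natural units and the network's domain.

Inputs are mapped affinely onto [-1, 1] using the training-data extremes
(for a rotatable CCD these sit at the axial points, coded +/-alpha), so the
scaled input of a coded setting c is simply c/alpha.  The response is mapped
from percent onto [0, 1].  The scaler that was fitted at training time is
stored inside the saved network so predictions always use it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .design import FactorSpec

logger = logging.getLogger(__name__)

__all__ = ["ScalerParams", "scale_input", "unscale_input", "scale_output", "unscale_output"]


@dataclass(frozen=True)
class ScalerParams:
    """Input bounds (actual units) and output bounds (%) for min-max scaling."""

    x_min: np.ndarray
    x_max: np.ndarray
    y_min: float = 0.0
    y_max: float = 100.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "x_min", np.asarray(self.x_min, dtype=float))
        object.__setattr__(self, "x_max", np.asarray(self.x_max, dtype=float))
        if np.any(self.x_max <= self.x_min):
            raise ValueError("x_max must exceed x_min componentwise")
        if not self.y_max > self.y_min:
            raise ValueError("y_max must exceed y_min")

    @classmethod
    def from_factors(cls, factors) -> "ScalerParams":
        """Bounds at the axial extremes of a CCD, the training-data min/max."""
        factors = tuple(factors)
        lo = np.array([f.center - f.axial * f.step for f in factors])
        hi = np.array([f.center + f.axial * f.step for f in factors])
        return cls(x_min=lo, x_max=hi)

    @classmethod
    def from_data(cls, x_actual: np.ndarray) -> "ScalerParams":
        x = np.asarray(x_actual, dtype=float)
        return cls(x_min=x.min(axis=0), x_max=x.max(axis=0))


def scale_input(x, params: ScalerParams) -> np.ndarray:
    """Affine map of actual inputs onto [-1, 1]: 2(x - min)/(max - min) - 1."""
    x = np.asarray(x, dtype=float)
    out = 2.0 * (x - params.x_min) / (params.x_max - params.x_min) - 1.0
    if np.any(np.abs(out) > 1.0 + 1e-12):
        logger.info("input %s scales outside [-1, 1] (extrapolation)", x)
    return out


def unscale_input(x_scaled, params: ScalerParams) -> np.ndarray:
    x_scaled = np.asarray(x_scaled, dtype=float)
    return params.x_min + (x_scaled + 1.0) / 2.0 * (params.x_max - params.x_min)


def scale_output(y, params: ScalerParams | None = None):
    """Map efficiency in % onto [0, 1] (default bounds 0 and 100)."""
    y_min, y_max = (0.0, 100.0) if params is None else (params.y_min, params.y_max)
    return (np.asarray(y, dtype=float) - y_min) / (y_max - y_min)


def unscale_output(y_scaled, params: ScalerParams | None = None):
    y_min, y_max = (0.0, 100.0) if params is None else (params.y_min, params.y_max)
    return y_min + np.asarray(y_scaled, dtype=float) * (y_max - y_min)
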