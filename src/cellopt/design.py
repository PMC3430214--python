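"""Rotatable central composite designs and coded/actual factor transforms.

A central composite design (CCD) for k factors consists of a 2^k full
factorial block at coded levels (+/-1), 2k axial ("star") points at coded
distance alpha along one axis, and replicated centre points.  Factor
settings are handled in *coded* units (dimensionless, centre 0, one unit =
one step) and mapped linearly to *actual* units (percent w/v,
hours, ...) through a :class:`FactorSpec`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FactorSpec",
    "DesignPoint",
    "REFERENCE_FACTORS",
    "generate_ccd",
    "coded_to_actual",
    "actual_to_coded",
]


@dataclass(frozen=True)
class FactorSpec:
    """Geometry of one experimental factor's coded levels.

    The actual value at coded level ``c`` is ``center + c * step``.

    Parameters
    ----------
    name : str
        Factor name, units included (e.g. ``"EDC concentration (% w/v)"``).
    center : float
        Actual value at coded level 0.
    step : float
        Actual units per one coded unit; must be positive.
    axial : float
        Coded distance of the axial (star) points, default 1.68.
    """

    name: str
    center: float
    step: float
    axial: float = 1.68

    def __post_init__(self) -> None:
        if not self.step > 0:
            raise ValueError(f"step must be > 0, got {self.step!r}")
        if not self.axial > 0:
            raise ValueError(f"axial must be > 0, got {self.axial!r}")

    def to_actual(self, coded: float) -> float:
        return self.center + coded * self.step

    def to_coded(self, actual: float) -> float:
        return (actual - self.center) / self.step


#: The three immobilization factors: carbodiimide coupling agent (EDC) and
#: enhancer (NHS) concentrations in % w/v, and coupling time in hours.
#: Axial actual values are kept exact (e.g. 0.40 + 1.68*0.20 = 0.736) and
#: rounded only for display.
REFERENCE_FACTORS: tuple[FactorSpec, ...] = (
    FactorSpec("EDC concentration (% w/v)", center=0.40, step=0.20),
    FactorSpec("NHS concentration (% w/v)", center=0.28, step=0.12),
    FactorSpec("coupling time (h)", center=3.00, step=1.50),
)


@dataclass(frozen=True)
class DesignPoint:
    """One experimental setting in coded and actual units."""

    coded: np.ndarray
    actual: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "coded", np.asarray(self.coded, dtype=float))
        object.__setattr__(self, "actual", np.asarray(self.actual, dtype=float))


def _check_factors(factors) -> tuple[FactorSpec, ...]:
    factors = tuple(factors)
    if len(factors) != 3:
        raise ValueError(f"expected 3 factors, got {len(factors)}")
    return factors


def coded_to_actual(coded, factors=REFERENCE_FACTORS) -> np.ndarray:
    """Map a coded 3-vector to actual factor units (linear, invertible)."""
    factors = _check_factors(factors)
    coded = np.asarray(coded, dtype=float)
    if coded.shape[-1] != 3:
        raise ValueError(f"expected 3 coded levels, got shape {coded.shape}")
    axial = np.array([f.axial for f in factors])
    if np.any(np.abs(coded) > axial + 1e-12):
        logger.info("coded setting %s lies outside the design region (|c| > axial)", coded)
    center = np.array([f.center for f in factors])
    step = np.array([f.step for f in factors])
    return center + coded * step


def actual_to_coded(actual, factors=REFERENCE_FACTORS) -> np.ndarray:
    """Inverse of :func:`coded_to_actual`."""
    factors = _check_factors(factors)
    actual = np.asarray(actual, dtype=float)
    if actual.shape[-1] != 3:
        raise ValueError(f"expected 3 actual values, got shape {actual.shape}")
    center = np.array([f.center for f in factors])
    step = np.array([f.step for f in factors])
    return (actual - center) / step


def generate_ccd(factors=REFERENCE_FACTORS, n_center: int = 6, axial: float = 1.68) -> list[DesignPoint]:
    """Generate the rotatable CCD: factorial, then axial, then centre points.

    Returns ``8 + 6 + n_center`` points for 3 factors, ordered exactly as the
    bundled experimental design matrix: the 2^3 factorial block with the
    first factor varying fastest, the axial pairs (-alpha, +alpha) per axis,
    then ``n_center`` replicates of the origin.
    """
    factors = _check_factors(factors)
    if n_center < 1:
        raise ValueError("n_center must be >= 1")
    rows: list[np.ndarray] = []
    for c in (-1.0, 1.0):
        for b in (-1.0, 1.0):
            for a in (-1.0, 1.0):
                rows.append(np.array([a, b, c]))
    for axis in range(3):
        for sign in (-1.0, 1.0):
            v = np.zeros(3)
            v[axis] = sign * axial
            rows.append(v)
    rows.extend(np.zeros(3) for _ in range(n_center))
    return [
        DesignPoint(coded=r, actual=coded_to_actual(r, factors), label=str(i + 1))
        for i, r in enumerate(rows)
    ]
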