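"""Synthetic CCD experiments from known quadratic response surfaces.

A full quadratic polynomial in coded units stands in for the unknown true
response, because the central composite design is the canonical design for
exactly that model class: recovery failures in end-to-end tests are then
attributable to the network or the search, not to identifiability.
Replicate noise is zero-mean Gaussian; its default standard deviation (5
efficiency points) matches the magnitude of the replicate SDs reported
alongside the bundled experimental table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dataset import Dataset, Trial
from .design import REFERENCE_FACTORS, coded_to_actual, generate_ccd

logger = logging.getLogger(__name__)

__all__ = ["SurfaceSpec", "evaluate_surface", "simulate_ccd", "analytic_optimum"]

_CUBE = ((-1.68, 1.68), (-1.68, 1.68), (-1.68, 1.68))


@dataclass(frozen=True)
class SurfaceSpec:
    """A quadratic truth surface in coded units.

    ``interactions`` holds the (x1*x2, x1*x3, x2*x3) coefficients.  The
    surface must stay within [0, 100] over the coded cube [-1.68, 1.68]^3
    (checked by grid scan on construction), so that noiseless responses are
    valid efficiencies.
    """

    intercept: float = 70.0
    linear: tuple = (0.0, 0.0, 0.0)
    quadratic: tuple = (0.0, 0.0, 0.0)
    interactions: tuple = (0.0, 0.0, 0.0)
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("linear", "quadratic", "interactions"):
            v = tuple(float(c) for c in getattr(self, name))
            if len(v) != 3:
                raise ValueError(f"{name} needs 3 coefficients")
            object.__setattr__(self, name, v)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        g = np.linspace(-1.68, 1.68, 43)
        grid = np.stack(np.meshgrid(g, g, g, indexing="ij"), axis=-1).reshape(-1, 3)
        vals = evaluate_surface(self, grid)
        if vals.min() < 0.0 or vals.max() > 100.0:
            raise ValueError(
                f"surface leaves [0, 100] over the coded cube "
                f"(range {vals.min():.1f}..{vals.max():.1f})"
            )


def evaluate_surface(spec: SurfaceSpec, coded) -> np.ndarray | float:
    """Noiseless efficiency (%) of the quadratic surface at coded settings."""
    x = np.asarray(coded, dtype=float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    b = np.array(spec.linear)
    q = np.array(spec.quadratic)
    it = np.array(spec.interactions)
    y = (
        spec.intercept
        + x @ b
        + (x**2) @ q
        + it[0] * x[:, 0] * x[:, 1]
        + it[1] * x[:, 0] * x[:, 2]
        + it[2] * x[:, 1] * x[:, 2]
    )
    return float(y[0]) if single else y


def simulate_ccd(
    spec: SurfaceSpec,
    factors=REFERENCE_FACTORS,
    n_center: int = 6,
    n_validation: int = 0,
) -> Dataset:
    """Simulate a CCD experiment: 8 factorial + 6 axial + ``n_center``
    centre trials (plus optional uniform-random validation points), with
    responses = surface + seeded Gaussian noise, clipped to [0, 100]."""
    rng = np.random.default_rng(spec.seed)
    points = generate_ccd(factors, n_center=n_center)
    coded = [p.coded for p in points]
    roles = ["training"] * len(points)
    if n_validation:
        # validation points are drawn from the factorial core [-1, 1]^3,
        # inside the region the design actually samples
        extra = rng.uniform(-1.0, 1.0, size=(n_validation, 3))
        coded.extend(extra)
        roles.extend(["validation"] * n_validation)
    coded = np.array(coded)
    y = evaluate_surface(spec, coded) + rng.normal(0.0, spec.noise_sd, size=len(coded))
    clipped = np.clip(y, 0.0, 100.0)
    n_clip = int(np.sum(clipped != y))
    if n_clip:
        logger.warning("%d simulated responses clipped to [0, 100]", n_clip)
    trials = [
        Trial(
            label=str(i + 1),
            coded=c,
            actual=coded_to_actual(c, factors),
            efficiency=float(v),
            role=role,
        )
        for i, (c, v, role) in enumerate(zip(coded, clipped, roles))
    ]
    return Dataset(factors=tuple(factors), trials=tuple(trials))


def analytic_optimum(spec: SurfaceSpec, bounds=_CUBE) -> tuple[np.ndarray, float]:
    """Maximum of the noiseless surface over the bounded cube.

    A dense grid scan (step 0.01 in coded units) is the oracle of record;
    when the stationary point of the quadratic is interior, negative
    definite and agrees with the grid, the exact stationary point is
    returned instead of the grid node.
    """
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    # grid scan, chunked along x1 to bound memory
    axes = [np.arange(lo[i], hi[i] + 1e-12, 0.01) for i in range(3)]
    best_val, best_x = -np.inf, None
    g2, g3 = np.meshgrid(axes[1], axes[2], indexing="ij")
    flat23 = np.column_stack([g2.ravel(), g3.ravel()])
    for x1 in axes[0]:
        pts = np.column_stack([np.full(len(flat23), x1), flat23])
        vals = evaluate_surface(spec, pts)
        i = int(np.argmax(vals))
        if vals[i] > best_val:
            best_val, best_x = float(vals[i]), pts[i]
    # exact stationary point of  c + b.x + x'Qx  where grad = b + 2Qx
    q = np.diag(spec.quadratic).astype(float)
    it = spec.interactions
    q[0, 1] = q[1, 0] = it[0] / 2.0
    q[0, 2] = q[2, 0] = it[1] / 2.0
    q[1, 2] = q[2, 1] = it[2] / 2.0
    b = np.array(spec.linear)
    try:
        x_star = np.linalg.solve(2.0 * q, -b)
    except np.linalg.LinAlgError:
        x_star = None
    if x_star is not None and np.all(x_star >= lo) and np.all(x_star <= hi):
        v_star = float(evaluate_surface(spec, x_star))
        if v_star >= best_val - 1e-9 and np.all(np.linalg.eigvalsh(q) < 0):
            return x_star, v_star
    return best_x, best_val
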