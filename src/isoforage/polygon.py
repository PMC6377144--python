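"""A-priori Monte-Carlo mixing-polygon feasibility test.

Each iteration resamples every source's TEF-corrected signature from
independent per-tracer normals, forms the convex hull in (δ13C, δ15N)
space, and asks whether each consumer falls inside. A consumer whose
inclusion probability falls below ``inclusion_alpha`` lies outside the
(1 − alpha)·100% mixing region, i.e. the proposed sources are unlikely
to explain it as a convex mixture.

Hull and point-inclusion primitives are self-contained (Andrew's
monotone chain; half-plane tests with boundary counted as inside).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import IsotopeSample, SourceGroup, TrophicEnrichment


class DegenerateHullError(ValueError):
    """Fewer than 3 points, or all points collinear."""


def _cross(o, a, b) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def convex_hull(points: Sequence[tuple[float, float]] | np.ndarray) -> np.ndarray:
    """Convex hull via Andrew's monotone chain.

    Returns hull vertices in counter-clockwise order with no duplicates and
    no interior or edge-collinear points. Raises DegenerateHullError for
    < 3 distinct points or a fully collinear set.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected an (n, 2) array, got shape {pts.shape}")
    uniq = sorted(set(map(tuple, pts)))
    if len(uniq) < 3:
        raise DegenerateHullError(f"need >= 3 distinct points, got {len(uniq)}")

    def half(seq):
        out: list[tuple[float, float]] = []
        for p in seq:
            while len(out) >= 2 and _cross(out[-2], out[-1], p) <= 0:
                out.pop()
            out.append(p)
        return out

    lower = half(uniq)
    upper = half(reversed(uniq))
    hull = lower[:-1] + upper[:-1]
    if len(hull) < 3:
        raise DegenerateHullError("all points collinear")
    return np.asarray(hull, dtype=float)


def point_in_polygon(
    point: tuple[float, float],
    hull: np.ndarray,
    rtol: float = 1e-12,
) -> bool:
    """True iff ``point`` lies inside or on the boundary of a CCW convex hull."""
    hull = np.asarray(hull, dtype=float)
    if hull.ndim != 2 or hull.shape[0] < 3:
        raise DegenerateHullError("hull must have >= 3 vertices")
    scale = max(1.0, float(np.abs(hull).max()))
    tol = rtol * scale * scale
    p = (float(point[0]), float(point[1]))
    for i in range(len(hull)):
        a, b = hull[i], hull[(i + 1) % len(hull)]
        if _cross(a, b, p) < -tol:
            return False
    return True


def hull_area(hull: np.ndarray) -> float:
    """Polygon area by the shoelace formula (positive for CCW input)."""
    hull = np.asarray(hull, dtype=float)
    x, y = hull[:, 0], hull[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _points_in_hull_mask(points: np.ndarray, hull: np.ndarray,
                         rtol: float = 1e-12) -> np.ndarray:
    """Vectorized boundary-inclusive inclusion test for many points."""
    scale = max(1.0, float(np.abs(hull).max()))
    tol = rtol * scale * scale
    inside = np.ones(len(points), dtype=bool)
    nv = len(hull)
    for i in range(nv):
        a = hull[i]
        b = hull[(i + 1) % nv]
        cross = ((b[0] - a[0]) * (points[:, 1] - a[1])
                 - (b[1] - a[1]) * (points[:, 0] - a[0]))
        inside &= cross >= -tol
    return inside


@dataclass
class PolygonSimulationResult:
    inclusion_probability: pd.Series       # indexed by consumer sample_id
    n_iterations: int
    inclusion_alpha: float
    outside_flags: pd.Series               # True where prob < alpha
    n_degenerate: int
    hulls: list[np.ndarray] | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": self.inclusion_probability.index,
            "inclusion_probability": self.inclusion_probability.values,
            "outside_region": self.outside_flags.values,
        })


def simulate_mixing_region(
    sources: Sequence[SourceGroup],
    consumers: Sequence[IsotopeSample],
    tef: TrophicEnrichment,
    n_iterations: int = 1500,
    seed: int = 0,
    inclusion_alpha: float = 0.05,
    retain_hulls: bool = False,
) -> PolygonSimulationResult:
    """Monte-Carlo mixing-polygon simulation for one consumer population.

    Per iteration every source's (d13C, d15N) is drawn from
    Normal(mu + TEF_mean, sqrt(sigma^2 + TEF_sd^2)) per tracer (independent
    tracers, matching the standard treatment), the hull of the draws is
    formed, and each consumer is tested for inclusion. A degenerate draw
    (collinear sources) counts as excluding everyone; more than 50%
    degenerate iterations aborts the simulation.
    """
    if len(sources) < 3:
        raise ValueError(f"need >= 3 sources to form a mixing polygon, "
                         f"got {len(sources)}")
    if n_iterations < 100:
        raise ValueError("n_iterations must be >= 100")
    rng = np.random.default_rng(seed)
    mu = np.array([[s.mu[0] + tef.delta_d13C_mean,
                    s.mu[1] + tef.delta_d15N_mean] for s in sources])
    sd = np.array([[math.sqrt(s.sigma[0] ** 2 + tef.delta_d13C_sd ** 2),
                    math.sqrt(s.sigma[1] ** 2 + tef.delta_d15N_sd ** 2)]
                   for s in sources])
    pts = np.array([[c.d13C, c.d15N] for c in consumers])
    ids = [c.sample_id for c in consumers]
    counts = np.zeros(len(consumers), dtype=int)
    n_degenerate = 0
    hulls: list[np.ndarray] | None = [] if retain_hulls else None
    for _ in range(n_iterations):
        draw = rng.normal(mu, sd)
        try:
            hull = convex_hull(draw)
        except DegenerateHullError:
            n_degenerate += 1
            continue
        if hulls is not None:
            hulls.append(hull)
        if len(pts):
            counts += _points_in_hull_mask(pts, hull)
    if n_degenerate > n_iterations // 2:
        raise DegenerateHullError(
            f"{n_degenerate}/{n_iterations} iterations produced a degenerate "
            "hull; sources are too collinear")
    prob = pd.Series(counts / n_iterations, index=ids, name="inclusion_probability")
    return PolygonSimulationResult(
        inclusion_probability=prob,
        n_iterations=n_iterations,
        inclusion_alpha=inclusion_alpha,
        outside_flags=prob < inclusion_alpha,
        n_degenerate=n_degenerate,
        hulls=hulls,
    )


def region_contours(
    result: PolygonSimulationResult,
    grid_resolution: int = 50,
    padding: float = 0.05,
) -> pd.DataFrame:
    """Inclusion-probability surface on a bounding grid of the retained hulls.

    Returns a long-format frame (d13C, d15N, probability); the 0.95 contour
    of the mixing region can be extracted from it. Requires the simulation
    to have been run with ``retain_hulls=True``.
    """
    if result.hulls is None:
        raise ValueError("simulation did not retain per-iteration hulls; "
                         "rerun with retain_hulls=True")
    allv = np.vstack(result.hulls)
    lo = allv.min(axis=0)
    hi = allv.max(axis=0)
    span = hi - lo
    lo -= padding * span
    hi += padding * span
    xs = np.linspace(lo[0], hi[0], grid_resolution)
    ys = np.linspace(lo[1], hi[1], grid_resolution)
    gx, gy = np.meshgrid(xs, ys)
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    counts = np.zeros(len(grid), dtype=int)
    for hull in result.hulls:
        counts += _points_in_hull_mask(grid, hull)
    prob = counts / result.n_iterations
    return pd.DataFrame({"d13C": grid[:, 0], "d15N": grid[:, 1],
                         "probability": prob})
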