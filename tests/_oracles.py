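"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles — per-pixel
point-in-polygon crossing tests, explicit point-to-segment distance
minimization, min-then-max grayscale filtering, binomial tail sums, and a
numerically integrated studentized-range distribution — so the oracles share
no code path with the package implementations they check.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate
from scipy import ndimage
from scipy.stats import norm


def points_in_polygon(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Even-odd (crossing-number) point-in-polygon test, vectorized over points."""
    x, y = points[:, 0], points[:, 1]
    inside = np.zeros(len(points), dtype=bool)
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        crosses = (y1 > y) != (y2 > y)
        if not crosses.any():
            continue
        x_int = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (x < x_int)
    return inside


def min_distance_to_polyline(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Exact minimum Euclidean distance from each point to a closed polyline."""
    best = np.full(len(points), np.inf)
    n = len(vertices)
    for i in range(n):
        a = vertices[i]
        b = vertices[(i + 1) % n]
        ab = b - a
        denom = float(ab @ ab)
        ap = points - a
        t = np.clip((ap @ ab) / denom, 0.0, 1.0) if denom > 0 else np.zeros(len(points))
        closest = a + t[:, None] * ab
        d = np.hypot(points[:, 0] - closest[:, 0], points[:, 1] - closest[:, 1])
        np.minimum(best, d, out=best)
    return best


def _pixel_centers(grid) -> np.ndarray:
    x = (np.arange(grid.width) + 0.5) * grid.pixel_size_um
    y = (np.arange(grid.height) + 0.5) * grid.pixel_size_um
    X, Y = np.meshgrid(x, y)
    return np.column_stack([X.ravel(), Y.ravel()])


def brute_body_mask(outer_v, inner_v, grid, erosion_um: float) -> np.ndarray:
    pts = _pixel_centers(grid)
    annulus = points_in_polygon(pts, outer_v) & ~points_in_polygon(pts, inner_v)
    if erosion_um > 0:
        d = np.minimum(
            min_distance_to_polyline(pts, outer_v), min_distance_to_polyline(pts, inner_v)
        )
        annulus &= d > erosion_um
    return annulus.reshape(grid.shape)


def brute_ribbon_mask(inner_v, grid, dilation_um: float) -> np.ndarray:
    pts = _pixel_centers(grid)
    d = min_distance_to_polyline(pts, inner_v)
    return (d <= dilation_um).reshape(grid.shape)


def brute_tophat(image: np.ndarray, radius_px: int) -> np.ndarray:
    """Min-then-max filtering route to the white top-hat (disk footprint)."""
    yy, xx = np.mgrid[-radius_px : radius_px + 1, -radius_px : radius_px + 1]
    footprint = xx**2 + yy**2 <= radius_px**2
    eroded = ndimage.minimum_filter(image, footprint=footprint, mode="reflect")
    opened = ndimage.maximum_filter(eroded, footprint=footprint, mode="reflect")
    return image - opened


def binomial_tail(k: int, n: int, p0: float) -> float:
    """P(X >= k) by explicit pmf summation (log-factorial based)."""
    from math import comb

    total = 0.0
    for i in range(k, n + 1):
        total += comb(n, i) * p0**i * (1 - p0) ** (n - i)
    return min(1.0, total)


def studentized_range_sf(q: float, k: int, df: int) -> float:
    """Upper tail of the studentized range by direct numeric integration.

    P(Q <= q) = ∫ f_S(s) · k ∫ φ(z) [Φ(z) − Φ(z − q·s)]^{k−1} dz ds where
    S = sqrt(chi2_df / df).
    """
    from math import gamma, log, exp

    def log_fs(s: float) -> float:
        # density of sqrt(chi2_df/df)
        return (
            (df / 2.0) * log(df / 2.0)
            - log(gamma(df / 2.0))
            + (df - 1) * log(s)
            - df * s * s / 2.0
            + log(2.0)
        )

    def inner(s: float) -> float:
        def f(z: float) -> float:
            return norm.pdf(z) * (norm.cdf(z) - norm.cdf(z - q * s)) ** (k - 1)

        val, _ = integrate.quad(f, -8.5, 8.5, limit=200)
        return k * val

    def outer(s: float) -> float:
        return exp(log_fs(s)) * inner(s)

    cdf, _ = integrate.quad(outer, 1e-8, 10.0, limit=200)
    return max(0.0, 1.0 - cdf)


def star_polygon(
    rng: np.random.Generator,
    center: tuple[float, float],
    base_radius: float,
    wobble: float = 0.25,
    n_vertices: int = 48,
) -> np.ndarray:
    """Random star-shaped (hence simple) polygon around a centre, in µm."""
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    amp = rng.uniform(0, wobble, size=3)
    phase = rng.uniform(0, 2 * np.pi, size=3)
    r = base_radius * (1.0 + sum(a * np.cos((i + 2) * theta + p) for i, (a, p) in enumerate(zip(amp, phase))))
    r = np.clip(r, 0.3 * base_radius, 1.8 * base_radius)
    return np.column_stack([center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)])
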