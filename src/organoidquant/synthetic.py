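"""Seeded synthetic inputs with planted ground truth for every pipeline stage.

Four generators emulate the study's data modalities:

* :func:`make_rosette_scene` — a 2D rosette image: elliptical lumen, a thin
  apical ribbon of elevated intensity hugging the lumen, a lower-intensity
  pseudostratified body, non-uniform illumination and additive Gaussian noise
  (clipped at zero).  Region intensities are *composited* (each pixel belongs
  to exactly one region), so noiseless region means equal their planted values
  exactly.
* :func:`make_marker_field` — a puncta field on an affine background plane,
  for top-hat/Otsu marker quantification.
* :func:`make_coloc_stack` — a 3-channel volume whose supra-threshold
  supports overlap by an exactly planted fraction of the target channel.
* :func:`make_count_experiment` — a pair of gene × cell negative-binomial
  count matrices with clusters, planted log2 fold changes, mitochondrial
  genes, and named QC-violating cells.

Every generator returns its output together with one :class:`SceneTruth`,
and is bit-reproducible for a fixed (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intensity import ImageChannel
from .roi import (
    BoundaryPolyline,
    PixelGrid,
    distance_to_polyline,
    ellipse_polyline,
    rasterize_polygon,
)
from .coloc import VolumeStack
from .screen import CountMatrix, QCThresholds

__all__ = [
    "RosetteSceneParams",
    "SceneTruth",
    "make_rosette_scene",
    "make_marker_field",
    "make_coloc_stack",
    "make_count_experiment",
]


@dataclass(frozen=True)
class RosetteSceneParams:
    """Geometry and photometry of one synthetic rosette image.

    Lengths in µm, intensities in arbitrary units (AU).  The illumination
    gradient is a linear ramp of the given total amplitude across the image
    width, centred on zero.
    """

    size_px: tuple[int, int] = (256, 256)  # (height, width)
    pixel_size_um: float = 0.5
    outer_semi_axes_um: tuple[float, float] = (30.0, 24.0)
    lumen_semi_axes_um: tuple[float, float] = (9.0, 7.0)
    center_um: tuple[float, float] | None = None  # default: image centre
    rotation_rad: float = 0.0
    body_mean: float = 100.0
    ribbon_mean: float = 300.0
    ribbon_halfwidth_um: float = 1.8
    background_mean: float = 20.0
    illumination_gradient_amplitude: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0
    n_vertices: int = 256

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not (
            self.lumen_semi_axes_um[0] < self.outer_semi_axes_um[0]
            and self.lumen_semi_axes_um[1] < self.outer_semi_axes_um[1]
        ):
            raise ValueError("lumen semi-axes must be strictly smaller than outer semi-axes")
        if min(self.body_mean, self.ribbon_mean, self.background_mean) < 0:
            raise ValueError("intensities must be non-negative")
        if self.ribbon_halfwidth_um <= 0:
            raise ValueError("ribbon_halfwidth_um must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass
class SceneTruth:
    """Planted ground truth carried by every generator output."""

    seed: int
    outer_polyline_um: np.ndarray | None = None
    inner_polyline_um: np.ndarray | None = None
    region_means: dict[str, float] = field(default_factory=dict)
    region_masks: dict[str, np.ndarray] = field(default_factory=dict)
    punctum_centers_um: np.ndarray | None = None
    punctum_amplitudes: np.ndarray | None = None
    foreground_mean: float | None = None
    tvc_fractions: dict[tuple[str, str], float] = field(default_factory=dict)
    channel_supports: dict[str, np.ndarray] = field(default_factory=dict)
    de_table: pd.DataFrame | None = None
    qc_violators: list[str] = field(default_factory=list)


def make_rosette_scene(params: RosetteSceneParams) -> tuple[ImageChannel, SceneTruth]:
    """Render one rosette scene and its ground truth.

    The noiseless image is a composite: background (+ illumination ramp)
    outside the rosette and in the lumen, ``body_mean`` in the annulus,
    ``ribbon_mean`` in the band within ``ribbon_halfwidth_um`` of the luminal
    boundary.  Planted region means are computed from the noiseless image so
    they are exact whatever the gradient.
    """
    h, w = params.size_px
    grid = PixelGrid(width=w, height=h, pixel_size_um=params.pixel_size_um)
    center = params.center_um
    if center is None:
        center = (w * params.pixel_size_um / 2.0, h * params.pixel_size_um / 2.0)

    outer = ellipse_polyline(center, params.outer_semi_axes_um, params.rotation_rad, params.n_vertices)
    inner = ellipse_polyline(center, params.lumen_semi_axes_um, params.rotation_rad, params.n_vertices)

    inside_outer = rasterize_polygon(outer, grid)
    inside_inner = rasterize_polygon(inner, grid)
    d_inner = distance_to_polyline(inner, grid)
    band = d_inner <= params.ribbon_halfwidth_um
    annulus = inside_outer & ~inside_inner
    body_region = annulus & ~band
    lumen_region = inside_inner & ~band

    X, _ = grid.pixel_centers_um()
    width_um = w * params.pixel_size_um
    gradient = params.illumination_gradient_amplitude * (X / width_um - 0.5)

    img = np.full(grid.shape, params.background_mean, dtype=float) + gradient
    img[body_region] = params.body_mean
    img[band] = params.ribbon_mean
    img = np.clip(img, 0.0, None)
    noiseless = img.copy()

    if params.noise_sigma > 0:
        rng = np.random.default_rng(params.seed)
        img = np.clip(img + rng.normal(0.0, params.noise_sigma, size=img.shape), 0.0, None)

    truth = SceneTruth(
        seed=params.seed,
        outer_polyline_um=outer.vertices_um,
        inner_polyline_um=inner.vertices_um,
        region_masks={
            "body": body_region,
            "ribbon": band,
            "lumen": lumen_region,
            "background": ~inside_outer & ~band,
        },
    )
    for name, mask in truth.region_masks.items():
        if mask.any():
            truth.region_means[name] = float(noiseless[mask].mean())
    return ImageChannel(img, grid, name="rosette"), truth


def make_marker_field(
    size_px: tuple[int, int] = (256, 256),
    pixel_size_um: float = 1.0,
    n_puncta: int = 30,
    punctum_radius_um: float = 5.0,
    punctum_amp: float = 200.0,
    background_plane_coeffs: tuple[float, float, float] = (50.0, 0.0, 0.0),
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[ImageChannel, SceneTruth]:
    """Puncta on an affine background plane ``a + b·x_um + c·y_um``.

    Puncta are disks (pixel-centre distance <= radius) of equal additive
    amplitude, placed uniformly at random but kept clear of the image border
    and of each other; a placement is retried up to 100 times before a
    placement error is raised.  The planted foreground mean is the punctum
    amplitude (what top-hat + Otsu should recover).
    """
    h, w = size_px
    grid = PixelGrid(width=w, height=h, pixel_size_um=pixel_size_um)
    X, Y = grid.pixel_centers_um()
    a, b, c = background_plane_coeffs
    img = a + b * X + c * Y
    if img.min() < 0:
        raise ValueError("background plane must be non-negative over the image")

    rng = np.random.default_rng(seed)
    margin = punctum_radius_um + pixel_size_um
    width_um, height_um = w * pixel_size_um, h * pixel_size_um
    if 2 * margin >= min(width_um, height_um) and n_puncta > 0:
        raise ValueError("punctum radius too large for the field")

    centers = []
    for _ in range(n_puncta):
        for attempt in range(100):
            cx = rng.uniform(margin, width_um - margin)
            cy = rng.uniform(margin, height_um - margin)
            if all((cx - px) ** 2 + (cy - py) ** 2 > (2 * punctum_radius_um + pixel_size_um) ** 2 for px, py in centers):
                centers.append((cx, cy))
                break
        else:
            raise RuntimeError("failed to place punctum after 100 attempts")
    centers_arr = np.asarray(centers, dtype=float).reshape(-1, 2)

    for cx, cy in centers_arr:
        disk = (X - cx) ** 2 + (Y - cy) ** 2 <= punctum_radius_um**2
        img[disk] += punctum_amp

    img = np.clip(img, 0.0, None)
    if noise_sigma > 0:
        img = np.clip(img + rng.normal(0.0, noise_sigma, size=img.shape), 0.0, None)

    truth = SceneTruth(
        seed=seed,
        punctum_centers_um=centers_arr,
        punctum_amplitudes=np.full(len(centers_arr), punctum_amp),
        foreground_mean=punctum_amp if n_puncta > 0 else None,
    )
    return ImageChannel(img, grid, name="marker"), truth


def make_coloc_stack(
    shape: tuple[int, int, int] = (64, 64, 64),
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0),
    overlap_nuclear: float = 0.5,
    overlap_neuronal: float = 0.5,
    n_blobs: int = 5,
    blob_radius_vox: float = 6.0,
    background: float = 5.0,
    foreground: float = 250.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[VolumeStack, SceneTruth]:
    """Three-channel volume with exactly planted overlap fractions.

    The target channel's support is a union of random balls.  Each secondary
    channel receives ``round(f · |target|)`` voxels drawn from the target
    support plus an equal-sized set of voxels disjoint from it, so the
    voxel-counted overlap fraction of the target equals the planted ``f``
    up to the single-voxel rounding (exact at f = 0 and f = 1, where the
    supports are disjoint and identical respectively).
    """
    for f in (overlap_nuclear, overlap_neuronal):
        if not (0.0 <= f <= 1.0):
            raise ValueError("overlap fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    zz, yy, xx = np.indices(shape)
    target = np.zeros(shape, dtype=bool)
    r = blob_radius_vox
    for _ in range(n_blobs):
        cz = rng.uniform(r, shape[0] - r)
        cy = rng.uniform(r, shape[1] - r)
        cx = rng.uniform(r, shape[2] - r)
        target |= (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    n_target = int(target.sum())
    if n_target == 0:
        raise ValueError("target support is empty; increase blob count or radius")

    flat_in = np.flatnonzero(target.ravel())
    flat_out = np.flatnonzero(~target.ravel())

    def secondary(f: float) -> np.ndarray:
        k = int(round(f * n_target))
        chosen = rng.choice(flat_in, size=k, replace=False)
        support = np.zeros(target.size, dtype=bool)
        support[chosen] = True
        if f < 1.0:
            n_extra = min(n_target - k, flat_out.size)
            if n_extra == 0 and k == 0:
                raise ValueError("infeasible overlap: secondary support would be empty")
            extra = rng.choice(flat_out, size=n_extra, replace=False)
            support[extra] = True
        return support.reshape(shape)

    nuclear = secondary(overlap_nuclear)
    neuronal = secondary(overlap_neuronal)

    def render(support: np.ndarray) -> np.ndarray:
        vol = np.where(support, foreground, background).astype(float)
        if noise_sigma > 0:
            vol = np.clip(vol + rng.normal(0.0, noise_sigma, size=shape), 0.0, None)
        return vol

    stack = VolumeStack(
        channels={"target": render(target), "nuclear": render(nuclear), "neuronal": render(neuronal)},
        voxel_size_um=voxel_size_um,
    )
    truth = SceneTruth(
        seed=seed,
        tvc_fractions={
            ("target", "nuclear"): round(overlap_nuclear * n_target) / n_target,
            ("target", "neuronal"): round(overlap_neuronal * n_target) / n_target,
        },
        channel_supports={"target": target, "nuclear": nuclear, "neuronal": neuronal},
    )
    return stack, truth


def _plant_qc_violation(
    counts: np.ndarray, col: int, rule: str, mito_idx: np.ndarray, thresholds: QCThresholds, rng
) -> None:
    n_genes = counts.shape[0]
    if rule == "high_nFeature":
        if n_genes <= thresholds.max_nFeature:
            raise ValueError("cannot plant high_nFeature: too few genes")
        counts[:, col] = np.maximum(counts[:, col], 1)
    elif rule == "low_nFeature":
        keep = rng.choice(n_genes, size=max(1, thresholds.min_nFeature // 4), replace=False)
        col_counts = np.zeros(n_genes, dtype=counts.dtype)
        col_counts[keep] = np.maximum(counts[keep, col], 1)
        counts[:, col] = col_counts
    elif rule == "high_nCount":
        g = rng.integers(0, n_genes)
        counts[g, col] += thresholds.max_nCount + 1
    elif rule == "high_pct_mito":
        if mito_idx.size == 0:
            raise ValueError("cannot plant high_pct_mito without mitochondrial genes")
        total = counts[:, col].sum()
        # make mito counts exceed the cutoff fraction with margin
        counts[mito_idx[0], col] += int(total) + 100
    else:
        raise ValueError(f"unknown QC violation rule {rule!r}")


def make_count_experiment(
    n_genes: int = 1000,
    n_cells_per_sample: int = 1500,
    n_clusters: int = 3,
    planted_log2fc: Mapping[tuple[str, str], float] | None = None,
    mito_gene_fraction: float = 0.05,
    qc_violations: Mapping[str, str] | None = None,
    dispersion: float = 0.1,
    qc_thresholds: QCThresholds = QCThresholds(),
    seed: int = 0,
    min_de_base_mean: float = 0.5,
) -> tuple[tuple[CountMatrix, CountMatrix], SceneTruth]:
    """Two-sample negative-binomial count experiment with planted effects.

    Per gene × cluster means: a lognormal per-gene base mean times a mild
    per-cluster modulation; sample B's mean for a planted (gene, cluster) is
    scaled by ``2^log2fc``.  Counts are NB with variance ``m + d·m²``
    (dispersion d, default 0.1).  ``qc_violations`` maps cell ids (of either
    sample, e.g. ``"A_cell_0007"``) to a rule in {high_nFeature, low_nFeature,
    high_nCount, high_pct_mito}; those cells are overwritten to violate
    exactly that rule and recorded in ``SceneTruth.qc_violators``.

    ``planted_log2fc`` keys are (gene id, cluster id as str).  Pass genes by
    index-derived id (``"gene_0042"``); DE genes should sit above
    ``min_de_base_mean`` base expression to be recoverable — the generator
    enforces this by raising the base mean of planted genes to the floor.
    """
    if n_clusters < 1:
        raise ValueError("need at least one cluster")
    cells_per_cluster = n_cells_per_sample // n_clusters
    if cells_per_cluster < 2:
        raise ValueError("cluster sizes below 2 are not allowed")
    rng = np.random.default_rng(seed)

    n_mito = int(round(mito_gene_fraction * n_genes))
    gene_ids = [f"MT-gene_{i:04d}" if i < n_mito else f"gene_{i:04d}" for i in range(n_genes)]
    mito_genes = frozenset(gene_ids[:n_mito])
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    base_mean = np.exp(rng.normal(0.0, 1.0, size=n_genes))
    base_mean = np.clip(base_mean, 0.05, 50.0)
    cluster_mod = np.exp(rng.normal(0.0, 0.1, size=(n_genes, n_clusters)))

    planted_log2fc = dict(planted_log2fc or {})
    for (gene, _cluster), _fc in planted_log2fc.items():
        if gene not in gene_pos:
            raise KeyError(f"planted gene {gene!r} not in matrix")
        base_mean[gene_pos[gene]] = max(base_mean[gene_pos[gene]], min_de_base_mean)

    clusters = np.repeat(np.arange(n_clusters), cells_per_cluster)
    leftover = n_cells_per_sample - clusters.size
    if leftover:
        clusters = np.concatenate([clusters, rng.integers(0, n_clusters, size=leftover)])
    cluster_ids = clusters.astype(str)

    mean_b = base_mean[:, None] * cluster_mod  # genes × clusters
    mean_a = mean_b.copy()
    # planted fc is the A-vs-B contrast, matching the screen's log2(mean_A/mean_B)
    for (gene, cluster), fc in planted_log2fc.items():
        ci = int(cluster)
        mean_a[gene_pos[gene], ci] *= 2.0**fc

    def draw(mean_gc: np.ndarray) -> np.ndarray:
        counts = np.zeros((n_genes, n_cells_per_sample), dtype=np.int64)
        n_nb = 1.0 / dispersion
        for ci in range(n_clusters):
            cols = np.flatnonzero(clusters == ci)
            m = mean_gc[:, ci][:, None]
            p = n_nb / (n_nb + m)
            counts[:, cols] = rng.negative_binomial(n_nb, p, size=(n_genes, cols.size))
        return counts

    counts_a = draw(mean_a)
    counts_b = draw(mean_b)

    cell_ids_a = [f"A_cell_{i:04d}" for i in range(n_cells_per_sample)]
    cell_ids_b = [f"B_cell_{i:04d}" for i in range(n_cells_per_sample)]
    mito_idx = np.arange(n_mito)

    qc_violations = dict(qc_violations or {})
    for cell, rule in qc_violations.items():
        if cell in cell_ids_a:
            _plant_qc_violation(counts_a, cell_ids_a.index(cell), rule, mito_idx, qc_thresholds, rng)
        elif cell in cell_ids_b:
            _plant_qc_violation(counts_b, cell_ids_b.index(cell), rule, mito_idx, qc_thresholds, rng)
        else:
            raise KeyError(f"QC violation names unknown cell {cell!r}")

    matrix_a = CountMatrix(counts_a, gene_ids, cell_ids_a, "A", cluster_ids.copy(), mito_genes)
    matrix_b = CountMatrix(counts_b, gene_ids, cell_ids_b, "B", cluster_ids.copy(), mito_genes)

    de_table = pd.DataFrame(
        [{"gene": g, "cluster": c, "log2fc": fc} for (g, c), fc in sorted(planted_log2fc.items())]
    )
    truth = SceneTruth(seed=seed, de_table=de_table, qc_violators=sorted(qc_violations))
    return (matrix_a, matrix_b), truth
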