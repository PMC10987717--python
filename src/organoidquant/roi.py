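"""Rosette ROI geometry: boundary polylines to Body/Ribbon masks and morphometrics.

A rosette is delineated by two hand-drawn closed polylines — an outer tissue
boundary and an inner luminal boundary, both in physical micrometres.  Two
regions of interest are derived from them:

* **Body** — the annulus between the boundaries, eroded by a physical margin
  (default 1.8 µm) so that neither the outer edge nor the apical ribbon is
  included in the body.
* **Ribbon** — the thin apical band within a physical distance (default
  1.8 µm) of the inner luminal boundary line.

All distances are measured in micrometres from pixel centres to the
*continuous* boundary polylines, so masks converge to the analytic regions as
the pixel size shrinks and body/ribbon are exactly disjoint at the shared
margin (body keeps strict ``>``, ribbon keeps ``<=``).

Coordinate convention: 0-based pixel indices, pixel (row i, col j) has its
centre at ``x = (j + 0.5) * pixel_size_um``, ``y = (i + 0.5) * pixel_size_um``,
with y increasing downward.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from skimage import measure
from skimage.draw import polygon_perimeter
from skimage.filters import threshold_otsu

__all__ = [
    "PixelGrid",
    "BoundaryPolyline",
    "RosetteROI",
    "RosetteMeasurement",
    "GeometryError",
    "DegenerateRegionError",
    "rasterize_polygon",
    "build_body_mask",
    "build_ribbon_mask",
    "build_rosette_roi",
    "rosette_morphometrics",
    "distance_to_polyline",
    "ellipse_polyline",
]

OTSU_BINS = 256


class GeometryError(ValueError):
    """Raised for invalid boundary geometry (open, self-intersecting, nested wrongly)."""


class DegenerateRegionError(ValueError):
    """Raised when a requested measurement region is empty."""


@dataclass(frozen=True)
class PixelGrid:
    """Calibrated raster geometry: image size in pixels plus µm-per-pixel."""

    width: int
    height: int
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("grid must be at least 1x1 pixels")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def pixel_centers_um(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) µm coordinates of every pixel centre, shape (H, W)."""
        x = (np.arange(self.width) + 0.5) * self.pixel_size_um
        y = (np.arange(self.height) + 0.5) * self.pixel_size_um
        return np.meshgrid(x, y)


@dataclass(frozen=True)
class BoundaryPolyline:
    """Ordered (x, y) vertices in µm; ``closed`` marks a polygon boundary."""

    vertices_um: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices_um, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise GeometryError("vertices must be an (n, 2) array of (x, y) µm")
        object.__setattr__(self, "vertices_um", v)

    def __len__(self) -> int:
        return len(self.vertices_um)

    def as_polygon(self) -> shapely.Polygon:
        if not self.closed or len(self) < 3:
            raise GeometryError("closed polygon with >= 3 vertices required")
        poly = shapely.Polygon(self.vertices_um)
        if not poly.is_valid or poly.area == 0:
            raise GeometryError("polygon is self-intersecting or degenerate")
        return poly

    def as_ring(self) -> shapely.LinearRing:
        return shapely.LinearRing(self.vertices_um)


def ellipse_polyline(
    center_um: tuple[float, float],
    semi_axes_um: tuple[float, float],
    rotation_rad: float = 0.0,
    n_vertices: int = 256,
) -> BoundaryPolyline:
    """Dense polygonal approximation of an ellipse, used both by the synthetic
    generator (ground-truth boundaries) and by geometry tests."""
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    a, b = semi_axes_um
    x = a * np.cos(t)
    y = b * np.sin(t)
    c, s = np.cos(rotation_rad), np.sin(rotation_rad)
    xs = center_um[0] + c * x - s * y
    ys = center_um[1] + s * x + c * y
    return BoundaryPolyline(np.column_stack([xs, ys]), closed=True)


def rasterize_polygon(boundary: BoundaryPolyline, grid: PixelGrid) -> np.ndarray:
    """Binary raster of a closed simple polygon.

    A pixel is set iff its centre lies inside the polygon (even-odd rule; for
    the required simple polygons this coincides with the winding rule used by
    the geometry backend).
    """
    poly = boundary.as_polygon()
    X, Y = grid.pixel_centers_um()
    inside = shapely.contains_xy(poly, X.ravel(), Y.ravel())
    return inside.reshape(grid.shape)


def distance_to_polyline(
    boundary: BoundaryPolyline,
    grid: PixelGrid,
    where: np.ndarray | None = None,
) -> np.ndarray:
    """Euclidean distance (µm) from each pixel centre to the boundary polyline.

    ``where`` restricts computation to a pixel subset; excluded pixels get
    +inf.  The distance is to the continuous closed curve, not to rasterized
    boundary pixels.
    """
    ring = boundary.as_ring() if boundary.closed else shapely.LineString(boundary.vertices_um)
    X, Y = grid.pixel_centers_um()
    out = np.full(grid.shape, np.inf)
    if where is None:
        where = np.ones(grid.shape, dtype=bool)
    pts = shapely.points(np.column_stack([X[where], Y[where]]))
    out[where] = shapely.distance(pts, ring)
    return out


def _band_candidates(boundary: BoundaryPolyline, grid: PixelGrid, reach_um: float) -> np.ndarray:
    """Bounding-box prefilter: pixels that can possibly lie within reach of the curve."""
    v = boundary.vertices_um
    px = grid.pixel_size_um
    X, Y = grid.pixel_centers_um()
    pad = reach_um + px
    return (
        (X >= v[:, 0].min() - pad)
        & (X <= v[:, 0].max() + pad)
        & (Y >= v[:, 1].min() - pad)
        & (Y <= v[:, 1].max() + pad)
    )


@dataclass
class RosetteROI:
    """Body and/or Ribbon masks for one rosette on a common grid."""

    grid: PixelGrid
    body_mask: np.ndarray | None = None
    ribbon_mask: np.ndarray | None = None
    erosion_um: float | None = None
    dilation_um: float | None = None
    otsu_threshold: float | None = None
    refinement_channel: str | None = None

    def union(self) -> np.ndarray:
        masks = [m for m in (self.body_mask, self.ribbon_mask) if m is not None]
        if not masks:
            raise DegenerateRegionError("ROI carries no masks")
        out = masks[0].copy()
        for m in masks[1:]:
            out |= m
        return out


@dataclass(frozen=True)
class RosetteMeasurement:
    """Per-rosette quantification record (mean intensities + morphometrics)."""

    rosette_id: str
    group: str
    mean_body: float
    mean_ribbon: float
    area_um2: float
    aspect_ratio: float

    def __post_init__(self) -> None:
        if self.area_um2 < 0:
            raise ValueError("area must be non-negative")
        if self.aspect_ratio < 1:
            raise ValueError("aspect ratio is major/minor and must be >= 1")


def _channel_array(channel) -> np.ndarray:
    # accepts a bare ndarray or any object exposing .data (e.g. ImageChannel)
    return np.asarray(getattr(channel, "data", channel), dtype=float)


def _otsu_over_region(values: np.ndarray) -> float:
    if values.size == 0 or np.ptp(values) == 0:
        raise DegenerateRegionError("cannot Otsu-refine a constant or empty region")
    return float(threshold_otsu(values, nbins=OTSU_BINS))


def build_body_mask(
    outer: BoundaryPolyline,
    inner: BoundaryPolyline,
    grid: PixelGrid,
    channel=None,
    erosion_um: float = 1.8,
    refine: bool = False,
) -> RosetteROI:
    """Body ROI: the inter-boundary annulus eroded by ``erosion_um`` (µm).

    Erosion keeps annulus pixels whose centres lie strictly farther than
    ``erosion_um`` from the annulus complement, i.e. from both boundary
    curves.  With ``refine=True`` the mask is further intersected with
    ``channel >= Otsu threshold``, the threshold being computed over the
    un-eroded annulus pixels (256-bin histogram) to drop background pixels
    from the hand-drawn region.
    """
    if erosion_um < 0:
        raise ValueError("erosion_um must be >= 0")
    poly_out = outer.as_polygon()
    poly_in = inner.as_polygon()
    if not poly_in.within(poly_out) or poly_in.touches(poly_out):
        raise GeometryError("inner boundary must lie strictly inside the outer boundary")

    annulus = rasterize_polygon(outer, grid) & ~rasterize_polygon(inner, grid)
    if erosion_um == 0:
        body = annulus.copy()
    else:
        d_in = distance_to_polyline(inner, grid, where=annulus)
        d_out = distance_to_polyline(outer, grid, where=annulus)
        body = annulus & (np.minimum(d_in, d_out) > erosion_um)

    threshold = None
    if refine:
        img = _channel_array(channel)
        if img.shape != grid.shape:
            raise ValueError("channel shape does not match grid")
        threshold = _otsu_over_region(img[annulus])
        body &= img >= threshold

    if not body.any():
        warnings.warn("body mask is empty after erosion/refinement", stacklevel=2)
    return RosetteROI(
        grid=grid,
        body_mask=body,
        erosion_um=erosion_um,
        otsu_threshold=threshold,
        refinement_channel=getattr(channel, "name", None) if refine else None,
    )


def build_ribbon_mask(
    inner: BoundaryPolyline,
    grid: PixelGrid,
    channel=None,
    dilation_um: float = 1.8,
    refine: bool = False,
) -> RosetteROI:
    """Ribbon ROI: pixels within ``dilation_um`` (µm, inclusive) of the inner
    luminal boundary line — the line dilated to capture the apical band.

    ``dilation_um == 0`` degenerates to the rasterized polyline itself.
    """
    if dilation_um < 0:
        raise ValueError("dilation_um must be >= 0")
    if dilation_um == 0:
        ribbon = np.zeros(grid.shape, dtype=bool)
        v = inner.vertices_um / grid.pixel_size_um - 0.5
        rr, cc = polygon_perimeter(v[:, 1], v[:, 0], shape=grid.shape, clip=True)
        ribbon[rr, cc] = True
    else:
        cand = _band_candidates(inner, grid, dilation_um)
        d = distance_to_polyline(inner, grid, where=cand)
        ribbon = d <= dilation_um

    threshold = None
    if refine:
        img = _channel_array(channel)
        if img.shape != grid.shape:
            raise ValueError("channel shape does not match grid")
        threshold = _otsu_over_region(img[ribbon])
        ribbon = ribbon & (img >= threshold)

    return RosetteROI(
        grid=grid,
        ribbon_mask=ribbon,
        dilation_um=dilation_um,
        otsu_threshold=threshold,
        refinement_channel=getattr(channel, "name", None) if refine else None,
    )


def build_rosette_roi(
    outer: BoundaryPolyline,
    inner: BoundaryPolyline,
    grid: PixelGrid,
    channel=None,
    erosion_um: float = 1.8,
    dilation_um: float = 1.8,
    refine: bool = False,
) -> RosetteROI:
    """Convenience: build Body and Ribbon together on one grid."""
    body = build_body_mask(outer, inner, grid, channel, erosion_um, refine)
    ribbon = build_ribbon_mask(inner, grid, channel, dilation_um, refine)
    return RosetteROI(
        grid=grid,
        body_mask=body.body_mask,
        ribbon_mask=ribbon.ribbon_mask,
        erosion_um=erosion_um,
        dilation_um=dilation_um,
        otsu_threshold=body.otsu_threshold,
        refinement_channel=body.refinement_channel,
    )


def rosette_morphometrics(roi: RosetteROI, grid: PixelGrid | None = None) -> tuple[float, float]:
    """Rosette area (µm², pixel count of body ∪ ribbon) and aspect ratio.

    The aspect ratio is major/minor axis length of the ellipse with the same
    normalized second central moments as the hole-filled union region — the
    lumen interior is filled so the axes describe the rosette outline, while
    the area excludes it.
    """
    grid = grid or roi.grid
    union = roi.union()
    if not union.any():
        raise DegenerateRegionError("empty body ∪ ribbon: no morphometrics")
    area_um2 = float(union.sum()) * grid.pixel_size_um**2

    filled = ndimage.binary_fill_holes(union)
    props = measure.regionprops(filled.astype(np.uint8))[0]
    minor = props.axis_minor_length
    if minor == 0:
        raise DegenerateRegionError("degenerate region: zero minor axis")
    aspect = props.axis_major_length / minor
    return area_um2, float(aspect)
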