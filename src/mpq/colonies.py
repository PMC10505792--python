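"""Colony detection in the DAPI channel.

A foreground mask is built by (relative) Otsu thresholding, cleaned by
morphological closing and hole filling, and connected components are kept
when their area matches the predicted micropattern size. Each accepted
colony gets a boundary polygon from an alpha shape of its foreground
pixels (convex-hull fallback; micropatterns are convex discs), whose
centroid defines the colony center used for all radial measurements.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import MultiPoint, Polygon
from skimage import measure, morphology
from skimage.filters import threshold_otsu
from skimage.segmentation import clear_border  # noqa: F401  (re-export convenience)

from .io import MultiChannelImage


class ThresholdFailureError(ValueError):
    """Raised when the DAPI channel has no contrast to threshold."""


@dataclass
class ColonyRegion:
    """One detected micropattern colony, in source-image pixel coordinates."""

    colony_id: str
    mask: np.ndarray  # bool, full image frame
    polygon: Polygon  # boundary, px coords (x=col, y=row)
    center_px: tuple[float, float]  # (x, y)
    center_um: tuple[float, float]
    area_um2: float
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)
    source_image: str = ""
    accepted: bool = True
    reject_reason: str = ""


@dataclass
class ColonyDetectionResult:
    colonies: list[ColonyRegion] = field(default_factory=list)
    rejects: list[ColonyRegion] = field(default_factory=list)

    def __iter__(self):
        return iter(self.colonies)

    def __len__(self):
        return len(self.colonies)


@dataclass
class ColonyCrop:
    """A per-colony multichannel crop plus its region in crop coordinates."""

    image: MultiChannelImage
    region: ColonyRegion
    origin_px: tuple[int, int]  # (row, col) of crop origin in the source
    clipped: bool = False


def alpha_shape(points: np.ndarray, alpha: float) -> Polygon:
    """Alpha shape of 2-D points: union of Delaunay triangles whose
    circumradius is at most ``alpha``. Falls back to the convex hull when
    triangulation fails or the filtered union is degenerate."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 4:
        return MultiPoint(pts).convex_hull
    try:
        tri = Delaunay(pts)
    except QhullError:
        return MultiPoint(pts).convex_hull
    t = pts[tri.simplices]  # (m, 3, 2)
    a = np.linalg.norm(t[:, 0] - t[:, 1], axis=1)
    b = np.linalg.norm(t[:, 1] - t[:, 2], axis=1)
    c = np.linalg.norm(t[:, 2] - t[:, 0], axis=1)
    s = (a + b + c) / 2
    area = np.sqrt(np.clip(s * (s - a) * (s - b) * (s - c), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        circum_r = a * b * c / (4 * area)
    keep = np.isfinite(circum_r) & (circum_r <= alpha)
    if not keep.any():
        return MultiPoint(pts).convex_hull
    polys = [Polygon(tv) for tv in t[keep]]
    union = shapely.union_all(polys)
    if union.geom_type != "Polygon" or union.is_empty:
        return MultiPoint(pts).convex_hull
    return union


def detect_colonies(
    dapi: np.ndarray,
    expected_diameter: float,
    pixel_size: float,
    alpha: float | None = None,
    area_tolerance: float = 0.35,
    closing_radius_um: float = 5.0,
    reject_border: bool = True,
    source_image: str = "",
) -> ColonyDetectionResult:
    """Detect micropattern colonies in a DAPI image.

    Parameters
    ----------
    dapi
        2-D DAPI channel.
    expected_diameter
        Predicted micropattern diameter in µm (500 for the assays here).
    pixel_size
        µm per pixel.
    alpha
        Alpha-shape scale in µm; defaults to ``expected_diameter / 5``.
    area_tolerance
        Candidate components are accepted when their area lies within
        ``[1 - tol, 1 + tol] * pi * (D/2)^2``; others are reported as
        rejects with a reason.
    """
    if expected_diameter <= 0:
        raise ValueError("expected_diameter must be positive")
    dapi = np.asarray(dapi, dtype=float)
    if dapi.size == 0:
        raise ValueError("empty image")
    if alpha is None:
        alpha = expected_diameter / 5.0
    if dapi.max() == dapi.min():
        if dapi.max() == 0:
            return ColonyDetectionResult()  # all-background
        raise ThresholdFailureError("constant non-zero image; cannot threshold")

    thr = threshold_otsu(dapi)
    fg = dapi > thr
    r_close = max(1, round(closing_radius_um / pixel_size))
    fg = morphology.closing(fg, morphology.disk(r_close))
    fg = morphology.remove_small_holes(fg, max_size=int(1e4 / pixel_size**2))
    labels = measure.label(fg)

    exp_area = math.pi * (expected_diameter / 2.0) ** 2
    lo, hi = (1 - area_tolerance) * exp_area, (1 + area_tolerance) * exp_area
    result = ColonyDetectionResult()
    h, w = dapi.shape
    for i, rp in enumerate(measure.regionprops(labels)):
        area_um2 = rp.area * pixel_size**2
        mask = labels == rp.label
        minr, minc, maxr, maxc = rp.bbox
        reason = ""
        if not (lo <= area_um2 <= hi):
            reason = "too-small" if area_um2 < lo else "too-large"
        elif reject_border and (minr == 0 or minc == 0 or maxr == h or maxc == w):
            reason = "border"
        cid = f"{source_image}:{i}" if source_image else str(i)
        if reason:
            cy, cx = rp.centroid
            result.rejects.append(
                ColonyRegion(
                    cid, mask, Polygon(), (cx, cy),
                    (cx * pixel_size, cy * pixel_size), area_um2,
                    rp.bbox, source_image, accepted=False, reject_reason=reason,
                )
            )
            continue
        rows, cols = np.nonzero(mask)
        pts = np.column_stack([cols, rows]).astype(float)
        if len(pts) > 4000:  # deterministic stride subsample for triangulation
            stride = int(np.ceil(len(pts) / 4000))
            pts = pts[::stride]
        poly = alpha_shape(pts, alpha / pixel_size)
        cx, cy = poly.centroid.x, poly.centroid.y
        if not mask[int(round(cy)), int(round(cx))]:
            warnings.warn(f"colony {cid}: polygon centroid off-mask", stacklevel=2)
        result.colonies.append(
            ColonyRegion(
                cid, mask, poly, (cx, cy),
                (cx * pixel_size, cy * pixel_size), area_um2,
                rp.bbox, source_image,
            )
        )
    return result


def extract_colony(
    image: MultiChannelImage, region: ColonyRegion, margin: float = 0.0
) -> ColonyCrop:
    """Crop all channels to the region bounding box plus a margin (µm).

    The region mask and center are re-expressed in crop coordinates; crops
    reaching past the image edge are clipped and flagged.
    """
    h, w = image.shape
    if region.mask.shape != (h, w):
        raise ValueError("region does not match image shape")
    m = int(round(margin / image.pixel_size))
    minr, minc, maxr, maxc = region.bbox
    r0, c0 = minr - m, minc - m
    r1, c1 = maxr + m, maxc + m
    clipped = r0 < 0 or c0 < 0 or r1 > h or c1 > w
    r0, c0 = max(0, r0), max(0, c0)
    r1, c1 = min(h, r1), min(w, c1)
    if r0 >= r1 or c0 >= c1:
        raise ValueError("region outside image bounds")
    channels = {n: ch[r0:r1, c0:c1].copy() for n, ch in image.channels.items()}
    crop_img = MultiChannelImage(channels, image.pixel_size, dict(image.meta))
    ps = image.pixel_size
    crop_region = ColonyRegion(
        region.colony_id,
        region.mask[r0:r1, c0:c1].copy(),
        shapely.affinity.translate(region.polygon, xoff=-c0, yoff=-r0)
        if not region.polygon.is_empty
        else region.polygon,
        (region.center_px[0] - c0, region.center_px[1] - r0),
        ((region.center_px[0] - c0) * ps, (region.center_px[1] - r0) * ps),
        region.area_um2,
        (0, 0, r1 - r0, c1 - c0),
        region.source_image,
        region.accepted,
        region.reject_reason,
    )
    return ColonyCrop(crop_img, crop_region, (r0, c0), clipped)
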