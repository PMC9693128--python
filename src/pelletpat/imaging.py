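"""Off-line two-step optical pellet sizing: segment bright pellet
projections from grayscale scans and measure maximum Feret, perpendicular
Feret and circle-equivalent diameters.

Segmentation is a global threshold (Otsu by default) followed by
connected-component labelling; regions touching the image border or below
a minimum pixel area are discarded (and counted). The maximum Feret is the
exact largest caliper width, computed as the maximum pairwise distance over
convex-hull vertices of the region's pixel centers (the rotating-calipers
diameter); the perpendicular Feret is the projection width orthogonal to
the max-Feret chord.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from skimage.measure import label, regionprops

from .types import ImageScale, ParticleMeasurement, PelletBatch

__all__ = [
    "SegmentationResult",
    "segment",
    "feret_diameters",
    "measure",
    "batch_from_image",
]

#: scanner scale at 1200 dpi
SCANNER_SCALE = ImageScale.from_dpi(1200.0)


@dataclass(frozen=True)
class SegmentationResult:
    regions: list          # skimage RegionProperties, one per retained particle
    n_border_discarded: int
    n_small_discarded: int
    threshold: float


def _threshold_value(image: np.ndarray, method: str | float) -> float:
    if isinstance(method, (int, float)) and not isinstance(method, bool):
        return float(method)
    if method == "otsu":
        from skimage.filters import threshold_otsu

        return float(threshold_otsu(image))
    raise ValueError(f"unknown threshold method {method!r}")


def segment(
    image: np.ndarray,
    min_area_px: int = 20,
    threshold: str | float = "otsu",
) -> SegmentationResult:
    """Label connected bright regions above a global threshold.

    `threshold` is either the tag "otsu" or a fixed gray value. Regions
    touching the border (truncated projections) or smaller than min_area_px
    are discarded; the counts are reported. An image with no foreground
    yields an empty region list, not an error.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("segment expects a single-channel image")
    if img.size == 0 or img.max() == img.min():
        return SegmentationResult([], 0, 0, float(img.max() if img.size else 0))
    thr = _threshold_value(img, threshold)
    labelled = label(img > thr)
    h, w = labelled.shape
    regions, n_border, n_small = [], 0, 0
    for region in regionprops(labelled):
        r0, c0, r1, c1 = region.bbox
        if r0 == 0 or c0 == 0 or r1 == h or c1 == w:
            n_border += 1
        elif region.area < min_area_px:
            n_small += 1
        else:
            regions.append(region)
    return SegmentationResult(regions, n_border, n_small, thr)


_SWEEP = np.deg2rad(np.arange(0.0, 180.0, 0.5))
_SWEEP_DIRS = np.stack([np.cos(_SWEEP), np.sin(_SWEEP)])


def feret_diameters(coords: np.ndarray) -> tuple[float, float]:
    """(max Feret, perpendicular Feret) in pixels from region pixel
    coordinates (rows of [row, col] pixel centers).

    The max Feret is the exact diameter of the convex hull of the pixel
    centers (the rotating-calipers maximum). Its direction is taken as the
    angle maximising the caliper width over a 0.5-degree sweep — more stable
    against pixel quantisation than the maximising chord itself — and the
    perpendicular Feret is the hull's projection width at 90 degrees to it.
    """
    pts = np.asarray(coords, dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least 2 pixels for a caliper measurement")
    unique = np.unique(pts, axis=0)
    if len(unique) > 3:
        try:
            hull_pts = unique[ConvexHull(unique).vertices]
        except Exception:  # degenerate (collinear) regions
            hull_pts = unique
    else:
        hull_pts = unique
    diff = hull_pts[:, None, :] - hull_pts[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    max_feret = float(np.sqrt(d2.max()))
    if max_feret == 0.0:
        raise ValueError("degenerate region: all pixels coincide")
    proj = hull_pts @ _SWEEP_DIRS
    widths = proj.max(axis=0) - proj.min(axis=0)
    k = int(np.argmax(widths))
    perp = float(widths[(k + len(_SWEEP) // 2) % len(_SWEEP)])
    return max_feret, perp


def measure(region, scale: ImageScale) -> ParticleMeasurement:
    """Caliper and area measurements of one labelled region, scaled to um.

    The region's area is its pixel count; CED = 2*sqrt(area/pi). Degenerate
    sub-2-pixel regions are rejected.
    """
    coords = region.coords
    if len(coords) < 2:
        raise ValueError("region too small to measure (needs >= 2 pixels)")
    max_f, perp_f = feret_diameters(coords)
    # the half-coverage threshold places region edges on the particle
    # outline, so center calipers are reported uncorrected; degenerate
    # single-row regions get a one-pixel floor
    perp_f = max(perp_f, 1.0)
    s = scale.microns_per_pixel
    area_px = float(region.area)
    ced_px = 2.0 * np.sqrt(area_px / np.pi)
    cy, cx = region.centroid
    return ParticleMeasurement(
        max_feret=max_f * s,
        perp_feret=min(perp_f, max_f) * s,
        ced=ced_px * s,
        projected_area=area_px * s * s,
        centroid=(cy * s, cx * s),
    )


def batch_from_image(
    image: np.ndarray,
    scale: ImageScale,
    sample_mass: float,
    min_area_px: int = 20,
    threshold: str | float = "otsu",
) -> PelletBatch:
    """Segment and measure every pellet in an image and attach the weighed
    sample mass [mg]. Zero regions with a nonzero mass is an error (the
    density of the batch would be undefined)."""
    seg = segment(image, min_area_px=min_area_px, threshold=threshold)
    measurements = [measure(r, scale) for r in seg.regions]
    if not measurements and sample_mass > 0:
        raise ValueError(
            "no particles found but sample mass is nonzero: density undefined"
        )
    return PelletBatch(
        max_feret=np.array([m.max_feret for m in measurements]),
        perp_feret=np.array([m.perp_feret for m in measurements]),
        sample_mass=sample_mass,
    )
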