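"""Disc segmentation: median filtering, contour interpolation, bone exclusion.

The masking procedure mirrors how mouse intervertebral discs are isolated
from in vivo microCT scans: the volume is smoothed with a blended median
filter, polygonal contours drawn around the outer edge of the vertebral
bodies on sparse keyframe slices are interpolated through the stack, bone
voxels are removed by a grayscale threshold, and the resulting binary mask
is smoothed with a morphological open followed by a close.

The "weight" of the median filter is interpreted as a convex blend,
``out = weight * median + (1 - weight) * original``: weight 1 is a pure
median filter and weight 0 the identity, the only reading consistent with
a weight constrained to [0, 1].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import polygon2mask
from skimage.filters import threshold_otsu
from skimage.morphology import ball

from .volume_io import Volume3D

__all__ = [
    "ContourKeyframe",
    "ContourSet",
    "BinaryMask",
    "blended_median_filter",
    "interpolate_contours",
    "rasterize_to_mask",
    "exclude_bone",
    "suggest_bone_threshold",
    "smooth_mask",
    "read_contours",
    "write_contours",
]


@dataclass
class BinaryMask:
    """3D boolean mask aligned to a companion :class:`Volume3D`."""

    voxels: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3D (z, y, x)")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def count(self) -> int:
        return int(self.voxels.sum())

    def dice(self, other: "BinaryMask") -> float:
        """Dice overlap coefficient with another mask of the same shape."""
        a, b = self.voxels, other.voxels
        if a.shape != b.shape:
            raise ValueError("masks must share a shape")
        denom = a.sum() + b.sum()
        if denom == 0:
            return 1.0
        return 2.0 * np.logical_and(a, b).sum() / denom


@dataclass
class ContourKeyframe:
    """A closed polygon on one transverse slice, vertices in (y, x) voxels."""

    slice_index: int
    polygon: np.ndarray

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float)
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2:
            raise ValueError("polygon must be an (n, 2) array of (y, x) vertices")
        if len(self.polygon) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        from shapely.geometry import Polygon

        poly = Polygon(self.polygon)
        if not poly.is_simple or poly.area == 0:
            raise ValueError(
                f"keyframe at slice {self.slice_index}: polygon must be simple "
                f"with nonzero area"
            )


@dataclass
class ContourSet:
    """Keyframe contours ordered by strictly increasing slice index."""

    keyframes: Sequence[ContourKeyframe]

    def __post_init__(self) -> None:
        self.keyframes = list(self.keyframes)
        if len(self.keyframes) < 2:
            raise ValueError("a contour set needs at least 2 keyframes")
        idx = [k.slice_index for k in self.keyframes]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(f"keyframe slice indices must strictly increase, got {idx}")

    @property
    def slice_indices(self) -> list[int]:
        return [k.slice_index for k in self.keyframes]

    @property
    def span(self) -> tuple[int, int]:
        return self.keyframes[0].slice_index, self.keyframes[-1].slice_index


def write_contours(contours: ContourSet, path: str | Path) -> None:
    """Save keyframe contours as a flat JSON file."""
    recs = [{"slice_index": k.slice_index, "polygon": k.polygon.tolist()}
            for k in contours.keyframes]
    Path(path).write_text(json.dumps({"keyframes": recs}, indent=2))


def read_contours(path: str | Path) -> ContourSet:
    d = json.loads(Path(path).read_text())
    return ContourSet([ContourKeyframe(r["slice_index"], np.array(r["polygon"]))
                       for r in d["keyframes"]])


# ---------------------------------------------------------------------------
# filtering


def blended_median_filter(volume: Volume3D, weight: float = 0.8,
                          radius: int = 7) -> Volume3D:
    """Blend of a cubic-neighborhood median filter with the original volume.

    ``out = weight * median(cube of edge 2*radius+1) + (1 - weight) * in``,
    with edge-replicated borders.  Output is real valued.  Integer volumes
    use an exact sliding-histogram median; float volumes fall back to
    selection filtering.
    """
    if not 0.0 <= weight <= 1.0:
        raise ValueError(f"weight must lie in [0, 1], got {weight}")
    if not (isinstance(radius, (int, np.integer)) and radius >= 1):
        raise ValueError(f"radius must be an integer >= 1, got {radius}")
    vox = volume.voxels
    if np.issubdtype(vox.dtype, np.integer):
        from ._median import median_filter_u16

        med = median_filter_u16(vox, radius).astype(np.float64)
    else:
        med = ndi.median_filter(vox, size=2 * radius + 1, mode="nearest")
        med = med.astype(np.float64)
    out = weight * med + (1.0 - weight) * vox.astype(np.float64)
    return Volume3D(out, volume.voxel_size, volume.intensity_units)


# ---------------------------------------------------------------------------
# contour interpolation


def _rasterize_keyframe(kf: ContourKeyframe, plane_shape: tuple[int, int]
                        ) -> np.ndarray:
    region = polygon2mask(plane_shape, kf.polygon)
    if not region.any():
        raise ValueError(f"keyframe at slice {kf.slice_index} rasterizes to an "
                         f"empty region on a {plane_shape} plane")
    return region


def _signed_distance(region: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance to the region boundary, negative inside."""
    return (ndi.distance_transform_edt(~region)
            - ndi.distance_transform_edt(region))


def interpolate_contours(contours: ContourSet, z_range: tuple[int, int],
                         plane_shape: tuple[int, int]
                         ) -> dict[int, np.ndarray]:
    """Morph keyframe contours through the stack by linear interpolation.

    Keyframe slices reproduce the rasterized keyframe polygon exactly.
    Between consecutive keyframes the region at fractional position
    ``a`` is the level set ``(1-a)*d1 + a*d2 <= 0`` of the two keyframes'
    signed Euclidean distance transforms (negative inside).  Signed-distance
    interpolation is well defined for polygons with unequal vertex counts,
    where direct vertex correspondence is not.

    No extrapolation: ``z_range`` must lie within the keyframe span.
    """
    z_lo, z_hi = int(z_range[0]), int(z_range[1])
    first, last = contours.span
    if z_lo > z_hi:
        raise ValueError(f"empty z_range {z_range}")
    if z_lo < first or z_hi > last:
        raise ValueError(
            f"z_range {z_range} extends outside the keyframe span "
            f"[{first}, {last}]; contours are never extrapolated"
        )

    rasters = {k.slice_index: _rasterize_keyframe(k, plane_shape)
               for k in contours.keyframes}
    sdfs: dict[int, np.ndarray] = {}

    def sdf(zi: int) -> np.ndarray:
        if zi not in sdfs:
            sdfs[zi] = _signed_distance(rasters[zi])
        return sdfs[zi]

    kf_idx = contours.slice_indices
    out: dict[int, np.ndarray] = {}
    for z in range(z_lo, z_hi + 1):
        if z in rasters:
            out[z] = rasters[z].copy()
            continue
        j = int(np.searchsorted(kf_idx, z))
        z1, z2 = kf_idx[j - 1], kf_idx[j]
        alpha = (z - z1) / (z2 - z1)
        blend = (1.0 - alpha) * sdf(z1) + alpha * sdf(z2)
        out[z] = blend <= 0
    return out


def rasterize_to_mask(regions: Mapping[int, np.ndarray],
                      volume_shape: tuple[int, int, int],
                      voxel_size: float) -> BinaryMask:
    """Stack per-slice regions into a 3D mask; uncontoured slices stay empty."""
    nz, ny, nx = volume_shape
    vox = np.zeros(volume_shape, dtype=bool)
    for z, region in regions.items():
        if not 0 <= z < nz:
            raise ValueError(f"slice {z} outside volume of {nz} slices")
        region = np.asarray(region, dtype=bool)
        if region.shape != (ny, nx):
            raise ValueError(
                f"slice {z} region shape {region.shape} != plane shape {(ny, nx)}"
            )
        vox[z] = region
    return BinaryMask(vox, voxel_size)


# ---------------------------------------------------------------------------
# bone exclusion


def exclude_bone(volume: Volume3D, roi: BinaryMask,
                 bone_threshold: float) -> BinaryMask:
    """Remove voxels at or above the bone threshold from the ROI.

    Applied to the *filtered* volume in the standard pipeline, since
    filtering precedes masking.  Raises if the threshold removes every
    ROI voxel.
    """
    if roi.shape != volume.shape:
        raise ValueError("roi shape must match volume shape")
    if roi.count == 0:
        raise ValueError("roi is empty")
    keep = roi.voxels & (volume.voxels < bone_threshold)
    if not keep.any():
        raise ValueError(
            f"bone threshold {bone_threshold} removed every ROI voxel"
        )
    return BinaryMask(keep, roi.voxel_size)


def suggest_bone_threshold(volume: Volume3D, roi: BinaryMask) -> float:
    """Otsu's threshold over ROI intensities; advisory, caller may override.

    Requires the ROI to contain both attenuation modes (bone and disc);
    a constant-intensity ROI has no threshold and raises.
    """
    if roi.shape != volume.shape:
        raise ValueError("roi shape must match volume shape")
    vals = volume.voxels[roi.voxels]
    if vals.size == 0:
        raise ValueError("roi is empty")
    if np.ptp(vals) == 0:
        raise ValueError("roi intensities are constant; no threshold exists")
    t = threshold_otsu(vals)
    # Otsu splits classes as (<= t) vs (> t); bone exclusion removes
    # voxels >= threshold, so return the midpoint of the class gap to be
    # convention-independent.
    lower = vals[vals <= t].max()
    upper = vals[vals > t].min()
    return float((lower + upper) / 2.0)


# ---------------------------------------------------------------------------
# morphological smoothing


def smooth_mask(mask: BinaryMask, radius: int = 2) -> BinaryMask:
    """Morphological opening then closing with a discrete ball element.

    Opening removes specks smaller than the element; closing fills voids.
    """
    if not (isinstance(radius, (int, np.integer)) and radius >= 1):
        raise ValueError(f"radius must be an integer >= 1, got {radius}")
    elem = ball(radius)
    opened = ndi.binary_opening(mask.voxels, structure=elem)
    closed = ndi.binary_closing(opened, structure=elem)
    return BinaryMask(closed, mask.voxel_size)
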