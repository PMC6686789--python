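"""Per-disc morphometry and contrast-uptake metrics.

Metrics mirror the standard contrast-enhanced microCT readouts for the
mouse intervertebral disc: mask volume (voxel count times voxel volume),
mean attenuation (average 16-bit grayscale inside the mask), the DI/DI0
post/pre attenuation ratio, and the average disc height across evenly
spaced points along the mid-sagittal plane.  For staggered multi-timepoint
acquisitions the per-level summary is the maximum attenuation over the
post-injection timepoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .segmentation import BinaryMask
from .volume_io import ScanMetadata, Volume3D

__all__ = [
    "DiscMetrics",
    "disc_volume",
    "mean_attenuation",
    "attenuation_ratio",
    "disc_height",
    "max_over_timepoints",
    "metrics_to_frame",
    "write_metrics_csv",
    "read_metrics_csv",
]

METRICS_COLUMNS = ["subject_id", "age_group", "level", "minutes",
                   "volume_mm3", "mean_attenuation", "di_ratio",
                   "disc_height_um"]


@dataclass
class DiscMetrics:
    """Per-scan disc measurements.

    ``di_ratio`` is None for baseline (pre-injection) scans.
    """

    volume_mm3: float
    mean_attenuation: float
    disc_height_um: float
    di_ratio: float | None = None
    metadata: ScanMetadata | None = None

    def __post_init__(self) -> None:
        if not self.volume_mm3 > 0:
            raise ValueError("volume_mm3 must be positive")
        if self.mean_attenuation < 0:
            raise ValueError("mean_attenuation must be >= 0")
        if self.di_ratio is not None and not self.di_ratio > 0:
            raise ValueError("di_ratio must be positive when present")


def disc_volume(mask: BinaryMask) -> float:
    """Disc volume in mm^3: voxel count times the voxel volume."""
    n = mask.count
    if n == 0:
        raise ValueError("mask is empty")
    return n * (mask.voxel_size / 1000.0) ** 3


def mean_attenuation(volume: Volume3D, mask: BinaryMask) -> float:
    """Arithmetic mean grayscale value over the mask voxels."""
    if mask.shape != volume.shape:
        raise ValueError("mask shape must match volume shape")
    if mask.count == 0:
        raise ValueError("mask is empty")
    return float(volume.voxels[mask.voxels].mean())


def attenuation_ratio(post: DiscMetrics, pre: DiscMetrics) -> float:
    """Post/pre mean-attenuation ratio DI/DI0 for one subject and level."""
    if post.metadata is not None and pre.metadata is not None:
        if (post.metadata.subject_id != pre.metadata.subject_id
                or post.metadata.level != pre.metadata.level):
            raise ValueError(
                f"cannot normalize {post.metadata.subject_id}/"
                f"{post.metadata.level} against "
                f"{pre.metadata.subject_id}/{pre.metadata.level}: "
                f"subject and level must match"
            )
    if not pre.mean_attenuation > 0:
        raise ValueError("baseline mean attenuation must be positive")
    return post.mean_attenuation / pre.mean_attenuation


def _longest_run(column: np.ndarray) -> int:
    """Length of the longest contiguous run of True along a 1D column."""
    if not column.any():
        return 0
    padded = np.concatenate([[False], column, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2]
    return int((stops - starts).max())


def disc_height(disc_mask: BinaryMask, n_points: int = 5) -> float:
    """Average disc height over ``n_points`` along the mid-sagittal plane.

    The mid-sagittal plane is the sagittal (fixed-x) slice through the
    mask centroid.  Within it, ``n_points`` anterior-posterior positions
    are evenly spaced between the 10th and 90th percentile of the mask's
    in-plane extent (trimming avoids degenerate columns at the disc rim,
    where the cranial-caudal chord vanishes).  Height at each position is
    the longest contiguous run of mask voxels along the cranial-caudal
    axis, times the voxel size.  Empty sampling columns are skipped with
    a warning.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    vox = disc_mask.voxels
    if not vox.any():
        raise ValueError("mask is empty")
    zs, ys, xs = np.nonzero(vox)
    x_mid = int(np.rint(xs.mean()))
    plane = vox[:, :, x_mid]
    ys_in_plane = np.flatnonzero(plane.any(axis=0))
    if ys_in_plane.size == 0:
        raise ValueError("mid-sagittal plane contains no mask voxels")
    y_lo, y_hi = ys_in_plane.min(), ys_in_plane.max()
    span = y_hi - y_lo
    positions = np.rint(y_lo + span * np.linspace(0.1, 0.9, n_points)
                        ).astype(int)
    heights = []
    for y in positions:
        run = _longest_run(plane[:, y])
        if run == 0:
            warnings.warn(
                f"disc_height: empty sampling column at y={y}; skipped",
                stacklevel=2,
            )
            continue
        heights.append(run * disc_mask.voxel_size)
    if not heights:
        raise ValueError("all disc-height sampling columns were empty")
    return float(np.mean(heights))


def max_over_timepoints(series: Sequence[DiscMetrics]
                        ) -> tuple[DiscMetrics, float]:
    """Entry with maximal mean attenuation over post-injection timepoints.

    ``series`` must be ordered by strictly increasing minutes for one
    subject and level.  Ties go to the earliest timepoint (the plateau
    onset).
    """
    if len(series) == 0:
        raise ValueError("series is empty")
    minutes = []
    for m in series:
        if m.metadata is None or m.metadata.minutes_post_injection is None:
            raise ValueError("max_over_timepoints requires post-injection "
                             "scans with timing metadata")
        minutes.append(m.metadata.minutes_post_injection)
    if any(b <= a for a, b in zip(minutes, minutes[1:])):
        raise ValueError("series must be ordered by strictly increasing minutes")
    subjects = {(m.metadata.subject_id, m.metadata.level) for m in series}
    if len(subjects) > 1:
        raise ValueError(f"series mixes subjects/levels: {sorted(subjects)}")
    best = max(range(len(series)),
               key=lambda i: (series[i].mean_attenuation, -minutes[i]))
    return series[best], minutes[best]


# ---------------------------------------------------------------------------
# tidy-table plumbing


def metrics_to_frame(metrics: Sequence[DiscMetrics]) -> pd.DataFrame:
    """One row per scan: subject, age_group, level, minutes and metrics."""
    rows = []
    for m in metrics:
        md = m.metadata
        rows.append({
            "subject_id": md.subject_id if md else "",
            "age_group": md.age_group if md else "",
            "level": md.level if md else "",
            "minutes": (np.nan if md is None or md.minutes_post_injection is None
                        else md.minutes_post_injection),
            "volume_mm3": m.volume_mm3,
            "mean_attenuation": m.mean_attenuation,
            "di_ratio": np.nan if m.di_ratio is None else m.di_ratio,
            "disc_height_um": m.disc_height_um,
        })
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)


def write_metrics_csv(metrics: Sequence[DiscMetrics], path: str | Path) -> None:
    metrics_to_frame(metrics).to_csv(path, index=False)


def read_metrics_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(METRICS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metrics CSV {path} lacks columns {sorted(missing)}")
    return df
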