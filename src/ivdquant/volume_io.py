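"""Volumetric image I/O and the canonical in-memory volume representation.

All volumes in this package are indexed ``(z, y, x)`` with ``z`` the scan
axis (cranial-caudal for spine scans), ``y`` the anterior-posterior axis
and ``x`` the left-right axis.  Voxels are isotropic; anisotropic inputs
are rejected rather than resampled, because silent resampling would change
every downstream metric.

Raw scans are unsigned 16-bit grayscale.  Filtered volumes are real valued
and stored on disk as 32-bit float (TIFF/NIfTI only; DICOM is restricted
to integer data).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, NamedTuple, Sequence

import numpy as np

__all__ = [
    "Volume3D",
    "ScanMetadata",
    "AGE_GROUPS",
    "SPINAL_LEVELS",
    "read_volume",
    "write_volume",
    "read_metadata",
    "write_metadata",
    "masked_histogram",
    "HistogramResult",
]

VolumeFormat = Literal["dicom_series", "nifti", "tiff_stack"]

AGE_GROUPS = ("growing_3mo", "adult_8mo")
SPINAL_LEVELS = ("CC5_CC6", "L5_L6", "T12_T13")

#: Relative tolerance used when checking that voxel spacing is isotropic.
_ISO_RTOL = 1e-5


@dataclass
class Volume3D:
    """A 3D grayscale voxel grid with isotropic spacing.

    Parameters
    ----------
    voxels:
        3D array indexed ``(z, y, x)``.  Unsigned 16-bit for raw scans,
        floating point after filtering.
    voxel_size:
        Physical edge length of a voxel in micrometers (isotropic).
    intensity_units:
        Free-text label for the intensity scale; raw scans use
        ``"grayscale"`` (16-bit scanner export units).
    """

    voxels: np.ndarray
    voxel_size: float
    intensity_units: str = "grayscale"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError(
                f"voxels must be a non-empty 3D (z, y, x) array, got shape "
                f"{self.voxels.shape}"
            )
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if np.issubdtype(self.voxels.dtype, np.integer):
            lo, hi = int(self.voxels.min()), int(self.voxels.max())
            if lo < 0 or hi > 65535:
                raise ValueError(
                    f"integer volumes must lie within [0, 65535], got [{lo}, {hi}]"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def astype_float(self) -> "Volume3D":
        """Return a float64 copy (no-op scaling)."""
        return Volume3D(self.voxels.astype(np.float64), self.voxel_size,
                        self.intensity_units)


@dataclass
class ScanMetadata:
    """Identity and acquisition context of one scan.

    ``minutes_post_injection is None`` marks a pre-injection baseline scan.
    """

    subject_id: str
    age_group: str
    level: str
    minutes_post_injection: float | None = None

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"age_group must be one of {AGE_GROUPS}, "
                             f"got {self.age_group!r}")
        if self.level not in SPINAL_LEVELS:
            raise ValueError(f"level must be one of {SPINAL_LEVELS}, "
                             f"got {self.level!r}")
        if self.minutes_post_injection is not None:
            if not float(self.minutes_post_injection) >= 0:
                raise ValueError("minutes_post_injection must be >= 0 or None")
            self.minutes_post_injection = float(self.minutes_post_injection)

    @property
    def is_baseline(self) -> bool:
        return self.minutes_post_injection is None


# ---------------------------------------------------------------------------
# format helpers


def _infer_format(path: Path) -> VolumeFormat:
    if path.is_dir():
        return "dicom_series"
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".tif", ".tiff")):
        return "tiff_stack"
    raise ValueError(f"cannot infer volume format from {path}")


def _check_isotropic(spacings_um: Sequence[float], where: str) -> float:
    s = np.asarray(spacings_um, dtype=float)
    if not np.allclose(s, s[0], rtol=_ISO_RTOL, atol=0):
        raise ValueError(
            f"non-isotropic voxel spacing {tuple(s)} um in {where}: this "
            f"pipeline assumes isotropic voxels and does not resample"
        )
    return float(s[0])


def _read_dicom_series(path: Path) -> Volume3D:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise ValueError(f"no .dcm files in {path}")
    datasets = [pydicom.dcmread(str(p)) for p in files]
    datasets.sort(key=lambda d: float(d.ImagePositionPatient[2]))

    rows, cols = datasets[0].Rows, datasets[0].Columns
    px = [float(v) for v in datasets[0].PixelSpacing]
    for d in datasets:
        if (d.Rows, d.Columns) != (rows, cols):
            raise ValueError(
                f"inconsistent slice dimensions in DICOM series {path}: "
                f"({d.Rows}, {d.Columns}) vs ({rows}, {cols})"
            )
        if [float(v) for v in d.PixelSpacing] != px:
            raise ValueError(f"inconsistent PixelSpacing in DICOM series {path}")

    zs = np.array([float(d.ImagePositionPatient[2]) for d in datasets])
    if len(zs) > 1:
        dz = np.diff(zs)
        if not np.allclose(dz, dz[0], rtol=_ISO_RTOL, atol=1e-9):
            raise ValueError(f"irregular slice spacing in DICOM series {path}")
        spacing_mm = [dz[0], px[0], px[1]]
    else:
        spacing_mm = [px[0], px[0], px[1]]
    voxel_size = _check_isotropic([s * 1000.0 for s in spacing_mm], str(path))

    vol = np.stack([d.pixel_array for d in datasets], axis=0)
    return Volume3D(vol, voxel_size)


def _write_dicom_series(volume: Volume3D, path: Path) -> None:
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage

    if not np.issubdtype(volume.voxels.dtype, np.integer):
        raise ValueError("DICOM export supports integer (raw) volumes only; "
                         "write filtered volumes to nifti or tiff_stack")
    path.mkdir(parents=True, exist_ok=True)
    data = volume.voxels.astype(np.uint16)
    mm = volume.voxel_size / 1000.0
    series_uid = pydicom.uid.generate_uid()
    study_uid = pydicom.uid.generate_uid()
    for z in range(data.shape[0]):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "CT"
        ds.InstanceNumber = z + 1
        ds.ImagePositionPatient = [0.0, 0.0, z * mm]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [mm, mm]
        ds.SliceThickness = mm
        ds.Rows, ds.Columns = data.shape[1], data.shape[2]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = data[z].tobytes()
        ds.save_as(str(path / f"slice_{z:04d}.dcm"), enforce_file_format=True)


def _read_nifti(path: Path) -> Volume3D:
    import nibabel as nib

    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    voxel_size = _check_isotropic([z * 1000.0 for z in zooms], str(path))
    # stored (x, y, z); transpose back to (z, y, x)
    data = np.asanyarray(img.dataobj).T
    return Volume3D(data, voxel_size)


def _write_nifti(volume: Volume3D, path: Path) -> None:
    import nibabel as nib

    data = volume.voxels
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.uint16)
    else:
        data = data.astype(np.float32)
    mm = volume.voxel_size / 1000.0
    affine = np.diag([mm, mm, mm, 1.0])
    img = nib.Nifti1Image(data.T, affine)
    img.header.set_zooms((mm, mm, mm))
    nib.save(img, str(path))


def _read_tiff(path: Path) -> Volume3D:
    import tifffile

    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description or "{}"
    try:
        meta = json.loads(desc)
    except json.JSONDecodeError:
        meta = {}
    if "voxel_size_um" not in meta:
        raise ValueError(f"TIFF stack {path} lacks voxel_size_um metadata")
    if data.ndim != 3:
        raise ValueError(f"TIFF stack {path} is not a 3D volume")
    return Volume3D(data, float(meta["voxel_size_um"]))


def _write_tiff(volume: Volume3D, path: Path) -> None:
    import tifffile

    data = volume.voxels
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.uint16)
    else:
        data = data.astype(np.float32)
    desc = json.dumps({"voxel_size_um": volume.voxel_size,
                       "axes_order": "zyx"})
    tifffile.imwrite(str(path), data, description=desc)


def read_volume(path: str | Path, format: VolumeFormat | None = None) -> Volume3D:
    """Read a volumetric scan from disk.

    Supported formats: a directory of single-slice DICOM files
    (``dicom_series``), a NIfTI-1 file (``nifti``) or a multi-page TIFF
    (``tiff_stack``).  Slices are returned in ascending z order; voxel
    size comes from the file metadata and must be isotropic.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "dicom_series":
        return _read_dicom_series(path)
    if fmt == "nifti":
        return _read_nifti(path)
    if fmt == "tiff_stack":
        return _read_tiff(path)
    raise ValueError(f"unknown volume format {fmt!r}")


def write_volume(volume: Volume3D, path: str | Path,
                 format: VolumeFormat | None = None) -> None:
    """Write a volume to disk; lossless round-trip for integer volumes."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "dicom_series":
        _write_dicom_series(volume, path)
    elif fmt == "nifti":
        _write_nifti(volume, path)
    elif fmt == "tiff_stack":
        path.parent.mkdir(parents=True, exist_ok=True)
        _write_tiff(volume, path)
    else:
        raise ValueError(f"unknown volume format {fmt!r}")


def write_metadata(meta: ScanMetadata, path: str | Path) -> None:
    """Write a ScanMetadata sidecar as a flat JSON key-value file."""
    Path(path).write_text(json.dumps({
        "subject_id": meta.subject_id,
        "age_group": meta.age_group,
        "level": meta.level,
        "minutes_post_injection": meta.minutes_post_injection,
    }, indent=2))


def read_metadata(path: str | Path) -> ScanMetadata:
    d = json.loads(Path(path).read_text())
    return ScanMetadata(**d)


# ---------------------------------------------------------------------------
# histogram


class HistogramResult(NamedTuple):
    """Intensity histogram restricted to a mask: lower bin edges and counts."""

    lower_edges: np.ndarray
    counts: np.ndarray

    @property
    def mean(self) -> float:
        """Mean intensity estimated from bin lower edges (for coarse QC)."""
        return float(np.average(self.lower_edges, weights=self.counts))


def masked_histogram(volume: Volume3D, mask, bin_width: float = 64.0
                     ) -> HistogramResult:
    """Histogram of voxel intensities inside a binary mask.

    Bins are aligned to multiples of ``bin_width`` and cover the observed
    intensity range; counts sum to the number of true mask voxels.  The
    default bin width of 64 grayscale units gives 1024 bins over the
    16-bit range.
    """
    mvox = np.asarray(getattr(mask, "voxels", mask), dtype=bool)
    if mvox.shape != volume.shape:
        raise ValueError(f"mask shape {mvox.shape} != volume shape {volume.shape}")
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    vals = volume.voxels[mvox]
    if vals.size == 0:
        raise ValueError("mask selects no voxels; nothing to histogram")
    lo = np.floor(vals.min() / bin_width) * bin_width
    hi = np.floor(vals.max() / bin_width + 1) * bin_width
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(vals, bins=edges)
    return HistogramResult(edges[:-1], counts)
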