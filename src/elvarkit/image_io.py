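"""Reading and writing CT volumes and binary masks.

All computational modules operate on :class:`CTVolume` (a calibrated
Hounsfield-unit grid) and :class:`BinaryMask` (a boolean grid bound to a
volume lattice).  This module isolates every on-disk dialect — DICOM
series, NIfTI, compressed numpy archives — from the pipeline proper.

Axis convention
---------------
Arrays are indexed ``(slice, row, col)``; the slice axis runs
cranio-caudal.  ``spacing`` follows the same order, in millimetres.
Intensities inside the pipeline are always Hounsfield units (HU); display
windowing is a rendering concern and is never applied to data.
"""

from __future__ import annotations

import uuid
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

__all__ = [
    "CTVolume",
    "BinaryMask",
    "MaskRole",
    "load_ct_series",
    "load_nifti",
    "save_nifti",
    "save_dicom_series",
    "save_mask",
    "load_mask",
]

MaskRole = Literal["coarse_air", "filled_contour", "hole", "lung_final", "interstitium"]

_MASK_FORMATS = ("nifti", "npz")

#: HU range representable by 12-bit CT acquisition; used for sanity checks.
HU_MIN, HU_MAX = -1024, 3071


@dataclass
class CTVolume:
    """A calibrated 3-D CT intensity grid.

    Parameters
    ----------
    data:
        3-D float array in Hounsfield units, axes ``(slice, row, col)``.
    spacing:
        Voxel spacing in mm, ``(slice, row, col)`` order; all components
        strictly positive.
    origin:
        Physical position of voxel ``(0, 0, 0)`` in mm.
    slice_positions:
        Physical position of each slice along the scan axis, strictly
        increasing after sorting.
    source_meta:
        Free-form provenance (series UID, rescale slope/intercept as read,
        vendor string, ...).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    slice_positions: np.ndarray | None = None
    source_meta: dict = field(default_factory=dict)
    grid_id: str = field(default_factory=lambda: uuid.uuid4().hex)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"CT data must have exactly 3 axes, got {self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be positive, got {self.spacing}")
        if self.slice_positions is None:
            self.slice_positions = self.origin[0] + self.spacing[0] * np.arange(
                self.data.shape[0], dtype=float
            )
        self.slice_positions = np.asarray(self.slice_positions, dtype=float)
        if np.any(np.diff(self.slice_positions) <= 0):
            raise ValueError("slice positions must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def new_mask(self, data: np.ndarray, role: MaskRole) -> "BinaryMask":
        """Create a mask bound to this volume's lattice."""
        return BinaryMask(data=data, grid_ref=self.grid_id, role=role, spacing=self.spacing)


@dataclass
class BinaryMask:
    """A boolean grid on the lattice of a :class:`CTVolume`."""

    data: np.ndarray
    grid_ref: str
    role: MaskRole
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def popcount(self) -> int:
        """Number of true voxels."""
        return int(self.data.sum())

    def same_lattice(self, other: "BinaryMask | CTVolume") -> bool:
        ref = other.grid_id if isinstance(other, CTVolume) else other.grid_ref
        return self.grid_ref == ref and self.shape == other.shape


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------


def load_ct_series(directory: str | Path) -> CTVolume:
    """Load a single-frame-per-file CT DICOM series into a calibrated volume.

    Slices are sorted by physical position along the scan axis regardless of
    on-disk file order, and stored values are rescaled to HU exactly once
    using each file's rescale slope and intercept.

    Raises
    ------
    ValueError
        On fewer than 3 slices, mixed series, missing rescale tags (the
        offending file is named), non-uniform in-plane spacing, duplicate
        slice positions, or inter-slice gaps exceeding twice the modal
        spacing (non-contiguous scans are rejected, not interpolated).
    """
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in paths:
        try:
            ds = pydicom.dcmread(p)
        except (pydicom.errors.InvalidDicomError, IsADirectoryError):
            continue
        if not hasattr(ds, "PixelData"):
            continue
        datasets.append((p, ds))
    if len(datasets) < 3:
        raise ValueError(
            f"need at least 3 CT slices in {directory}, found {len(datasets)}"
        )

    uids = {str(getattr(ds, "SeriesInstanceUID", "")) for _, ds in datasets}
    if len(uids) > 1:
        raise ValueError(f"mixed series in {directory}: {sorted(uids)}")

    slices = []
    for p, ds in datasets:
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise ValueError(f"missing rescale slope/intercept in {p}")
        slope = float(ds.RescaleSlope)
        intercept = float(ds.RescaleIntercept)
        if "ImagePositionPatient" in ds:
            zpos = float(ds.ImagePositionPatient[2])
        elif "SliceLocation" in ds:
            zpos = float(ds.SliceLocation)
        else:
            raise ValueError(f"no slice position tag in {p}")
        hu = ds.pixel_array.astype(np.float32) * slope + intercept
        slices.append((zpos, tuple(float(v) for v in ds.PixelSpacing), hu, ds, p))

    slices.sort(key=lambda t: t[0])
    zs = np.array([s[0] for s in slices])
    dz = np.diff(zs)
    if np.any(dz == 0):
        raise ValueError("duplicate slice positions in series")
    pixel_spacings = {s[1] for s in slices}
    if len(pixel_spacings) > 1:
        raise ValueError(f"non-uniform in-plane spacing across slices: {pixel_spacings}")
    modal_dz = float(np.median(dz))
    if np.any(dz > 2.0 * modal_dz + 1e-9):
        raise ValueError(
            f"inter-slice gap {dz.max():.2f} mm exceeds twice the modal spacing "
            f"{modal_dz:.2f} mm; non-contiguous series rejected"
        )

    data = np.stack([s[2] for s in slices], axis=0)
    row_mm, col_mm = slices[0][1]
    ds0 = slices[0][3]
    origin = (
        float(zs[0]),
        float(ds0.ImagePositionPatient[1]) if "ImagePositionPatient" in ds0 else 0.0,
        float(ds0.ImagePositionPatient[0]) if "ImagePositionPatient" in ds0 else 0.0,
    )
    meta = {
        "series_uid": str(getattr(ds0, "SeriesInstanceUID", "")),
        "rescale_slope": float(ds0.RescaleSlope),
        "rescale_intercept": float(ds0.RescaleIntercept),
        "vendor": str(getattr(ds0, "Manufacturer", "")),
        "n_files": len(slices),
    }
    return CTVolume(
        data=data,
        spacing=(modal_dz, row_mm, col_mm),
        origin=origin,
        slice_positions=zs,
        source_meta=meta,
    )


def save_dicom_series(vol: CTVolume, directory: str | Path, *, shuffle_names: bool = False) -> list[Path]:
    """Write a volume as a single-frame-per-slice CT DICOM series.

    Stored values use slope 1 / intercept −1024 so the full diagnostic HU
    range fits in unsigned 16-bit pixels. Returns the written paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    n = vol.shape[0]
    order = np.arange(n)
    if shuffle_names:
        order = order[::-1]  # deterministic non-sorted naming for tests
    written = []
    for name_idx, i in enumerate(order):
        sl = vol.data[i]
        stored = np.clip(np.round(sl - (-1024.0)), 0, 65535).astype(np.uint16)

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.Manufacturer = "elvarkit synthetic"
        ds.PatientName = "phantom"
        ds.PatientID = "phantom"
        ds.InstanceNumber = int(i) + 1
        ds.ImagePositionPatient = [
            float(vol.origin[2]),
            float(vol.origin[1]),
            float(vol.slice_positions[i]),
        ]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.SliceLocation = float(vol.slice_positions[i])
        ds.PixelSpacing = [float(vol.spacing[1]), float(vol.spacing[2])]
        ds.SliceThickness = float(vol.spacing[0])
        ds.Rows, ds.Columns = sl.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1
        ds.RescaleIntercept = -1024
        ds.PixelData = stored.tobytes()

        path = directory / f"slice_{name_idx:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------


def _nifti_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    # NIfTI x,y,z maps to our (col, row, slice); diagonal affine keeps the
    # round trip exact for axis-aligned synthetic data.
    return np.diag([spacing[2], spacing[1], spacing[0], 1.0])


def save_nifti(vol: CTVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI (values stay in HU)."""
    path = Path(path)
    img = nib.Nifti1Image(
        np.ascontiguousarray(vol.data.transpose(2, 1, 0)).astype(np.float32),
        _nifti_affine(vol.spacing),
    )
    nib.save(img, path)
    return path


def load_nifti(path: str | Path) -> CTVolume:
    """Load a single 3-D NIfTI volume; values are assumed already in HU.

    Axes are permuted to the package's ``(slice, row, col)`` convention and
    spacing is taken from the affine. 4-D images and images without affine
    metadata are rejected.
    """
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got {img.ndim}-D: {path}")
    if img.affine is None:
        raise ValueError(f"missing affine metadata: {path}")
    data = np.asarray(img.dataobj, dtype=np.float32).transpose(2, 1, 0)
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    origin = tuple(float(v) for v in img.affine[:3, 3][::-1])
    return CTVolume(
        data=data,
        spacing=spacing,
        origin=origin,
        source_meta={"path": str(path), "format": "nifti"},
    )


# ---------------------------------------------------------------------------
# Masks
# ---------------------------------------------------------------------------


def save_mask(mask: BinaryMask, path: str | Path, format: str = "nifti") -> Path:
    """Write a mask losslessly; ``format`` is ``"nifti"`` or ``"npz"``.

    The path extension must agree with the format (``.nii``/``.nii.gz`` for
    NIfTI, ``.npz`` for the compressed array format).
    """
    path = Path(path)
    if format not in _MASK_FORMATS:
        raise ValueError(f"unsupported format {format!r}; supported: {_MASK_FORMATS}")
    suffix = "".join(path.suffixes)
    if format == "nifti":
        if not (suffix.endswith(".nii") or suffix.endswith(".nii.gz")):
            raise ValueError(f"format 'nifti' requires a .nii/.nii.gz path, got {path}")
        img = nib.Nifti1Image(
            np.ascontiguousarray(mask.data.transpose(2, 1, 0)).astype(np.uint8),
            _nifti_affine(mask.spacing),
        )
        img.header["descrip"] = f"role={mask.role}".encode()[:80]
        nib.save(img, path)
    else:
        if not suffix.endswith(".npz"):
            raise ValueError(f"format 'npz' requires a .npz path, got {path}")
        np.savez_compressed(
            path,
            data=np.packbits(mask.data),
            shape=np.array(mask.shape),
            spacing=np.array(mask.spacing),
            role=np.array(mask.role),
            grid_ref=np.array(mask.grid_ref),
        )
    return path


def load_mask(path: str | Path, format: str | None = None) -> BinaryMask:
    """Load a mask written by :func:`save_mask`."""
    path = Path(path)
    suffix = "".join(path.suffixes)
    if format is None:
        format = "npz" if suffix.endswith(".npz") else "nifti"
    if format == "nifti":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj).transpose(2, 1, 0) > 0
        zooms = img.header.get_zooms()[:3]
        descrip = bytes(img.header["descrip"].tobytes()).rstrip(b"\x00").decode(errors="ignore")
        role = descrip.removeprefix("role=") if descrip.startswith("role=") else "lung_final"
        return BinaryMask(
            data=data,
            grid_ref=str(path),
            role=role,  # type: ignore[arg-type]
            spacing=(float(zooms[2]), float(zooms[1]), float(zooms[0])),
        )
    if format == "npz":
        with np.load(path) as f:
            shape = tuple(int(v) for v in f["shape"])
            data = np.unpackbits(f["data"])[: int(np.prod(shape))].reshape(shape).astype(bool)
            return BinaryMask(
                data=data,
                grid_ref=str(f["grid_ref"]),
                role=str(f["role"]),  # type: ignore[arg-type]
                spacing=tuple(float(v) for v in f["spacing"]),
            )
    raise ValueError(f"unsupported format {format!r}; supported: {_MASK_FORMATS}")
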