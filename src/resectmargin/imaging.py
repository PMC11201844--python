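"""Volume/mask data model, file I/O, isotropic resampling and metric morphology.

Conventions used throughout the package
---------------------------------------
* Arrays are indexed ``(z, y, x)``; world coordinates are millimetres in the
  same axis order.  The world position of voxel index ``i`` is
  ``origin + i * spacing`` — orientation is normalized to an axis-aligned
  identity when a file is loaded.
* CT intensities are Hounsfield Units (HU).
* Masks are boolean arrays sharing the exact lattice of the volume they
  annotate.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage as ndi

from .errors import (
    EmptyInputError,
    FormatError,
    GridMismatchError,
    MetadataError,
    PreconditionError,
    ResampleError,
)

# Thin-slice chest CT for margin reconstruction uses sub-1.5 mm slices; thicker
# inputs are accepted but flagged, since the pipeline's accuracy claims assume
# near-isotropic source data.
THICK_SLICE_WARNING_MM = 1.5


def _as_triple(value) -> tuple[float, float, float]:
    arr = np.asarray(value, dtype=float).reshape(-1)
    if arr.size == 1:
        arr = np.repeat(arr, 3)
    if arr.size != 3:
        raise ValueError("expected a scalar or length-3 sequence")
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass
class ImageVolume:
    """A 3D scalar grid in HU with physical spacing and origin (mm, z/y/x)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise PreconditionError("volume data must be 3D with each axis >= 1")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise PreconditionError("spacing components must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def grid(self) -> tuple[tuple, tuple, tuple]:
        """(shape, spacing, origin) triple identifying the lattice."""
        return (self.shape, self.spacing, self.origin)

    def same_grid(self, other: "ImageVolume | BinaryMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def is_isotropic(self, tol: float = 1e-6) -> bool:
        s = self.spacing
        return abs(s[0] - s[1]) <= tol and abs(s[1] - s[2]) <= tol

    def index_to_world(self, idx) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def world_to_index(self, pts) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)


@dataclass
class BinaryMask(ImageVolume):
    """Boolean grid on the same lattice as the volume it annotates."""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype != bool:
            self.data = self.data.astype(bool)
        super().__post_init__()

    def count(self) -> int:
        return int(self.data.sum())

    def centroid_mm(self) -> np.ndarray:
        if not self.data.any():
            raise EmptyInputError("centroid of an empty mask")
        idx = np.argwhere(self.data).mean(axis=0)
        return self.index_to_world(idx)[0]

    def like(self, data: np.ndarray) -> "BinaryMask":
        """New mask on this mask's lattice."""
        return BinaryMask(data, self.spacing, self.origin)


def _require_same_grid(a: ImageVolume, b: ImageVolume) -> None:
    if not a.same_grid(b):
        raise GridMismatchError("inputs are not on the same lattice")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def _from_sitk(img: sitk.Image) -> ImageVolume:
    # Normalize orientation to axis-aligned identity: reorient the data array
    # so the stored direction cosines become the identity matrix.
    if img.GetDimension() != 3:
        raise FormatError("only 3D images are supported")
    direction = np.array(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-3):
        img = sitk.DICOMOrient(img, "LPS")
    data = sitk.GetArrayFromImage(img).astype(np.float32)
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    return ImageVolume(data, spacing, origin)


def _read_dicom_dir(path: str) -> ImageVolume:
    import pydicom

    files = sorted(
        os.path.join(path, f)
        for f in os.listdir(path)
        if not f.startswith(".")
    )
    if not files:
        raise FormatError(f"no files in DICOM directory {path!r}")
    slices = []
    for f in files:
        try:
            slices.append(pydicom.dcmread(f))
        except Exception as exc:  # pragma: no cover - corrupt file branch
            raise FormatError(f"unreadable DICOM file {f!r}: {exc}") from exc
    # Sort by slice position along the normal (z in patient coordinates).
    try:
        slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
        zs = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    except Exception as exc:
        raise MetadataError("DICOM slices lack ImagePositionPatient") from exc
    if len(slices) > 1:
        dz = np.diff(zs)
        if dz.min() <= 0 or (dz.max() - dz.min()) > 0.01 * dz.mean() + 1e-3:
            raise MetadataError("inconsistent DICOM slice spacing")
        slice_spacing = float(dz.mean())
    else:
        slice_spacing = float(getattr(slices[0], "SliceThickness", 1.0) or 1.0)
    rows_cols = {(int(ds.Rows), int(ds.Columns)) for ds in slices}
    if len(rows_cols) != 1:
        raise MetadataError("DICOM slices have differing matrix sizes")
    planes = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float32)
        slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
        intercept = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
        planes.append(arr * slope + intercept)
    data = np.stack(planes, axis=0)
    py, px = (float(v) for v in slices[0].PixelSpacing)
    ox, oy, oz = (float(v) for v in slices[0].ImagePositionPatient)
    return ImageVolume(data, (slice_spacing, py, px), (oz, oy, ox))


def read_volume(path: str, fmt: str | None = None) -> ImageVolume:
    """Read a CT volume from NIfTI, NRRD, or a DICOM series directory.

    ``fmt`` is one of ``{"nifti", "nrrd", "dicom_dir"}``; when omitted it is
    inferred from the path.  DICOM rescale slope/intercept is applied so the
    returned intensities are HU.
    """
    if fmt is None:
        if os.path.isdir(path):
            fmt = "dicom_dir"
        elif path.endswith((".nii", ".nii.gz")):
            fmt = "nifti"
        elif path.endswith(".nrrd"):
            fmt = "nrrd"
        else:
            raise FormatError(f"cannot infer format of {path!r}")
    if fmt == "dicom_dir":
        if not os.path.isdir(path):
            raise FormatError(f"not a directory: {path!r}")
        vol = _read_dicom_dir(path)
    elif fmt in ("nifti", "nrrd"):
        if not os.path.exists(path):
            raise FormatError(f"no such file: {path!r}")
        try:
            img = sitk.ReadImage(path)
        except Exception as exc:
            raise FormatError(f"unreadable {fmt} file {path!r}: {exc}") from exc
        vol = _from_sitk(img)
    else:
        raise FormatError(f"unknown format {fmt!r}")
    if max(vol.spacing) > THICK_SLICE_WARNING_MM:
        import warnings

        warnings.warn(
            f"voxel spacing {vol.spacing} mm exceeds {THICK_SLICE_WARNING_MM} mm; "
            "margin accuracy assumes thin-slice input",
            stacklevel=2,
        )
    return vol


def write_volume(vol: ImageVolume, path: str) -> None:
    """Write a volume (float32) or mask (uint8 with values {0,1}) to disk."""
    if isinstance(vol, BinaryMask):
        arr = vol.data.astype(np.uint8)
    else:
        arr = np.asarray(vol.data, dtype=np.float32)
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(reversed(vol.spacing)))
    img.SetOrigin(tuple(reversed(vol.origin)))
    sitk.WriteImage(img, path)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------


def resample_isotropic(
    vol: ImageVolume, target_spacing: float = 1.0, mode: str | None = None
) -> ImageVolume:
    """Resample onto an isotropic grid of ``target_spacing`` mm.

    HU volumes use linear interpolation, masks nearest-neighbour; ``mode``
    overrides the default.  The origin is preserved (voxel-centre convention),
    so physical extent is preserved to within one voxel.
    """
    if target_spacing <= 0:
        raise PreconditionError("target_spacing must be > 0")
    is_mask = isinstance(vol, BinaryMask)
    if mode is None:
        mode = "nearest" if is_mask else "linear"
    if mode not in ("linear", "nearest"):
        raise PreconditionError(f"unknown mode {mode!r}")
    spacing = np.asarray(vol.spacing)
    shape = np.asarray(vol.shape)
    if mode == "linear" and (shape < 2).any():
        raise ResampleError("linear resampling needs >= 2 voxels per axis")
    new_shape = np.maximum(1, np.round(shape * spacing / target_spacing).astype(int))
    if tuple(new_shape) == tuple(shape) and np.allclose(spacing, target_spacing):
        out = vol.data.copy()
    else:
        # new index j lies at old (fractional) index j * target / spacing
        coords = np.meshgrid(
            *[np.arange(n) * target_spacing / s for n, s in zip(new_shape, spacing)],
            indexing="ij",
        )
        order = 1 if mode == "linear" else 0
        out = ndi.map_coordinates(
            vol.data.astype(np.float32, copy=False),
            coords,
            order=order,
            mode="nearest",
        )
    new_spacing = (target_spacing,) * 3
    if is_mask:
        return BinaryMask(out > 0.5, new_spacing, vol.origin)
    return ImageVolume(out, new_spacing, vol.origin)


# ---------------------------------------------------------------------------
# Metric morphology
# ---------------------------------------------------------------------------


def ball_footprint(radius_mm: float, spacing_mm: float) -> np.ndarray:
    """Discrete ball: all lattice offsets with ``||o * spacing|| <= radius``."""
    r_vox = int(np.floor(radius_mm / spacing_mm + 1e-9))
    if r_vox < 1:
        return np.ones((1, 1, 1), dtype=bool)
    ax = np.arange(-r_vox, r_vox + 1)
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    d2 = (zz**2 + yy**2 + xx**2) * spacing_mm**2
    return d2 <= radius_mm**2 + 1e-9


def _check_metric_mask(mask: BinaryMask, radius_mm: float) -> None:
    if radius_mm < 0:
        raise PreconditionError("radius must be >= 0")
    if not mask.is_isotropic():
        raise PreconditionError(
            "metric morphology requires an isotropic grid; resample first"
        )


def erode_mm(mask: BinaryMask, radius_mm: float) -> BinaryMask:
    """Erode by a discrete ball of the given physical radius (mm)."""
    _check_metric_mask(mask, radius_mm)
    if radius_mm == 0:
        return mask.like(mask.data.copy())
    fp = ball_footprint(radius_mm, mask.spacing[0])
    return mask.like(ndi.binary_erosion(mask.data, structure=fp, border_value=0))


def dilate_mm(mask: BinaryMask, radius_mm: float) -> BinaryMask:
    """Dilate by a discrete ball of the given physical radius (mm)."""
    _check_metric_mask(mask, radius_mm)
    if radius_mm == 0:
        return mask.like(mask.data.copy())
    fp = ball_footprint(radius_mm, mask.spacing[0])
    return mask.like(ndi.binary_dilation(mask.data, structure=fp, border_value=0))


_SIX_CONN = ndi.generate_binary_structure(3, 1)


def mask_surface(mask: BinaryMask) -> np.ndarray:
    """Voxel indices of mask voxels with >= 1 six-connected background neighbour.

    The grid edge counts as background, so a full-grid mask has the grid
    boundary as its surface.  Returns an ``(n, 3)`` integer index array in
    lexicographic order.
    """
    if not mask.data.any():
        raise EmptyInputError("surface of an empty mask")
    interior = ndi.binary_erosion(mask.data, structure=_SIX_CONN, border_value=0)
    return np.argwhere(mask.data & ~interior)


def surface_mask(mask: BinaryMask) -> BinaryMask:
    """Boolean-mask variant of :func:`mask_surface` on the same lattice."""
    if not mask.data.any():
        raise EmptyInputError("surface of an empty mask")
    interior = ndi.binary_erosion(mask.data, structure=_SIX_CONN, border_value=0)
    return mask.like(mask.data & ~interior)
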