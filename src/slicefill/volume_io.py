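"""Volumes and label maps in standard medical-imaging formats.

The internal convention is a fixed (slice, row, col) axis order where the
slice axis is the scanner's axial (z) axis: one "section" — the unit of
manual annotation in this workflow — is ``data[i]``.  On read, the file's
orientation metadata is inspected only to locate the slice axis; full
oblique reorientation is deliberately out of scope.

NIfTI (.nii/.nii.gz) is read and written through nibabel; NRRD (.nrrd), as
exported by 3D Slicer, is read through SimpleITK.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from ._errors import (
    Non3DImageError,
    ShapeMismatchError,
    UnknownLabelError,
    UnsupportedFormatError,
)

#: canonical label codes
BACKGROUND, KIDNEY, TUMOR = 0, 1, 2
ALLOWED_CODES = frozenset({BACKGROUND, KIDNEY, TUMOR})
DEFAULT_STRUCTURE_NAMES = {
    BACKGROUND: "background",
    KIDNEY: "kidney",
    TUMOR: "tumor",
}


@dataclass
class Volume:
    """A 3D scalar image in canonical (slice, row, col) order.

    Parameters
    ----------
    data : ndarray, shape (n_slices, n_rows, n_cols)
        Voxel intensities (HU-like arbitrary units).
    spacing : tuple of float
        Voxel size ``(dz, dy, dx)`` in millimetres, each strictly positive.
    origin : tuple of float
        World position of voxel (0, 0, 0) in millimetres.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise Non3DImageError(
                f"volume must be 3D, got {self.data.ndim}D shape {self.data.shape}"
            )
        if min(self.data.shape) < 1:
            raise Non3DImageError("every dimension must be >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]


@dataclass
class LabelMap:
    """Integer segmentation aligned to a :class:`Volume`.

    Codes: 0 = background, 1 = neoplastic kidney parenchyma, 2 = tumor.
    Kidney and tumor are mutually exclusive by construction (each voxel
    carries exactly one code).
    """

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    structure_names: dict[int, str] = field(
        default_factory=lambda: dict(DEFAULT_STRUCTURE_NAMES)
    )

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise Non3DImageError(
                f"label map must be 3D, got {self.labels.ndim}D shape {self.labels.shape}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            if np.any(self.labels != np.round(self.labels)):
                raise UnknownLabelError("label map contains non-integer values")
            self.labels = self.labels.astype(np.int16)
        codes = set(np.unique(self.labels).tolist())
        bad = codes - ALLOWED_CODES
        if bad:
            raise UnknownLabelError(f"unknown label codes {sorted(bad)}; allowed {sorted(ALLOWED_CODES)}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def n_slices(self) -> int:
        return self.labels.shape[0]

    def mask(self, code: int) -> np.ndarray:
        """Binary mask of one structure."""
        if code not in self.structure_names:
            raise UnknownLabelError(f"unknown structure code {code}")
        return self.labels == code

    def copy(self) -> "LabelMap":
        return LabelMap(self.labels.copy(), self.spacing, dict(self.structure_names))


_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def _is_nrrd(path: Path) -> bool:
    return path.name.lower().endswith(".nrrd")


def _axis_order(world_by_axis: np.ndarray) -> list[int]:
    """Canonical (slice, row, col) order of the three array axes.

    ``world_by_axis[:, k]`` is the world-space direction of array axis k;
    the slice axis is the one closest to world z, rows to world y, cols to
    world x (dominant-component assignment; oblique volumes beyond that
    are out of scope).
    """
    slice_axis = int(np.argmax(np.abs(world_by_axis[2, :])))
    rest = [a for a in range(3) if a != slice_axis]
    if np.abs(world_by_axis[1, rest[0]]) >= np.abs(world_by_axis[1, rest[1]]):
        row_axis, col_axis = rest
    else:
        col_axis, row_axis = rest
    return [slice_axis, row_axis, col_axis]


def _canonicalize(data: np.ndarray, spacing: np.ndarray, order: list[int]):
    data = np.transpose(data, order)
    return np.ascontiguousarray(data), spacing[order]


def _read_array(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read any supported file to canonical (slice,row,col) + spacing + origin."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    if _is_nifti(path):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        if data.ndim != 3:
            raise Non3DImageError(f"non-3D input: {path} has {data.ndim} dimensions")
        aff = img.affine[:3, :3]
        order = _axis_order(aff)
        spacing = np.linalg.norm(aff, axis=0)
        origin = img.affine[:3, 3]
        data, spacing = _canonicalize(data, spacing, order)
        return data, spacing, np.asarray(origin, dtype=float)
    if _is_nrrd(path):
        img = sitk.ReadImage(str(path))
        if img.GetDimension() != 3:
            raise Non3DImageError(f"non-3D input: {path}")
        data = sitk.GetArrayFromImage(img)  # (z, y, x) index order
        direction = np.asarray(img.GetDirection()).reshape(3, 3)
        # direction column i is the world direction of index axis i
        # (x, y, z index order); index axis i is array axis 2-i
        world_by_axis = direction[:, ::-1]
        order = _axis_order(world_by_axis)
        spacing = np.asarray(img.GetSpacing())[::-1]  # -> (z, y, x)
        data, spacing = _canonicalize(data, spacing, order)
        return data, spacing, np.asarray(img.GetOrigin(), dtype=float)[::-1]
    raise UnsupportedFormatError(f"unsupported format: {path.name} (expect .nii, .nii.gz or .nrrd)")


def read_volume(path) -> Volume:
    """Read a NIfTI or NRRD scalar image into canonical orientation."""
    data, spacing, origin = _read_array(path)
    return Volume(data, tuple(spacing), tuple(origin))


def write_volume(volume: Volume, path) -> Path:
    """Write a volume as NIfTI (lossless for integer data).

    The array is stored with axes (col, row, slice) so the affine is the
    plain diagonal ``diag(dx, dy, dz)`` — reading it back reproduces the
    canonical order exactly.
    """
    path = Path(path)
    if not _is_nifti(path):
        raise UnsupportedFormatError(f"volumes are written as NIfTI; got {path.name}")
    dz, dy, dx = volume.spacing
    affine = np.diag([dx, dy, dz, 1.0])
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(np.asarray(volume.data).T, affine)
    img.header.set_zooms((dx, dy, dz))
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def read_labelmap(path, volume: Volume | None = None, relabel: dict[int, int] | None = None,
                  strict: bool = True) -> LabelMap:
    """Read a label map, validating codes against {0, 1, 2}.

    Parameters
    ----------
    volume : Volume, optional
        If given, the label shape must match the volume shape.
    relabel : dict, optional
        Mapping applied to foreign code values before validation
        (e.g. ``{3: 1, 4: 2}`` for files produced with other conventions).
    strict : bool
        If False, codes outside the allowed set are silently mapped to
        background instead of raising.
    """
    data, spacing, _ = _read_array(path)
    if volume is not None and data.shape != volume.shape:
        raise ShapeMismatchError(
            f"shape mismatch: labels {data.shape} vs volume {volume.shape}"
        )
    labels = np.rint(np.asarray(data)).astype(np.int16)
    if relabel:
        out = labels.copy()
        for src, dst in relabel.items():
            out[labels == src] = dst
        labels = out
    codes = set(np.unique(labels).tolist())
    bad = codes - ALLOWED_CODES
    if bad:
        if strict:
            raise UnknownLabelError(
                f"unknown label codes {sorted(bad)} in {path}; pass a relabel map or strict=False"
            )
        labels[np.isin(labels, sorted(bad))] = BACKGROUND
    sp = tuple(spacing) if volume is None else volume.spacing
    return LabelMap(labels, sp)


def write_labelmap(labelmap: LabelMap, path) -> Path:
    """Write a label map as integer NIfTI (lossless round-trip)."""
    vol = Volume(labelmap.labels.astype(np.int16), labelmap.spacing)
    return write_volume(vol, path)
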