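"""Volume and label-mask I/O plus geometry bookkeeping.

All stages of the pipeline exchange :class:`Volume` objects: a 3-D grid of
standardised-uptake values (SUV, g/mL) stored as float32 together with its
isotropic-or-not voxel spacing in mm. Volumes and masks are serialised as
NIfTI-1; the internal orientation convention is RAS with the affine built
directly from the voxel spacing, so axial/coronal/sagittal plane extraction
is deterministic (axis 0 = L-R, axis 1 = P-A, axis 2 = I-S).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "LabelMask",
    "FormatError",
    "AlignmentError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "check_aligned",
    "body_mask",
]

#: spacing agreement tolerance in mm for paired-volume operations
SPACING_TOL_MM = 1e-6


class FormatError(ValueError):
    """Raised when a file does not hold a valid 3-D volume."""


class AlignmentError(ValueError):
    """Raised when two grids disagree in shape or spacing."""


@dataclasses.dataclass
class Volume:
    """A 3-D SUV image with voxel spacing in mm and free-form provenance."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise FormatError(f"volume must be 3-D, got shape {self.data.shape}")
        vs = tuple(float(v) for v in np.atleast_1d(self.voxel_size_mm).ravel())
        if len(vs) == 1:
            vs = vs * 3
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise FormatError(f"invalid voxel size {self.voxel_size_mm!r}")
        self.voxel_size_mm = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (= cm^3)."""
        return float(np.prod(self.voxel_size_mm)) / 1000.0

    def copy(self, data: np.ndarray | None = None, **meta) -> "Volume":
        d = self.data.copy() if data is None else data
        return Volume(d, self.voxel_size_mm, {**self.meta, **meta})


@dataclasses.dataclass
class LabelMask:
    """Integer label grid aligned to a :class:`Volume`.

    Legend maps label value -> region name. Label 0 is background by
    convention; the phantom generator uses 1 body, 2 liver, 3/4 lungs and
    100+id for lesions.
    """

    labels: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    legend: dict[int, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise FormatError(f"mask must be 3-D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError("mask labels must be integers")
        if self.labels.min() < 0:
            raise FormatError("mask labels must be >= 0")
        vs = tuple(float(v) for v in np.atleast_1d(self.voxel_size_mm).ravel())
        if len(vs) == 1:
            vs = vs * 3
        self.voxel_size_mm = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size_mm)) / 1000.0

    def region(self, label: int) -> np.ndarray:
        return self.labels == label

    def label_of(self, name: str) -> int:
        for k, v in self.legend.items():
            if v == name:
                return k
        raise KeyError(f"no label named {name!r}")


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def _load_3d(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(
            f"{path}: expected 3-D data, header dim gives shape {data.shape}"
        )
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise FormatError(f"{path}: non-positive spacing in header pixdim {zooms}")
    return data, tuple(float(z) for z in zooms)


def read_volume(path) -> Volume:
    """Read a 3-D NIfTI-1 volume; values become float32 SUV."""
    data, zooms = _load_3d(path)
    return Volume(data.astype(np.float32), zooms, {"source": str(path)})


def write_volume(vol: Volume, path) -> None:
    """Write as NIfTI-1 float32 with spacing in the header."""
    img = nib.Nifti1Image(vol.data.astype(np.float32), _affine(vol.voxel_size_mm))
    img.header.set_zooms(vol.voxel_size_mm)
    nib.save(img, str(path))


def read_mask(path) -> LabelMask:
    """Read an integer label mask; legend loaded from a ``.labels.txt`` sidecar if present."""
    data, zooms = _load_3d(path)
    labels = np.rint(np.asarray(data)).astype(np.int32)
    legend: dict[int, str] = {}
    sidecar = Path(str(path)).with_suffix("").with_suffix("")  # strip .nii[.gz]
    sidecar = Path(str(sidecar) + ".labels.txt")
    if sidecar.exists():
        for line in sidecar.read_text().splitlines():
            line = line.strip()
            if line:
                k, _, name = line.partition(" ")
                legend[int(k)] = name.strip()
    return LabelMask(labels, zooms, legend)


def write_mask(mask: LabelMask, path) -> None:
    img = nib.Nifti1Image(mask.labels.astype(np.int16), _affine(mask.voxel_size_mm))
    img.header.set_zooms(mask.voxel_size_mm)
    nib.save(img, str(path))
    if mask.legend:
        sidecar = Path(str(path)).with_suffix("").with_suffix("")
        sidecar = Path(str(sidecar) + ".labels.txt")
        sidecar.write_text(
            "\n".join(f"{k} {v}" for k, v in sorted(mask.legend.items())) + "\n"
        )


def check_aligned(a: Volume | LabelMask, b: Volume | LabelMask) -> None:
    """Assert two grids share shape and spacing (within ``SPACING_TOL_MM``).

    Every paired-volume operation in the package calls this first, so no
    computation ever silently broadcasts across mismatched grids.
    """
    if a.shape != b.shape:
        raise AlignmentError(f"shape mismatch: {a.shape} vs {b.shape}")
    da = np.asarray(a.voxel_size_mm)
    db = np.asarray(b.voxel_size_mm)
    if np.any(np.abs(da - db) > SPACING_TOL_MM):
        raise AlignmentError(
            f"spacing mismatch: {tuple(da)} vs {tuple(db)} mm "
            f"(tolerance {SPACING_TOL_MM} mm)"
        )


def body_mask(vol: Volume, threshold_suv: float = 0.2, smooth_mm: float = 6.0) -> np.ndarray:
    """Boolean body support estimated from intensities.

    Air carries essentially zero uptake, so a light smooth followed by a low
    SUV threshold separates the patient/phantom body from background. Used as
    the default evaluation mask so that air voxels do not dilute voxel-wise
    metrics.
    """
    from scipy import ndimage

    sigma_vox = [smooth_mm / s for s in vol.voxel_size_mm]
    smoothed = ndimage.gaussian_filter(vol.data.astype(np.float64), sigma_vox)
    return smoothed > threshold_suv
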