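"""Volume/mask containers, NIfTI/NRRD round-trips and SUV conversion.

PET tracer concentration is stored as the standardized uptake value (SUV),
the tissue activity concentration normalized by injected dose per unit body
weight.  Arrays are indexed (x, y, z) with the spacing metadata authoritative;
SimpleITK handles the on-disk formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = [
    "SuvVolume",
    "VoiMask",
    "FormatError",
    "DegenerateVoiError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "activity_to_suv",
]


class FormatError(ValueError):
    """Raised for image payloads this pipeline cannot interpret (e.g. 4D)."""


class DegenerateVoiError(ValueError):
    """Raised when an operation requires a non-empty volume of interest."""


def _as_tuple3(x) -> tuple[float, float, float]:
    t = tuple(float(v) for v in x)
    if len(t) != 3:
        raise ValueError(f"expected 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass
class SuvVolume:
    """A 3D scalar field of SUV values on a regular grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Dimensionless SUV values; must be finite.
    spacing : (float, float, float)
        Voxel spacing in mm along (x, y, z); strictly positive.
    origin : (float, float, float)
        Physical position (mm) of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise FormatError(f"volume must be 3D, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self.spacing = _as_tuple3(self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = _as_tuple3(self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class VoiMask:
    """A binary volume-of-interest mask aligned to a :class:`SuvVolume`.

    ``provenance`` records how the contour was obtained: ``"original"``,
    ``"dilated(+1mm)"``, ``"dilated(+2mm)"``, ``"eroded(-1mm)"`` or
    ``"mirrored"``.  An erosion that empties the mask is kept but flagged
    ``degenerate`` so downstream stages can drop-and-log it.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    provenance: str = "original"
    degenerate: bool = field(default=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise FormatError(f"mask must be 3D, got ndim={self.data.ndim}")
        self.spacing = _as_tuple3(self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = _as_tuple3(self.origin)
        if not self.data.any():
            self.degenerate = True

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def with_data(self, data: np.ndarray, provenance: str | None = None) -> "VoiMask":
        return replace(
            self,
            data=data,
            provenance=self.provenance if provenance is None else provenance,
            degenerate=not np.asarray(data).any(),
        )


# ---------------------------------------------------------------------------
# File IO (NIfTI-1 and NRRD via SimpleITK)
# ---------------------------------------------------------------------------

def _to_sitk(data: np.ndarray, spacing, origin) -> sitk.Image:
    # SimpleITK arrays are (z, y, x); our convention is (x, y, z).
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(data, (2, 1, 0))))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, tuple, tuple]:
    if img.GetDimension() != 3 or img.GetNumberOfComponentsPerPixel() != 1:
        raise FormatError(
            f"expected a 3D scalar image, got {img.GetDimension()}D with "
            f"{img.GetNumberOfComponentsPerPixel()} components"
        )
    arr = sitk.GetArrayFromImage(img)
    if arr.ndim != 3:
        raise FormatError(f"expected a 3D payload, got ndim={arr.ndim}")
    return np.transpose(arr, (2, 1, 0)), tuple(img.GetSpacing()), tuple(img.GetOrigin())


def write_volume(vol: SuvVolume, path: str | Path) -> None:
    """Write a volume as NIfTI (.nii/.nii.gz) or NRRD (.nrrd), by extension."""
    img = _to_sitk(vol.data.astype(np.float32), vol.spacing, vol.origin)
    sitk.WriteImage(img, str(path))


def read_volume(path: str | Path) -> SuvVolume:
    """Read a 3D scalar NIfTI/NRRD volume; non-3D payloads raise FormatError."""
    img = sitk.ReadImage(str(path))
    arr, spacing, origin = _from_sitk(img)
    return SuvVolume(arr.astype(np.float64), spacing, origin)


def write_mask(mask: VoiMask, path: str | Path) -> None:
    """Write a mask as unsigned 8-bit 0/1."""
    img = _to_sitk(mask.data.astype(np.uint8), mask.spacing, mask.origin)
    sitk.WriteImage(img, str(path))


def read_mask(path: str | Path, provenance: str = "original") -> VoiMask:
    img = sitk.ReadImage(str(path))
    arr, spacing, origin = _from_sitk(img)
    return VoiMask(arr > 0, spacing, origin, provenance=provenance)


# ---------------------------------------------------------------------------
# SUV conversion
# ---------------------------------------------------------------------------

def activity_to_suv(
    activity_kbq_per_ml: np.ndarray,
    injected_dose_mbq: float,
    body_weight_kg: float,
    spacing,
    origin=(0.0, 0.0, 0.0),
) -> SuvVolume:
    """Convert an activity-concentration map to body-weight SUV.

    SUV = activity [kBq/ml] x body weight [kg] / injected dose [MBq].  The
    units are consistent because MBq/kg == kBq/g and soft tissue is taken at
    1 g/ml; the result is dimensionless.  Activity is assumed decay-corrected
    by the scanner.
    """
    if injected_dose_mbq <= 0:
        raise ValueError(f"injected dose must be positive, got {injected_dose_mbq}")
    if body_weight_kg <= 0:
        raise ValueError(f"body weight must be positive, got {body_weight_kg}")
    activity = np.asarray(activity_kbq_per_ml, dtype=np.float64)
    suv = activity * (body_weight_kg / injected_dose_mbq)
    return SuvVolume(suv, spacing, origin)
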