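"""Geometry on lesion masks: isotropic resampling, contour perturbation,
contralateral mirroring.

Contour-robustness analysis rates each feature on four contour variants of the
same lesion (original, +1 mm and +2 mm expansions, -1 mm contraction).
Perturbations here are Euclidean-distance based and spacing-aware, so a +1 mm
expansion on a 1 mm isotropic grid adds exactly the face-adjacent shell.
"""

from __future__ import annotations

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .io import DegenerateVoiError, SuvVolume, VoiMask, _to_sitk

__all__ = ["resample_isotropic", "perturb_mask", "mirror_mask", "crop_to_mask"]

_EPS = 1e-9


def resample_isotropic(
    vol: SuvVolume,
    mask: VoiMask | None = None,
    target_mm: float = 1.0,
) -> SuvVolume | tuple[SuvVolume, VoiMask]:
    """Resample a volume (and optionally its mask) to an isotropic grid.

    The volume is interpolated trilinearly; the mask is interpolated linearly
    as a float field and thresholded at 0.5, which preserves its volume in
    expectation.  Output size is chosen so the physical extent is preserved to
    within one voxel.

    Raises
    ------
    DegenerateVoiError
        If a supplied mask has no foreground voxels left after resampling.
    """
    if mask is not None and mask.shape != vol.shape:
        raise ValueError("volume and mask must share the same grid")
    size = [max(1, int(round(n * s / target_mm))) for n, s in zip(vol.shape, vol.spacing)]
    # edge-aligned output grid: voxel *edges* of the two grids coincide, which
    # keeps the physical extent and avoids systematic 0.5-threshold ties when
    # spacings are integer multiples
    new_origin = tuple(
        o + (target_mm - s) / 2.0 for o, s in zip(vol.origin, vol.spacing)
    )
    new_spacing = (target_mm, target_mm, target_mm)

    def _resample(data, dtype):
        img = _to_sitk(data.astype(dtype), vol.spacing, vol.origin)
        out = sitk.Resample(
            img,
            size,
            sitk.Transform(),
            sitk.sitkLinear,
            new_origin,
            new_spacing,
            img.GetDirection(),
            0.0,
            sitk.sitkFloat64,
            useNearestNeighborExtrapolator=True,
        )
        return np.transpose(sitk.GetArrayFromImage(out), (2, 1, 0))

    out_vol = SuvVolume(_resample(vol.data, np.float64), new_spacing, new_origin)
    if mask is None:
        return out_vol
    mdata = _resample(mask.data.astype(np.float64), np.float64) >= 0.5
    if not mdata.any():
        raise DegenerateVoiError("mask is empty after resampling")
    out_mask = VoiMask(mdata, new_spacing, new_origin, provenance=mask.provenance)
    return out_vol, out_mask


def perturb_mask(mask: VoiMask, delta_mm: float) -> VoiMask:
    """Expand (delta > 0) or contract (delta < 0) a contour by |delta| mm.

    Uses the spacing-aware Euclidean distance transform: expansion adds all
    background voxels within |delta| mm of the contour, contraction removes
    foreground voxels within |delta| mm of the background.  A contraction that
    empties the mask returns a variant flagged ``degenerate`` rather than
    raising, so cohort loops can drop-and-log it.
    """
    if mask.degenerate:
        raise DegenerateVoiError("cannot perturb an empty mask")
    if delta_mm == 0:
        return mask.with_data(mask.data.copy(), provenance=mask.provenance)
    sampling = mask.spacing
    if delta_mm > 0:
        dist = ndimage.distance_transform_edt(~mask.data, sampling=sampling)
        out = mask.data | (dist <= delta_mm + _EPS)
        prov = f"dilated(+{delta_mm:g}mm)"
    else:
        dist = ndimage.distance_transform_edt(mask.data, sampling=sampling)
        out = dist > abs(delta_mm) + _EPS
        prov = f"eroded({delta_mm:g}mm)"
    return mask.with_data(out, provenance=prov)


def mirror_mask(mask: VoiMask, midline_axis: int = 0) -> VoiMask:
    """Reflect a mask across the volume's geometric midline plane.

    Used to copy a lesion contour onto the contralateral breast for background
    SUV estimation.  Reflection about the grid midline preserves voxel count
    exactly; a double mirror returns the original mask.
    """
    if not 0 <= midline_axis <= 2:
        raise ValueError(f"midline_axis must be 0, 1 or 2, got {midline_axis}")
    out = np.flip(mask.data, axis=midline_axis).copy()
    return mask.with_data(out, provenance="mirrored")


def crop_to_mask(
    vol: SuvVolume, mask: VoiMask, margin_mm: float = 8.0
) -> tuple[SuvVolume, VoiMask]:
    """Crop volume+mask to the mask bounding box plus a physical margin.

    The margin keeps enough context for contour expansion and for the 1 cm^3
    peak sphere, while keeping the resampled array small.
    """
    if mask.shape != vol.shape:
        raise ValueError("volume and mask must share the same grid")
    if mask.degenerate:
        raise DegenerateVoiError("cannot crop to an empty mask")
    idx = np.nonzero(mask.data)
    lo, hi, origin = [], [], []
    for ax in range(3):
        m = int(np.ceil(margin_mm / mask.spacing[ax]))
        a = max(0, int(idx[ax].min()) - m)
        b = min(mask.shape[ax], int(idx[ax].max()) + 1 + m)
        lo.append(a)
        hi.append(b)
        origin.append(mask.origin[ax] + a * mask.spacing[ax])
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    cvol = SuvVolume(vol.data[sl].copy(), vol.spacing, tuple(origin))
    cmask = VoiMask(
        mask.data[sl].copy(), mask.spacing, tuple(origin), provenance=mask.provenance
    )
    return cvol, cmask
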