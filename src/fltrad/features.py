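"""SUV statistics and radiomic feature extraction from a volume + VOI mask.

The implemented vector covers the three SUV statistics plus the intensity,
intensity-volume-histogram, local-intensity, GLCM, GLRLM, GLSZM, GLDZM, NGLDM
and NGTDM indices used in the contour-robustness and response models.  The
extraction pipeline is: crop to the lesion, resample to 1 mm isotropic voxels,
discretize to a fixed number of gray levels (32 bins), then compute each
family.  Intensity (ID_*) statistics and the IVH use the raw, undiscretized
SUV values; texture matrices use the discretized levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from . import _texture
from .io import DegenerateVoiError, SuvVolume, VoiMask
from .voi import crop_to_mask, perturb_mask, resample_isotropic

__all__ = [
    "FeatureConfig",
    "DiscretizedVoi",
    "discretize_fbn",
    "suv_statistics",
    "local_intensity_peak",
    "intensity_features",
    "ivh_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldzm_features",
    "ngldm_features",
    "ngtdm_coarseness",
    "extract_all",
    "extract_contour_variants",
    "ALL_FEATURES",
    "TABLE_FEATURES",
    "SCALE_INVARIANT_FEATURES",
]


@dataclass(frozen=True)
class FeatureConfig:
    """Extraction settings; the defaults reproduce the study protocol
    (1 mm^3 resampling, 32 gray levels, 1 cm^3 peak sphere)."""

    n_bins: int = 32
    resample_mm: float = 1.0
    peak_radius_mm: float = 6.2
    margin_mm: float = 8.0


@dataclass
class DiscretizedVoi:
    """Fixed-bin-number discretization of the in-mask intensities.

    ``levels`` holds integer gray levels 1..n_bins inside the mask and 0
    outside; ``vmin``/``vmax`` are the original in-mask range used for
    binning.
    """

    levels: np.ndarray
    n_bins: int
    vmin: float
    vmax: float


def _masked_values(vol: SuvVolume, mask: VoiMask) -> np.ndarray:
    if mask.shape != vol.shape:
        raise ValueError("volume and mask must share the same grid")
    if mask.degenerate:
        raise DegenerateVoiError("empty VOI")
    return vol.data[mask.data]


def discretize_fbn(vol: SuvVolume, mask: VoiMask, n_bins: int = 32) -> DiscretizedVoi:
    """Fixed-bin-number gray-level quantization.

    level = 1 + floor(n_bins * (x - min) / (max - min)), with x = max mapped
    to n_bins; a constant VOI maps every voxel to level 1.
    """
    vals = _masked_values(vol, mask)
    vmin, vmax = float(vals.min()), float(vals.max())
    levels = np.zeros(vol.shape, dtype=np.int64)
    if vmax > vmin:
        lv = 1 + np.floor(n_bins * (vol.data[mask.data] - vmin) / (vmax - vmin))
        levels[mask.data] = np.minimum(lv, n_bins).astype(np.int64)
    else:
        levels[mask.data] = 1
    return DiscretizedVoi(levels, n_bins, vmin, vmax)


# ---------------------------------------------------------------------------
# SUV statistics and local intensity peak
# ---------------------------------------------------------------------------

def _sphere_mean_map(vol: SuvVolume, radius_mm: float) -> np.ndarray:
    """Mean intensity in a sphere around every voxel, sphere clipped to the
    volume. The sphere holds all voxels whose centers lie within radius_mm."""
    ranges = [int(np.floor(radius_mm / s)) for s in vol.spacing]
    gx, gy, gz = np.meshgrid(
        *(np.arange(-r, r + 1) * s for r, s in zip(ranges, vol.spacing)),
        indexing="ij",
    )
    kernel = (gx**2 + gy**2 + gz**2 <= radius_mm**2 + 1e-9).astype(np.float64)
    num = fftconvolve(vol.data, kernel, mode="same")
    den = fftconvolve(np.ones_like(vol.data), kernel, mode="same")
    return num / den


def suv_statistics(
    vol: SuvVolume, mask: VoiMask, peak_radius_mm: float = 6.2
) -> tuple[float, float, float]:
    """(SUV_max, SUV_mean, SUV_peak) inside the VOI.

    SUV_peak is the mean over a ~1 cm^3 sphere (radius 6.2 mm) centered on the
    in-mask voxel that maximizes that sphere mean; the sphere itself may
    extend beyond the mask but is clipped to the volume.
    """
    vals = _masked_values(vol, mask)
    sphere = _sphere_mean_map(vol, peak_radius_mm)
    suv_peak = float(sphere[mask.data].max())
    return float(vals.max()), float(vals.mean()), suv_peak


def local_intensity_peak(
    vol: SuvVolume, mask: VoiMask, radius_mm: float = 6.2
) -> float:
    """Mean intensity in a ~1 cm^3 sphere centered at the global in-mask
    maximum voxel (first occurrence on ties)."""
    _ = _masked_values(vol, mask)
    masked = np.where(mask.data, vol.data, -np.inf)
    center = np.unravel_index(int(np.argmax(masked)), vol.shape)
    sphere = _sphere_mean_map(vol, radius_mm)
    return float(sphere[center])


# ---------------------------------------------------------------------------
# Intensity (first-order) statistics on raw SUV values
# ---------------------------------------------------------------------------

def intensity_features(vol: SuvVolume, mask: VoiMask) -> dict[str, float]:
    """The ID_* block: first-order statistics of the raw in-mask intensities.

    Population (ddof=0) moments; CoefficientOfVariation = sd/mean;
    RobustMeanAbsoluteDeviation restricts to values within [P10, P90];
    MedianAbsoluteDeviation is the mean absolute deviation about the median;
    QuartileCoefficientOfDispersion = (P75-P25)/(P75+P25); Energy = sum(x^2).
    """
    x = _masked_values(vol, mask).astype(np.float64)
    return intensity_statistics(x)


def intensity_statistics(x: np.ndarray) -> dict[str, float]:
    """Same as :func:`intensity_features` but on a plain value vector."""
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.size == 0:
        raise DegenerateVoiError("empty value vector")
    mean = float(x.mean())
    var = float(x.var())
    sd = float(np.sqrt(var))
    p10, p25, p75, p90 = (float(np.percentile(x, q)) for q in (10, 25, 75, 90))
    median = float(np.median(x))
    robust = x[(x >= p10) & (x <= p90)]
    m2 = var
    m3 = float(((x - mean) ** 3).mean())
    m4 = float(((x - mean) ** 4).mean())
    return {
        "ID_Mean": mean,
        "ID_Variance": var,
        "ID_Median": median,
        "ID_Min": float(x.min()),
        "ID_Max": float(x.max()),
        "ID_10thPercentile": p10,
        "ID_90thPercentile": p90,
        "ID_InterquartileRange": p75 - p25,
        "ID_Range": float(x.max() - x.min()),
        "ID_MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "ID_RobustMeanAbsoluteDeviation": (
            float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
        ),
        "ID_MedianAbsoluteDeviation": float(np.abs(x - median).mean()),
        "ID_CoefficientOfVariation": sd / mean if mean != 0 else 0.0,
        "ID_QuartileCoefficientOfDispersion": (
            (p75 - p25) / (p75 + p25) if (p75 + p25) != 0 else 0.0
        ),
        "ID_Energy": float((x**2).sum()),
        "ID_RootMeanSquare": float(np.sqrt((x**2).mean())),
        "ID_Skewness": m3 / m2**1.5 if m2 > 0 else 0.0,
        "ID_Kurtosis": m4 / m2**2 - 3.0 if m2 > 0 else 0.0,
    }


# ---------------------------------------------------------------------------
# Intensity-volume histogram
# ---------------------------------------------------------------------------

def ivh_features(
    vol: SuvVolume, mask: VoiMask, n_grid: int = 1000
) -> dict[str, float]:
    """IVH block from fractional intensities gamma = (x - min)/(max - min).

    V90 is the volume fraction with gamma >= 0.90; I10 is the smallest gamma
    attained by the top 10% of voxels by intensity; the AUC is the mean of the
    volume-fraction curve over a fine gamma grid.  A constant VOI has gamma
    defined as 1 everywhere (V90 = I10 = AUC = 1).
    """
    x = _masked_values(vol, mask)
    return ivh_statistics(x, n_grid=n_grid)


def ivh_statistics(x: np.ndarray, n_grid: int = 1000) -> dict[str, float]:
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.size == 0:
        raise DegenerateVoiError("empty value vector")
    vmin, vmax = x.min(), x.max()
    if vmax > vmin:
        gamma = (x - vmin) / (vmax - vmin)
    else:
        gamma = np.ones_like(x)
    v90 = float((gamma >= 0.90 - 1e-12).mean())
    k = int(np.ceil(0.10 * x.size))
    i10 = float(np.sort(gamma)[::-1][k - 1])
    grid = (np.arange(n_grid) + 0.5) / n_grid
    frac = (gamma[None, :] >= grid[:, None] - 1e-12).mean(axis=1)
    auc = float(frac.mean())
    return {
        "IVH_VolumeIntFract_90": v90,
        "IVH_IntensityVolFract_10": i10,
        "IVH_AreaUnderIVHCurve": auc,
    }


# ---------------------------------------------------------------------------
# Texture families (thin wrappers over _texture on a DiscretizedVoi)
# ---------------------------------------------------------------------------

def _tight_levels(disc: DiscretizedVoi) -> np.ndarray:
    """Crop the level array to the mask bounding box (texture matrices only
    look at in-mask voxels and their immediate neighbors)."""
    idx = np.nonzero(disc.levels)
    sl = tuple(slice(int(i.min()), int(i.max()) + 1) for i in idx)
    return disc.levels[sl]


def glcm_features(disc: DiscretizedVoi) -> dict[str, float]:
    lv = _tight_levels(disc)
    if (lv > 0).sum() < 2:
        raise DegenerateVoiError("GLCM requires at least two in-mask voxels")
    return _texture.glcm_features(_texture.glcm_matrix(lv, disc.n_bins))


def glrlm_features(disc: DiscretizedVoi) -> dict[str, float]:
    lv = _tight_levels(disc)
    rlm = _texture.glrlm_matrix(lv, disc.n_bins)
    return _texture.glrlm_features(rlm, int((lv > 0).sum()))


def glszm_features(disc: DiscretizedVoi) -> dict[str, float]:
    szm, _ = _texture.glszm_gldzm_matrices(_tight_levels(disc), disc.n_bins)
    return _texture.glszm_features(szm)


def gldzm_features(disc: DiscretizedVoi) -> dict[str, float]:
    _, dzm = _texture.glszm_gldzm_matrices(_tight_levels(disc), disc.n_bins)
    return _texture.gldzm_features(dzm)


def ngldm_features(disc: DiscretizedVoi) -> dict[str, float]:
    lv = _tight_levels(disc)
    return _texture.ngldm_features(_texture.ngldm_matrix(lv, disc.n_bins))


def ngtdm_coarseness(disc: DiscretizedVoi) -> float:
    return _texture.ngtdm_coarseness(_tight_levels(disc), disc.n_bins)


# ---------------------------------------------------------------------------
# Full extraction
# ---------------------------------------------------------------------------

def _extract_on_grid(
    vol: SuvVolume, mask: VoiMask, config: FeatureConfig
) -> dict[str, float]:
    """Compute every feature on an (already resampled) grid."""
    out: dict[str, float] = {}
    smax, smean, speak = suv_statistics(vol, mask, config.peak_radius_mm)
    out["SUV_max"] = smax
    out["SUV_peak"] = speak
    out["SUV_mean"] = smean
    out.update(intensity_features(vol, mask))
    out.update(ivh_features(vol, mask))
    out["LIF_LocalIntensityPeak"] = local_intensity_peak(
        vol, mask, config.peak_radius_mm
    )
    disc = discretize_fbn(vol, mask, config.n_bins)
    out.update(glcm_features(disc))
    out.update(glrlm_features(disc))
    out.update(glszm_features(disc))
    out.update(gldzm_features(disc))
    out.update(ngldm_features(disc))
    out["NID_Coarseness"] = ngtdm_coarseness(disc)
    return out


def extract_all(
    vol: SuvVolume, mask: VoiMask, config: FeatureConfig = FeatureConfig()
) -> dict[str, float]:
    """Crop, resample to isotropic voxels, discretize and compute the full
    feature vector.  Deterministic: the same input yields the same vector."""
    cvol, cmask = crop_to_mask(vol, mask, config.margin_mm)
    rvol, rmask = resample_isotropic(cvol, cmask, config.resample_mm)
    return _extract_on_grid(rvol, rmask, config)


def extract_contour_variants(
    vol: SuvVolume,
    mask: VoiMask,
    deltas_mm: tuple[float, ...] = (0.0, 1.0, 2.0, -1.0),
    config: FeatureConfig = FeatureConfig(),
) -> dict[str, dict[str, float] | None]:
    """Feature vectors for the contour-perturbation variants of one lesion.

    The volume is resampled once; perturbation happens on the isotropic grid
    so +/-1 mm is exactly one voxel.  A variant whose mask becomes empty
    (erosion of a tiny lesion) maps to ``None`` so callers can drop-and-log.
    """
    margin = max(config.margin_mm, max(abs(d) for d in deltas_mm) + 2.0)
    cvol, cmask = crop_to_mask(vol, mask, margin)
    rvol, rmask = resample_isotropic(cvol, cmask, config.resample_mm)
    out: dict[str, dict[str, float] | None] = {}
    for delta in deltas_mm:
        name = variant_name(delta)
        pmask = perturb_mask(rmask, delta)
        if pmask.degenerate:
            out[name] = None
            continue
        try:
            out[name] = _extract_on_grid(rvol, pmask, config)
        except DegenerateVoiError:
            # e.g. a contracted contour left a single voxel: no co-occurrence
            # statistics exist, so the variant is dropped-and-logged upstream
            out[name] = None
    return out


def variant_name(delta_mm: float) -> str:
    if delta_mm == 0:
        return "original"
    return f"{delta_mm:+g}mm"


# The full implemented vector (46 indices).
ALL_FEATURES: tuple[str, ...] = (
    "SUV_max", "SUV_peak", "SUV_mean",
    "ID_Mean", "ID_Variance", "ID_Median", "ID_Min", "ID_Max",
    "ID_10thPercentile", "ID_90thPercentile", "ID_InterquartileRange",
    "ID_Range", "ID_MeanAbsoluteDeviation", "ID_RobustMeanAbsoluteDeviation",
    "ID_MedianAbsoluteDeviation", "ID_CoefficientOfVariation",
    "ID_QuartileCoefficientOfDispersion", "ID_Energy", "ID_RootMeanSquare",
    "ID_Skewness", "ID_Kurtosis",
    "IVH_VolumeIntFract_90", "IVH_IntensityVolFract_10", "IVH_AreaUnderIVHCurve",
    "LIF_LocalIntensityPeak",
    "GLCM_JointAverage", "GLCM_SumAverage", "GLCM_AutoCorrelation",
    "GLCM_InformationMeasureCor1",
    "GLRLM_ShortRunEmphasis", "GLRLM_LongRunEmphasis", "GLRLM_HighGLRunEmpha",
    "GLRLM_ShortRunHighGLEmpha", "GLRLM_LongRunHighGLEmpha",
    "GLRLM_GLNonuniformity", "GLRLM_RLNonuniformity", "GLRLM_RunPercentage",
    "GLSZM_LargeZoneHighGLEmpha", "GLSZM_GLNonuniformity",
    "GLDZM_GLNonuniformity", "GLDZM_ZDNonuniformity",
    "NGLD_HighGLCountEmpha", "NGLD_HighDepenHighFLEmpha",
    "NGLD_GLNonuniformity", "NGLD_DepCountNonuniformity",
    "NID_Coarseness",
)

# The 42 indices of the published contour-robust set (the implemented vector
# adds ID_Mean, ID_Max, ID_Skewness and ID_Kurtosis from the same first-order
# family).
TABLE_FEATURES: tuple[str, ...] = tuple(
    f for f in ALL_FEATURES if f not in ("ID_Mean", "ID_Max", "ID_Skewness", "ID_Kurtosis")
)

# Indices that are invariant under a uniform multiplicative rescaling of the
# lesion intensities: dimensionless intensity ratios, the IVH block (min-max
# normalized) and every discretized-texture family (fixed-bin-number levels
# are scale-free).  Used to build planted-signal covariate sets.
SCALE_INVARIANT_FEATURES: tuple[str, ...] = (
    "ID_CoefficientOfVariation", "ID_QuartileCoefficientOfDispersion",
    "ID_Skewness", "ID_Kurtosis",
    "IVH_VolumeIntFract_90", "IVH_IntensityVolFract_10", "IVH_AreaUnderIVHCurve",
    "GLCM_JointAverage", "GLCM_SumAverage", "GLCM_AutoCorrelation",
    "GLCM_InformationMeasureCor1",
    "GLRLM_ShortRunEmphasis", "GLRLM_LongRunEmphasis", "GLRLM_HighGLRunEmpha",
    "GLRLM_ShortRunHighGLEmpha", "GLRLM_LongRunHighGLEmpha",
    "GLRLM_GLNonuniformity", "GLRLM_RLNonuniformity", "GLRLM_RunPercentage",
    "GLSZM_LargeZoneHighGLEmpha", "GLSZM_GLNonuniformity",
    "GLDZM_GLNonuniformity", "GLDZM_ZDNonuniformity",
    "NGLD_HighGLCountEmpha", "NGLD_HighDepenHighFLEmpha",
    "NGLD_GLNonuniformity", "NGLD_DepCountNonuniformity",
    "NID_Coarseness",
)
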