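"""Synthetic paired-timepoint FLT-PET cohorts with known ground truth.

Each synthetic patient has a baseline scan (FLT1) and a post-first-cycle scan
(FLT2) on one of two scanner geometries, an ellipsoidal breast lesion with a
heterogeneous uptake texture, and a contralateral background region obtained
by mirroring the lesion mask across the mid-sagittal plane.  Responders scale
their lesion uptake down by a fractional decline drawn from a configured
range; non-responders decline only marginally.  The generator is the ground
truth for every downstream stage: labels, declines, residual-cancer-burden
categories and scanner assignment are all recorded in a truth table.

Noise model: additive Gaussian on the background (detector noise floor),
multiplicative lognormal on the lesion (PET count noise grows with uptake).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import DegenerateVoiError, SuvVolume, VoiMask, write_mask, write_volume
from .voi import mirror_mask

__all__ = ["CohortConfig", "SyntheticPatient", "generate_lesion_texture",
           "generate_cohort", "write_cohort"]

# (spacing mm, grid shape) per scanner geometry; A is the coarser BGO system,
# B the finer LSO system with thinner slices.
SCANNER_GEOMETRIES = {
    "A": ((3.9, 3.9, 4.25), (48, 48, 32)),
    "B": ((4.1, 4.1, 3.0), (48, 48, 44)),
}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the clinical cohort being emulated: 15 evaluable
    patients, 9/15 responders, 10/15 on the coarser scanner geometry, dosing
    at 3.5 MBq/kg capped at 350 MBq.  A fraction of responders (7/9 by
    default) shows complete disappearance of lesion uptake — the decline is
    drawn from (0.95, 1.0) so the residual signal drops below the breast
    background and the scan reads as a complete metabolic response; the
    remaining responders decline partially within ``responder_decline``.
    Non-responders decline by at most 10%.
    """

    n_patients: int = 15
    responder_fraction: float = 9 / 15
    scanner_mix: float = 10 / 15  # fraction on geometry A
    lesion_radius_mm: tuple[float, float] = (6.0, 11.0)
    baseline_suv_max: tuple[float, float] = (3.0, 10.0)
    heterogeneity_corr_mm: float = 5.0
    heterogeneity_amplitude: float = 0.6
    responder_decline: tuple[float, float] = (0.40, 0.70)
    responder_complete_fraction: float = 7 / 9
    complete_decline: tuple[float, float] = (0.95, 1.00)
    nonresponder_decline: tuple[float, float] = (0.00, 0.10)
    background_suv: float = 0.5
    background_noise_sd: float = 0.05
    lesion_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("responder_fraction", "scanner_mix", "responder_complete_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("lesion_radius_mm", "baseline_suv_max", "responder_decline",
                     "complete_decline", "nonresponder_decline"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range has low > high: ({lo}, {hi})")


@dataclass
class SyntheticPatient:
    patient_id: str
    true_label: str  # "responder" | "nonresponder"
    scanner: str  # "A" | "B"
    flt1: SuvVolume
    flt2: SuvVolume
    lesion_mask: VoiMask
    contralateral_mask: VoiMask
    rcb_category: str
    decline: float
    dose_mbq: float
    weight_kg: float
    metadata: dict = field(default_factory=dict)


def generate_lesion_texture(
    shape_mask: VoiMask,
    heterogeneity: tuple[float, float],
    suv_range: tuple[float, float],
    seed,
) -> SuvVolume:
    """A smooth positive random uptake field inside a lesion mask.

    A Gaussian random field (white noise smoothed with a kernel whose width is
    the correlation length), exponentiated for positivity and min-max rescaled
    into ``suv_range``: the hottest voxel equals ``suv_range[1]`` exactly and
    the coldest in-mask voxel equals ``suv_range[0]``.  With amplitude 0 the
    field is constant at ``suv_range[1]``.  Deterministic for a fixed seed.
    """
    if shape_mask.degenerate:
        raise DegenerateVoiError("cannot texture an empty lesion mask")
    corr_mm, amplitude = heterogeneity
    lo, hi = suv_range
    if lo >= hi:
        raise ValueError(f"suv_range must have low < high, got ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(shape_mask.shape)
    if amplitude > 0:
        sigma = [max(corr_mm / s, 1e-6) for s in shape_mask.spacing]
        g = ndimage.gaussian_filter(noise, sigma=sigma)
        sd = g.std()
        if sd > 0:
            g = g / sd
        fld = np.exp(amplitude * g)
        inside = fld[shape_mask.data]
        fmin, fmax = inside.min(), inside.max()
        if fmax > fmin:
            scaled = lo + (hi - lo) * (fld - fmin) / (fmax - fmin)
        else:
            scaled = np.full_like(fld, hi)
    else:
        scaled = np.full(shape_mask.shape, hi)
    out = np.zeros(shape_mask.shape)
    out[shape_mask.data] = scaled[shape_mask.data]
    return SuvVolume(out, shape_mask.spacing, shape_mask.origin)


def _ellipsoid_mask(shape, spacing, center_mm, radii_mm) -> np.ndarray:
    grids = np.meshgrid(
        *(np.arange(n) * s for n, s in zip(shape, spacing)), indexing="ij"
    )
    acc = np.zeros(shape)
    for g, c, r in zip(grids, center_mm, radii_mm):
        acc += ((g - c) / r) ** 2
    return acc <= 1.0


def _make_patient(
    pid: str,
    label: str,
    scanner: str,
    cfg: CohortConfig,
    rng: np.random.Generator,
) -> SyntheticPatient:
    spacing, shape = SCANNER_GEOMETRIES[scanner]
    fov = [n * s for n, s in zip(shape, spacing)]
    radii = rng.uniform(*cfg.lesion_radius_mm, size=3)
    # lesion in one lateral half (first axis is left-right); mirrored mask
    # then lands in the other half
    center = [
        rng.uniform(0.25 * fov[0] - 10, 0.25 * fov[0] + 10),
        rng.uniform(0.45 * fov[1], 0.55 * fov[1]),
        rng.uniform(0.45 * fov[2], 0.55 * fov[2]),
    ]
    mdata = _ellipsoid_mask(shape, spacing, center, radii)
    lesion = VoiMask(mdata, spacing, provenance="original")
    contralateral = mirror_mask(lesion)
    if (lesion.data & contralateral.data).any():
        raise RuntimeError("lesion and contralateral masks overlap")

    smax = rng.uniform(*cfg.baseline_suv_max)
    texture = generate_lesion_texture(
        lesion,
        (cfg.heterogeneity_corr_mm, cfg.heterogeneity_amplitude),
        (max(2.0 * cfg.background_suv, 0.3 * smax), smax),
        rng.integers(0, 2**31 - 1),
    )
    if label == "responder":
        if rng.uniform() < cfg.responder_complete_fraction:
            decline_range = cfg.complete_decline
        else:
            decline_range = cfg.responder_decline
    else:
        decline_range = cfg.nonresponder_decline
    decline = float(rng.uniform(*decline_range))

    def _scan(scale: float) -> SuvVolume:
        bg = cfg.background_suv + cfg.background_noise_sd * rng.standard_normal(shape)
        data = np.clip(bg, 0.0, None)
        lesion_vals = texture.data[lesion.data] * scale
        if cfg.lesion_noise_sd > 0:
            lesion_vals = lesion_vals * rng.lognormal(
                0.0, cfg.lesion_noise_sd, size=lesion_vals.shape
            )
        data[lesion.data] = np.maximum(data[lesion.data], lesion_vals)
        return SuvVolume(data, spacing)

    flt1 = _scan(1.0)
    flt2 = _scan(1.0 - decline)

    if label == "responder":
        rcb = "RCB-0" if rng.uniform() < 0.9 else "RCB-I"
    else:
        rcb = "RCB-II" if rng.uniform() < 0.85 else "RCB-III"

    weight = float(np.clip(rng.normal(70.0, 10.0), 45.0, 110.0))
    dose = float(min(3.5 * weight, 350.0))
    return SyntheticPatient(
        patient_id=pid,
        true_label=label,
        scanner=scanner,
        flt1=flt1,
        flt2=flt2,
        lesion_mask=lesion,
        contralateral_mask=contralateral,
        rcb_category=rcb,
        decline=decline,
        dose_mbq=dose,
        weight_kg=weight,
    )


def generate_cohort(config: CohortConfig) -> tuple[list[SyntheticPatient], pd.DataFrame]:
    """Generate a cohort and its truth table.

    Exactly ``round(n_patients * responder_fraction)`` patients are
    responders and ``round(n_patients * scanner_mix)`` are imaged on geometry
    A; assignments are shuffled.  One master seed drives everything, with an
    independent stream spawned per patient so cohorts are reproducible under
    partial regeneration.
    """
    cfg = config
    master = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    n_resp = int(round(n * cfg.responder_fraction))
    n_a = int(round(n * cfg.scanner_mix))
    labels = np.array(["responder"] * n_resp + ["nonresponder"] * (n - n_resp))
    scanners = np.array(["A"] * n_a + ["B"] * (n - n_a))
    master.shuffle(labels)
    master.shuffle(scanners)
    streams = np.random.SeedSequence(cfg.seed).spawn(n)

    patients = []
    for i in range(n):
        pid = f"P{i + 1:03d}"
        rng = np.random.default_rng(streams[i])
        patients.append(_make_patient(pid, str(labels[i]), str(scanners[i]), cfg, rng))

    truth = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "true_label": [p.true_label for p in patients],
            "scanner": [p.scanner for p in patients],
            "decline": [p.decline for p in patients],
            "rcb_category": [p.rcb_category for p in patients],
            "dose_MBq": [p.dose_mbq for p in patients],
            "weight_kg": [p.weight_kg for p in patients],
        }
    )
    return patients, truth


def write_cohort(
    patients: list[SyntheticPatient], truth: pd.DataFrame, outdir: str | Path
) -> Path:
    """Write volumes/masks as NIfTI plus a cohort manifest CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for p in patients:
        pdir = outdir / p.patient_id
        pdir.mkdir(exist_ok=True)
        write_volume(p.flt1, pdir / "flt1.nii.gz")
        write_volume(p.flt2, pdir / "flt2.nii.gz")
        write_mask(p.lesion_mask, pdir / "lesion.nii.gz")
        write_mask(p.contralateral_mask, pdir / "contralateral.nii.gz")
    truth.to_csv(outdir / "manifest.csv", index=False)
    return outdir
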