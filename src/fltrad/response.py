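"""Response coding: percentage change, background correction, EORTC PET
classes, residual-cancer-burden mapping and PET-vs-pathology concordance.

Timepoints are the baseline scan (FLT1) and the scan after the first
chemotherapy cycle (FLT2).  Binary coding throughout: complete response
(CMR / pCR) = 1, anything else = 0.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher

__all__ = [
    "ResponseRecord",
    "percent_change",
    "background_correct",
    "classify_eortc",
    "map_rcb",
    "concordance",
    "fisher_exact_2x2",
    "summarize_flow",
    "EXCLUSION_NO_HISTOLOGY",
    "EXCLUSION_NO_SECOND_SCAN",
]

_EPS = 1e-9

EORTC_CLASSES = ("CMR", "PMR", "SMD", "PMD")
RCB_CATEGORIES = ("RCB-0", "RCB-I", "RCB-II", "RCB-III")
EXCLUSION_NO_HISTOLOGY = "no_histology"
EXCLUSION_NO_SECOND_SCAN = "no_second_scan"


@dataclass
class ResponseRecord:
    """Per-patient response coding.

    ``eortc_class`` is None when the second scan is missing; ``rcb_category``
    is None when histology is unavailable.  A record is evaluable only when
    both are present.
    """

    patient_id: str
    eortc_class: str | None = None
    rcb_category: str | None = None
    suv_max_change_pct: float | None = None

    def __post_init__(self) -> None:
        if self.eortc_class is not None and self.eortc_class not in EORTC_CLASSES:
            raise ValueError(f"unknown EORTC class {self.eortc_class!r}")
        if self.rcb_category is not None and self.rcb_category not in RCB_CATEGORIES:
            raise ValueError(f"unknown RCB category {self.rcb_category!r}")

    @property
    def pet_binary(self) -> int | None:
        if self.eortc_class is None:
            return None
        return 1 if self.eortc_class == "CMR" else 0

    @property
    def path_binary(self) -> int | None:
        if self.rcb_category is None:
            return None
        return map_rcb(self.rcb_category)

    @property
    def evaluable(self) -> bool:
        return self.eortc_class is not None and self.rcb_category is not None

    @property
    def exclusion_reason(self) -> str | None:
        if self.rcb_category is None:
            return EXCLUSION_NO_HISTOLOGY
        if self.eortc_class is None:
            return EXCLUSION_NO_SECOND_SCAN
        return None


def percent_change(v1: float, v2: float) -> float:
    """(FLT1 - FLT2) / FLT1 * 100; a reduction is positive.

    Returns NaN (the undefined flag) when the baseline is ~0; such values are
    excluded from modeling.
    """
    if not np.isfinite(v1):
        raise ValueError("baseline value must be finite")
    if abs(v1) < _EPS:
        return float("nan")
    return (v1 - v2) / v1 * 100.0


def background_correct(
    lesion_stats: tuple[float, float, float],
    contralateral_stats: tuple[float, float, float],
) -> tuple[float, float, float]:
    """Subtract contralateral-breast background statistics, floored at 0.

    Each of (SUV_max, SUV_mean, SUV_peak) has the same statistic of the
    mirrored VOI subtracted.
    """
    return tuple(
        max(0.0, float(a) - float(b))
        for a, b in zip(lesion_stats, contralateral_stats)
    )  # type: ignore[return-value]


def classify_eortc(
    suv1_corrected: float,
    suv2_corrected: float,
    pmr_threshold_pct: float = 15.0,
    pmd_threshold_pct: float = 25.0,
    cmr_tolerance: float = 0.0,
) -> str:
    """EORTC 1999 PET class from background-corrected SUV_max at the two scans.

    * CMR: uptake at FLT2 has vanished into background (corrected value at
      most ``cmr_tolerance``, exactly 0 by default).
    * PMD: increase greater than ``pmd_threshold_pct``.
    * PMR: reduction of at least ``pmr_threshold_pct`` (the one-cycle bound).
    * SMD: everything in between.

    The default PMR threshold is the 15% reduction allowed after a single
    chemotherapy cycle; both thresholds are configurable.  A nonzero
    ``cmr_tolerance`` absorbs residual background-noise differences between
    the lesion and the mirrored contralateral region.

    Raises
    ------
    ValueError
        If the baseline corrected uptake is ~0 so the percent change is
        undefined (unevaluable scan pair).
    """
    if suv2_corrected <= cmr_tolerance + _EPS:
        return "CMR"
    pct = percent_change(suv1_corrected, suv2_corrected)
    if not np.isfinite(pct):
        raise ValueError("baseline corrected SUV_max ~ 0: response unevaluable")
    if pct < -pmd_threshold_pct:
        return "PMD"
    if pct >= pmr_threshold_pct:
        return "PMR"
    return "SMD"


def map_rcb(rcb_category: str) -> int:
    """RCB-0/I -> 1 (pathological complete response), RCB-II/III -> 0."""
    if rcb_category not in RCB_CATEGORIES:
        raise ValueError(f"unknown RCB category {rcb_category!r}")
    return 1 if rcb_category in ("RCB-0", "RCB-I") else 0


def concordance(records: list[ResponseRecord]) -> tuple[np.ndarray, int]:
    """Cross-tabulate PET response against pathological response.

    Returns
    -------
    table : 2x2 int array, rows = PET (CMR=1 first), cols = pathology
        (pCR=1 first); table[0, 0] counts CMR & pCR.
    agreement : diagonal sum (patients where PET agreed with pathology).
    """
    pairs = [
        (r.pet_binary, r.path_binary)
        for r in records
        if r.pet_binary is not None and r.path_binary is not None
    ]
    if not pairs:
        raise ValueError("no records with both PET and pathology codes")
    table = np.zeros((2, 2), dtype=np.int64)
    for pet, path in pairs:
        table[1 - pet, 1 - path] += 1
    agreement = int(table[0, 0] + table[1, 1])
    return table, agreement


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table of nonnegative integers.

    The p-value sums the hypergeometric probabilities (margins fixed) of all
    tables at most as probable as the observed one.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        tf = t.astype(np.float64)
        if np.any(tf < 0) or np.any(tf != np.round(tf)):
            raise ValueError("table cells must be nonnegative integers")
        t = tf.astype(np.int64)
    return float(_scipy_fisher(t, alternative="two-sided").pvalue)


def summarize_flow(records: list[ResponseRecord]) -> dict:
    """Patient-flow accounting: enrolled = evaluable + excluded (by reason).

    Also reports the PET (CR/PR) and pathology (pCR/pPR) margins of the
    evaluable set.
    """
    evaluable = [r for r in records if r.evaluable]
    reasons = Counter(
        r.exclusion_reason for r in records if r.exclusion_reason is not None
    )
    return {
        "n_enrolled": len(records),
        "n_evaluable": len(evaluable),
        "n_excluded": len(records) - len(evaluable),
        "exclusions": dict(sorted(reasons.items())),
        "pet_cr": sum(r.pet_binary == 1 for r in evaluable),
        "pet_pr": sum(r.pet_binary == 0 for r in evaluable),
        "path_pcr": sum(r.path_binary == 1 for r in evaluable),
        "path_ppr": sum(r.path_binary == 0 for r in evaluable),
    }


def response_table(records: list[ResponseRecord]) -> pd.DataFrame:
    """Tidy per-patient response table (evaluable and excluded rows)."""
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "eortc_class": [r.eortc_class for r in records],
            "pet_binary": [r.pet_binary for r in records],
            "rcb_category": [r.rcb_category for r in records],
            "path_binary": [r.path_binary for r in records],
            "suv_max_change_pct": [r.suv_max_change_pct for r in records],
            "exclusion_reason": [r.exclusion_reason for r in records],
        }
    )
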