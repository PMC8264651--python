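"""Planted-signal simulation designs used to validate the pipeline.

Two reusable experiment designs on synthetic cohorts where the ground truth
is known by construction:

* **Contour-robustness trial** — a cohort is generated, features are
  extracted on the four contour variants, percentage changes are computed,
  and contour-*sensitive* decoy features (independent noise redrawn per
  contour variant) are appended.  The ICC filter should retain the
  contour-stable SUV statistics and reject the decoys.

* **Model-recovery trial** — the planted signal is the percentage change of
  SUV_max, which separates responders from non-responders by construction
  (40-70% declines vs 0-10%).  The decoy covariates are the scale-invariant
  indices (intensity ratios, IVH, all discretized-texture families): under
  the generator's uniform multiplicative decline their percentage changes
  carry no label information, while any raw-intensity statistic would be
  collinear with the planted column.  The LASSO-LOOCV model should select
  SUV_max with a positive sign (complete response = 1) and classify well.

The trial cohort is a well-separated partial-decline design:
30 patients, half responders, no complete disappearances, so lesions stay
textured at both timepoints and the decoys stay uninformative.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import SCALE_INVARIANT_FEATURES
from .model import lasso_logistic_loocv
from .pipeline import PipelineConfig, extract_cohort_features, pct_change_table
from .robustness import robust_filter
from .synth import CohortConfig, generate_cohort

__all__ = [
    "planted_cohort_config",
    "cohort_pct_changes",
    "add_contour_noise_decoys",
    "robustness_trial",
    "model_recovery_trial",
]

SUV_STATISTICS = ("SUV_max", "SUV_mean", "SUV_peak")


def planted_cohort_config(seed: int, n_patients: int = 30) -> CohortConfig:
    """Cohort with a planted partial-decline separation (40-70% vs 0-10%)."""
    return CohortConfig(
        n_patients=n_patients,
        responder_fraction=0.5,
        lesion_radius_mm=(5.0, 9.0),
        responder_decline=(0.40, 0.70),
        responder_complete_fraction=0.0,
        nonresponder_decline=(0.00, 0.10),
        seed=seed,
    )


def cohort_pct_changes(
    config: CohortConfig, pipeline: PipelineConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a cohort and return (percentage-change table, truth table)."""
    if pipeline is None:
        pipeline = PipelineConfig(cohort=config)
    patients, truth = generate_cohort(config)
    features = extract_cohort_features(patients, pipeline)
    return pct_change_table(features), truth


def add_contour_noise_decoys(
    pct: pd.DataFrame, n_decoys: int = 5, seed: int = 0
) -> pd.DataFrame:
    """Append contour-sensitive decoy features to a percentage-change table.

    Each decoy value is redrawn independently per (patient, contour variant),
    emulating an index with no agreement across contours; its ICC is ~0.
    """
    rng = np.random.default_rng(seed)
    patients = sorted(pct["patient_id"].unique())
    variants = sorted(pct["contour_variant"].unique())
    rows = []
    for d in range(n_decoys):
        for pid in patients:
            for v in variants:
                rows.append(
                    {
                        "patient_id": pid,
                        "contour_variant": v,
                        "feature_id": f"DECOY_ContourNoise_{d}",
                        "value": rng.normal(0.0, 1.0),
                    }
                )
    return pd.concat([pct, pd.DataFrame(rows)], ignore_index=True)


def robustness_trial(
    pct: pd.DataFrame,
    n_decoys: int = 5,
    decoy_seed: int = 0,
    threshold: float = 0.60,
) -> dict:
    """Run the ICC filter against planted stable/unstable features.

    Returns which SUV statistics passed and how many decoys were rejected.
    """
    table = add_contour_noise_decoys(pct, n_decoys=n_decoys, seed=decoy_seed)
    retained, icc_table = robust_filter(table, threshold=threshold)
    retained_set = set(retained)
    decoys = [f"DECOY_ContourNoise_{d}" for d in range(n_decoys)]
    return {
        "suv_stats_retained": all(s in retained_set for s in SUV_STATISTICS),
        "decoys_rejected": all(d not in retained_set for d in decoys),
        "n_retained": len(retained),
        "icc_table": icc_table,
    }


def model_recovery_trial(pct: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Fit the LASSO-LOOCV model on planted SUV_max signal + decoy covariates.

    Covariates: percentage change of SUV_max (the planted signal) plus the
    scale-invariant feature set (structurally uninformative under uniform
    decline).  Outcome: true responder label, complete response coded 1.
    """
    covariates = ["SUV_max", *SCALE_INVARIANT_FEATURES]
    wide = pct[pct["contour_variant"] == "original"].pivot_table(
        index="patient_id", columns="feature_id", values="value"
    )
    wide = wide.reindex(columns=covariates)
    y = (
        truth.set_index("patient_id")["true_label"]
        .reindex(wide.index)
        .eq("responder")
        .to_numpy(float)
    )
    keep = ~wide.isna().any(axis=1).to_numpy()
    fit = lasso_logistic_loocv(
        wide.to_numpy()[keep], y[keep], covariates, outcome="true_response"
    )
    suv_coef = fit.coefficients.get("SUV_max", 0.0)
    return {
        "selected_suv_max": suv_coef != 0.0,
        "suv_max_sign_positive": suv_coef > 0.0,
        "loocv_error": fit.loocv_error,
        "n_nonzero": len(fit.coefficients),
        "n_decoys_selected": len(
            [k for k in fit.coefficients if k != "SUV_max"]
        ),
        "fit": fit,
    }
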