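"""Contour-robustness of radiomic features via the intraclass correlation.

Each feature is measured on the four contour variants of every lesion
(original, +1 mm, +2 mm, -1 mm); the variants play the role of "raters" in a
two-way random-effects ANOVA.  A feature is retained when the lower bound of
the 95% CI of the single-measurement, absolute-agreement ICC(A,1) is at least
0.60 (inclusive).  ICC and CI follow McGraw & Wong's mean-squares form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["IccResult", "icc_a1", "robust_filter", "ContourRobustnessFilter"]


@dataclass
class IccResult:
    """ICC(A,1) for one feature over k contour variants of n lesions."""

    icc: float
    ci_lower: float
    ci_upper: float
    n_subjects: int
    k_raters: int
    feature_id: str | None = None
    defined: bool = True  # False for a constant feature (zero total variance)


def icc_a1(matrix: np.ndarray, alpha: float = 0.05, feature_id: str | None = None) -> IccResult:
    """Single-measurement absolute-agreement ICC(A,1) with its F-based CI.

    Parameters
    ----------
    matrix : array, shape (n_subjects, k_raters)
        One row per lesion, one column per contour variant; no missing cells.

    Notes
    -----
    With MSR/MSC/MSE the row, column and residual mean squares of the two-way
    ANOVA::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    Negative estimates are reported as computed.  Zero total variance yields
    an undefined-flagged result.
    """
    x = np.asarray(matrix, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("matrix must be 2D (subjects x raters)")
    n, k = x.shape
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("matrix contains non-finite values")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sse = ((x - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    total_var = msr + msc + mse
    if total_var <= 0 or np.ptp(x) == 0:
        return IccResult(np.nan, np.nan, np.nan, n, k, feature_id, defined=False)

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return IccResult(np.nan, np.nan, np.nan, n, k, feature_id, defined=False)
    icc = (msr - mse) / denom

    if mse == 0 and msc == 0:
        # perfect agreement across variants with real subject variance
        return IccResult(1.0, 1.0, 1.0, n, k, feature_id)

    # McGraw & Wong (1996) CI for ICC(A,1); Satterthwaite df for the
    # rater/error mixture.
    fj = msj_over_mse = msc / mse if mse > 0 else np.inf
    df_e = (n - 1) * (k - 1)
    vn = df_e * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
    vd = (n - 1) * k**2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
    v = vn / vd
    f_u = f_dist.ppf(1 - alpha / 2, n - 1, v)
    f_l = f_dist.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
    return IccResult(float(icc), float(lower), float(upper), n, k, feature_id)


def _pivot_variant_table(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Split a tidy table (patient_id, contour_variant, feature_id, value)
    into per-feature subjects x variants matrices, dropping subjects with any
    missing variant."""
    out = {}
    for fid, sub in table.groupby("feature_id", sort=True):
        wide = sub.pivot_table(
            index="patient_id", columns="contour_variant", values="value"
        )
        wide = wide.dropna(axis=0, how="any")
        out[str(fid)] = wide
    return out


def robust_filter(
    table: pd.DataFrame, threshold: float = 0.60, alpha: float = 0.05
) -> tuple[list[str], pd.DataFrame]:
    """Apply the ICC robustness filter to a tidy feature/variant table.

    Parameters
    ----------
    table : DataFrame with columns patient_id, contour_variant, feature_id,
        value — typically percentage-change values matched across variants.
    threshold : retain a feature iff the ICC 95% CI lower bound >= threshold
        (inclusive).

    Returns
    -------
    (retained, icc_table) : the retained feature ids and a DataFrame with one
        row per feature (feature_id, icc, ci_lower, ci_upper, n_subjects,
        defined, retained).
    """
    rows = []
    for fid, wide in _pivot_variant_table(table).items():
        res = icc_a1(wide.to_numpy(), alpha=alpha, feature_id=fid)
        retained = bool(res.defined and res.ci_lower >= threshold)
        rows.append(
            {
                "feature_id": fid,
                "icc": res.icc,
                "ci_lower": res.ci_lower,
                "ci_upper": res.ci_upper,
                "n_subjects": res.n_subjects,
                "defined": res.defined,
                "retained": retained,
            }
        )
    icc_table = pd.DataFrame(rows).set_index("feature_id").sort_index()
    retained_ids = [fid for fid in icc_table.index[icc_table["retained"]]]
    return retained_ids, icc_table


class ContourRobustnessFilter(BaseEstimator, TransformerMixin):
    """Feature selector retaining contour-robust features (sklearn-style).

    ``fit`` expects a 3D array X of shape (n_subjects, k_variants,
    n_features) — each feature's subjects x variants slab is scored with
    ICC(A,1) — and ``transform`` then selects the retained columns from a 2D
    (n_subjects, n_features) matrix (e.g. the original-contour values).

    Parameters
    ----------
    threshold : float, default 0.60
        Inclusive cutoff on the ICC 95% CI lower bound.
    alpha : float, default 0.05
        CI level (1 - alpha).

    Attributes
    ----------
    icc_ : ndarray of ICC estimates per feature.
    ci_lower_ : ndarray of CI lower bounds per feature.
    support_ : boolean mask of retained features.
    """

    def __init__(self, threshold: float = 0.60, alpha: float = 0.05):
        self.threshold = threshold
        self.alpha = alpha

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError(
                "X must have shape (n_subjects, k_variants, n_features)"
            )
        n, k, p = X.shape
        icc = np.empty(p)
        lower = np.empty(p)
        for j in range(p):
            res = icc_a1(X[:, :, j], alpha=self.alpha)
            icc[j] = res.icc
            lower[j] = res.ci_lower if res.defined else -np.inf
        self.n_features_in_ = p
        self.icc_ = icc
        self.ci_lower_ = lower
        self.support_ = lower >= self.threshold
        return self

    def get_support(self, indices: bool = False):
        check_is_fitted(self, "support_")
        return np.flatnonzero(self.support_) if indices else self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = np.asarray(X)
        if X.shape[-1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[-1]} features, expected {self.n_features_in_}"
            )
        return X[..., self.support_]
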