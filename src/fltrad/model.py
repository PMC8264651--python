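"""L1-penalized logistic response models with leave-one-out lambda tuning.

The classifier mirrors the glmnet-style workflow: covariates standardized,
intercept unpenalized, a descending log-spaced penalty grid starting at the
smallest lambda for which every slope is exactly zero, lambda selected by
minimal leave-one-out binomial deviance, final refit on the full data.  The
misclassification rate at a 0.5 probability cutoff is reported separately
from the tuning loss, which is the stable criterion at small n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted, check_X_y

__all__ = ["LassoFit", "LassoLoocvClassifier", "lasso_logistic_loocv", "classification_error"]

_P_CLIP = 1e-12


@dataclass
class LassoFit:
    """Report of one fitted response model: nonzero terms, penalty, error."""

    outcome: str
    covariates: list[str]
    intercept: float
    coefficients: dict[str, float]  # nonzero only, standardized scale
    lambda_min: float
    loocv_error: float
    cv_deviance: float

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "covariates": list(self.covariates),
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "lambda_min": self.lambda_min,
            "loocv_error": self.loocv_error,
            "cv_deviance": self.cv_deviance,
        }


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _P_CLIP, 1 - _P_CLIP)
    return float(-2.0 * (y * np.log(p) + (1 - y) * np.log(1 - p)).sum())


class LassoLoocvClassifier(BaseEstimator, ClassifierMixin):
    """LASSO logistic regression tuned by leave-one-out cross-validation.

    Parameters
    ----------
    n_lambdas : int, default 100
        Size of the descending log-spaced penalty grid.
    lambda_min_ratio : float, default 0.01
        Smallest grid value as a fraction of lambda_max.
    lambda_fixed : float or None
        If set, skip tuning and fit at this penalty (used by the external
        LOOCV error oracle).
    standardize : bool, default True
        Center/scale covariates before penalization (L1 is scale dependent);
        reported coefficients stay on the standardized scale.
    tol, max_iter : solver convergence controls (saga).

    Attributes
    ----------
    coef_ : (n_features,) slope vector on the standardized scale.
    intercept_ : float.
    lambda_min_ : selected penalty.
    lambdas_, cv_deviance_path_ : the grid and its LOOCV deviances.
    loocv_error_ : LOOCV misclassification rate at the selected penalty
        (ties at p = 0.5 predict class 1).
    """

    def __init__(
        self,
        n_lambdas: int = 100,
        lambda_min_ratio: float = 0.01,
        lambda_fixed: float | None = None,
        standardize: bool = True,
        tol: float = 1e-6,
        max_iter: int = 10000,
    ):
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.lambda_fixed = lambda_fixed
        self.standardize = standardize
        self.tol = tol
        self.max_iter = max_iter

    # -- internals --------------------------------------------------------

    def _prepare(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("y must contain exactly two classes")
        if not np.array_equal(classes, [0, 1]):
            raise ValueError("y must be coded 0/1 (complete response = 1)")
        if X.shape[0] < 5:
            raise ValueError(f"need at least 5 samples, got {X.shape[0]}")
        return X, y.astype(np.float64)

    def _scale(self, X):
        if self.standardize:
            mean = X.mean(axis=0)
            sd = X.std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
        else:
            mean = np.zeros(X.shape[1])
            sd = np.ones(X.shape[1])
        return (X - mean) / sd, mean, sd

    @staticmethod
    def _lambda_grid(Xs, y, n_lambdas, ratio):
        n = Xs.shape[0]
        resid = y - y.mean()
        lam_max = np.abs(Xs.T @ resid).max() / n
        if lam_max <= 0:
            return None
        return np.geomspace(lam_max, lam_max * ratio, n_lambdas)

    def _fit_at(self, Xs, y, lam):
        """One penalized fit; returns (intercept, coef) on the given scale."""
        n = Xs.shape[0]
        if y.min() == y.max() or lam <= 0 or not np.any(Xs.std(axis=0) > 0):
            p = np.clip(y.mean(), _P_CLIP, 1 - _P_CLIP)
            return float(np.log(p / (1 - p))), np.zeros(Xs.shape[1])
        clf = LogisticRegression(
            l1_ratio=1.0,
            C=1.0 / (lam * n),
            solver="saga",
            tol=self.tol,
            max_iter=self.max_iter,
            random_state=0,
        )
        with warnings.catch_warnings():
            # separable data at weak penalties converges slowly; the deviance
            # and selection path are insensitive to the residual gap
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(Xs, y)
        coef = clf.coef_[0].copy()
        coef[np.abs(coef) < 1e-10] = 0.0  # solver float noise at the boundary
        return float(clf.intercept_[0]), coef

    def _path_fits(self, Xs, y, grid):
        """Fits along a descending penalty grid with warm starts.

        Returns per-lambda (intercept, coef) pairs; degenerate inputs fall
        back to per-lambda intercept-only fits.
        """
        n = Xs.shape[0]
        if y.min() == y.max() or not np.any(Xs.std(axis=0) > 0):
            return [self._fit_at(Xs, y, lam) for lam in grid]
        clf = LogisticRegression(
            l1_ratio=1.0,
            C=1.0,
            solver="saga",
            tol=self.tol,
            max_iter=self.max_iter,
            warm_start=True,
            random_state=0,
        )
        out = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for lam in grid:
                clf.set_params(C=1.0 / (lam * n))
                clf.fit(Xs, y)
                coef = clf.coef_[0].copy()
                coef[np.abs(coef) < 1e-10] = 0.0
                out.append((float(clf.intercept_[0]), coef))
        return out

    # -- sklearn API ------------------------------------------------------

    def fit(self, X, y):
        X, y = self._prepare(X, y)
        n = X.shape[0]
        Xs, self.mean_, self.scale_ = self._scale(X)

        if self.lambda_fixed is not None:
            grid = np.asarray([float(self.lambda_fixed)])
        else:
            grid = self._lambda_grid(Xs, y, self.n_lambdas, self.lambda_min_ratio)
        if grid is None:
            # no informative covariate: intercept-only model
            self.lambdas_ = np.asarray([0.0])
            self.cv_deviance_path_ = np.asarray([np.nan])
            self.lambda_min_ = 0.0
            self.intercept_, self.coef_ = self._fit_at(Xs, y, 0.0)
            self.loocv_error_ = self._loocv_error(Xs, y, 0.0)
            self.cv_deviance_ = float("nan")
            self.classes_ = np.array([0.0, 1.0])
            self.n_features_in_ = X.shape[1]
            return self

        # LOOCV deviance path: one held-out probability per fold per lambda,
        # warm-starting along the descending grid within each fold.
        dev = np.zeros(grid.size)
        for i in range(n):
            tr = np.ones(n, dtype=bool)
            tr[i] = False
            for j, (b0, b) in enumerate(self._path_fits(Xs[tr], y[tr], grid)):
                p = 1.0 / (1.0 + np.exp(-(b0 + Xs[i] @ b)))
                dev[j] += _binomial_deviance(y[i : i + 1], np.asarray([p]))
        best = int(np.argmin(dev))  # ties -> largest lambda (first index)
        self.lambdas_ = grid
        self.cv_deviance_path_ = dev
        self.lambda_min_ = float(grid[best])
        self.cv_deviance_ = float(dev[best])
        self.intercept_, self.coef_ = self._fit_at(Xs, y, self.lambda_min_)
        self.loocv_error_ = self._loocv_error(Xs, y, self.lambda_min_)
        self.classes_ = np.array([0.0, 1.0])
        self.n_features_in_ = X.shape[1]
        return self

    def _loocv_error(self, Xs, y, lam) -> float:
        n = Xs.shape[0]
        wrong = 0
        for i in range(n):
            tr = np.ones(n, dtype=bool)
            tr[i] = False
            b0, b = self._fit_at(Xs[tr], y[tr], lam)
            p = 1.0 / (1.0 + np.exp(-(b0 + Xs[i] @ b)))
            pred = 1.0 if p >= 0.5 else 0.0  # tie at 0.5 -> class 1
            wrong += pred != y[i]
        return wrong / n

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=np.float64)
        Xs = (X - self.mean_) / self.scale_
        return self.intercept_ + Xs @ self.coef_

    def predict_proba(self, X):
        z = self.decision_function(X)
        p = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([1 - p, p])

    def predict(self, X):
        p = self.predict_proba(X)[:, 1]
        return (p >= 0.5).astype(float)  # tie at 0.5 -> class 1

    def n_nonzero_(self) -> int:
        check_is_fitted(self, "coef_")
        return int(np.sum(self.coef_ != 0))


def lasso_logistic_loocv(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    outcome: str = "pet_response",
    **params,
) -> LassoFit:
    """Fit the tuned model and return a report of the nonzero terms."""
    if len(feature_names) != np.asarray(X).shape[1]:
        raise ValueError("feature_names length must match X columns")
    est = LassoLoocvClassifier(**params).fit(X, y)
    nonzero = {
        name: float(c)
        for name, c in zip(feature_names, est.coef_)
        if c != 0.0
    }
    return LassoFit(
        outcome=outcome,
        covariates=list(feature_names),
        intercept=float(est.intercept_),
        coefficients=nonzero,
        lambda_min=float(est.lambda_min_),
        loocv_error=float(est.loocv_error_),
        cv_deviance=float(est.cv_deviance_),
    )


def classification_error(
    est: LassoLoocvClassifier, X, y, loocv: bool = False
) -> float:
    """Misclassification rate at the 0.5 cutoff; with ``loocv=True`` the
    model is refit n times at the selected penalty, excluding each sample."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if not loocv:
        return float((est.predict(X) != y).mean())
    Xs = (X - est.mean_) / est.scale_
    return est._loocv_error(Xs, y, est.lambda_min_)
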