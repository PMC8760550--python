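"""Pre-clustering covariate scan and residualization.

Protein levels in plasma co-vary strongly with body-mass index, age and
sample age (entry date). Before clustering these are removed: each
antibody's log-MFI is regressed on intercept + BMI + age + entry date in
one joint OLS, and the residual (plus the fitted intercept, so the
location is preserved) is carried forward. Held-out samples (doubles,
replicates) are adjusted with the coefficients estimated on the study
samples only, never refit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import MFIMatrix

__all__ = ["CovariateAdjuster", "CovariateScanResult", "covariate_scan", "residualize"]

DEFAULT_COVARIATES = ("bmi", "age", "entry_date")


@dataclass
class CovariateScanResult:
    """Per-antibody covariate p-values from the joint linear model."""

    pvalues: pd.DataFrame  # antibodies x covariates
    coefficients: pd.DataFrame
    n_samples: int

    def significant_counts(self, alpha: float = 0.05) -> pd.Series:
        return (self.pvalues < alpha).sum(axis=0)


def _design(covariates: pd.DataFrame, names) -> np.ndarray:
    cols = [np.ones(len(covariates))]
    for c in names:
        v = covariates[c].to_numpy(float)
        if np.isnan(v).any():
            raise ValueError(f"covariate {c} has missing values; drop those samples first")
        cols.append(v)
    D = np.column_stack(cols)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("rank-deficient design (constant or collinear covariate)")
    return D


class CovariateAdjuster(TransformerMixin, BaseEstimator):
    """OLS residualization of log-MFI on clinical covariates.

    fit(X, covariates=...) estimates per-antibody slopes on the supplied
    samples; transform removes the covariate contribution (keeping the
    fitted intercept) from any sample set with known covariates.

    Attributes
    ----------
    coef_ : pandas.DataFrame
        (1 + n_covariates) x n_antibodies coefficient matrix
        (intercept row first).
    """

    def __init__(self, covariates=DEFAULT_COVARIATES):
        self.covariates = covariates

    def fit(self, X: MFIMatrix, covariates: pd.DataFrame = None, y=None):
        if covariates is None:
            raise ValueError("fit requires a covariates DataFrame")
        cov = covariates.loc[X.values.index]
        D = _design(cov, self.covariates)
        # center covariates at their training means: the intercept becomes
        # the column mean, so adjustment preserves each antibody's location
        self.cov_means_ = D[:, 1:].mean(axis=0)
        D = D.copy()
        D[:, 1:] -= self.cov_means_
        Y = np.log(X.values.to_numpy())
        beta, *_ = np.linalg.lstsq(D, Y, rcond=None)
        self.coef_ = pd.DataFrame(
            beta, index=["intercept", *self.covariates], columns=X.values.columns)
        self._D = D
        self._Y = Y
        self._index = X.values.index
        return self

    def scan(self) -> CovariateScanResult:
        """Two-sided t-test p per covariate per antibody from the joint fit."""
        D, Y = self._D, self._Y
        n, q = D.shape
        beta = self.coef_.to_numpy()
        resid = Y - D @ beta
        dof = n - q
        sigma2 = (resid ** 2).sum(axis=0) / dof
        XtX_inv = np.linalg.inv(D.T @ D)
        se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
        tstat = beta / se
        pv = 2 * stats.t.sf(np.abs(tstat), dof)
        pvals = pd.DataFrame(pv[1:].T, index=self.coef_.columns,
                             columns=list(self.covariates))
        coefs = pd.DataFrame(beta[1:].T, index=self.coef_.columns,
                             columns=list(self.covariates))
        return CovariateScanResult(pvalues=pvals, coefficients=coefs, n_samples=n)

    def transform(self, X: MFIMatrix, covariates: pd.DataFrame = None) -> MFIMatrix:
        if covariates is None:
            raise ValueError("transform requires a covariates DataFrame")
        cov = covariates.loc[X.values.index]
        D = _design(cov, self.covariates)
        Y = np.log(X.values.to_numpy())
        beta = self.coef_.to_numpy()
        # remove the covariate part relative to the training means
        adj = Y - (D[:, 1:] - self.cov_means_) @ beta[1:]
        out = pd.DataFrame(np.exp(adj), index=X.values.index,
                           columns=X.values.columns)
        return X.with_values(out)


def covariate_scan(
    matrix: MFIMatrix, covariates: pd.DataFrame,
    names=DEFAULT_COVARIATES,
) -> CovariateScanResult:
    """Joint OLS of log-MFI on the named covariates; per-coefficient
    two-sided t-test p-values."""
    adj = CovariateAdjuster(covariates=names).fit(matrix, covariates=covariates)
    return adj.scan()


def residualize(
    matrix: MFIMatrix, covariates: pd.DataFrame,
    names=DEFAULT_COVARIATES,
    fit_on: pd.Index | None = None,
) -> MFIMatrix:
    """Residualize log-MFI on covariates; coefficients estimated on
    ``fit_on`` samples (default: samples with role 'study'), all samples
    transformed."""
    if fit_on is None:
        fit_on = matrix.values.index[(matrix.roles == "study").to_numpy()]
        if len(fit_on) == 0:
            fit_on = matrix.values.index
    adj = CovariateAdjuster(covariates=names).fit(
        matrix.subset(samples=fit_on), covariates=covariates)
    return adj.transform(matrix, covariates=covariates)
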