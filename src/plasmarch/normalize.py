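"""Within-plate Abs-PQN and between-plate MA normalization.

Abs-PQN (antibody-specific probabilistic quotient normalization) removes
per-sample dilution differences within each 96-well plate. Classical PQN
divides every sample by the median quotient of its profile against a
plate-reference profile; the antibody-specific variant computes that
median quotient separately for every antibody over the set of antibodies
most similar to it (Spearman correlation), so antibodies riding on
different dilution regimes get their own factor. With the similarity set
widened to all antibodies it degrades exactly to classical PQN.

MA normalization removes between-plate batch effects: per plate and
antibody, the difference M of the plate median log-intensity from the
global median is smoothed (lowess) as a function of the average level A
and the fitted trend is subtracted from the plate's samples.

Both are exposed as sklearn-style transformers (`AbsPQN`, `MANormalizer`)
operating on :class:`~plasmarch.containers.MFIMatrix`, plus thin
functional wrappers `abs_pqn` / `ma_normalize`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import MFIMatrix

__all__ = ["AbsPQN", "MANormalizer", "abs_pqn", "ma_normalize"]


def _check_positive(matrix: MFIMatrix) -> None:
    if np.any(matrix.values.to_numpy() <= 0):
        raise ValueError("MFI matrix must be strictly positive")


class AbsPQN(TransformerMixin, BaseEstimator):
    """Antibody-specific probabilistic quotient normalization, per plate.

    Parameters
    ----------
    n_similar : int, default=50
        Size of the per-antibody similarity set (the antibody itself
        included). ``n_similar >= n_antibodies`` reduces to classical
        global PQN.
    use_roles : bool, default=True
        Exclude pool samples from the reference profile and similarity
        correlations (they are still transformed with the plate's
        factors).

    Attributes
    ----------
    factors_ : pandas.DataFrame
        Per-sample, per-antibody quotient factors of the last transform.
    """

    def __init__(self, n_similar: int = 50, use_roles: bool = True):
        self.n_similar = n_similar
        self.use_roles = use_roles

    def fit(self, X: MFIMatrix, y=None):
        _check_positive(X)
        return self

    def transform(self, X: MFIMatrix) -> MFIMatrix:
        _check_positive(X)
        if self.n_similar < 1:
            raise ValueError("n_similar must be >= 1")
        vals = X.values
        out = vals.copy()
        factors = pd.DataFrame(1.0, index=vals.index, columns=vals.columns)
        for plate, idx in vals.groupby(X.plates).groups.items():
            sub = vals.loc[idx]
            if len(sub) < 3:
                raise ValueError(f"plate {plate} has fewer than 3 samples")
            ref_mask = np.ones(len(sub), bool)
            if self.use_roles:
                ref_mask = (X.roles.loc[idx] != "pool").to_numpy()
                if ref_mask.sum() < 3:
                    ref_mask = np.ones(len(sub), bool)
            f = self._plate_factors(sub.to_numpy(), ref_mask)
            factors.loc[idx] = f
            out.loc[idx] = sub.to_numpy() / f
        self.factors_ = factors
        return X.with_values(out)

    def _plate_factors(self, x: np.ndarray, ref_mask: np.ndarray) -> np.ndarray:
        n, p = x.shape
        ref = np.median(x[ref_mask], axis=0)  # plate reference profile
        quot = x / ref[None, :]
        m = min(self.n_similar, p)
        if m >= p:
            # classical PQN: one factor per sample
            f = np.median(quot, axis=1)
            return np.repeat(f[:, None], p, axis=1)
        # Spearman correlation between antibodies across the plate's
        # reference samples; ties in the ranking broken by column order
        ranks = rankdata(np.log(x[ref_mask]), axis=0)
        ranks -= ranks.mean(axis=0)
        norm = np.sqrt((ranks ** 2).sum(axis=0))
        norm[norm == 0] = 1.0
        corr = (ranks.T @ ranks) / np.outer(norm, norm)
        # stable selection: sort by (-corr, column index)
        order = np.argsort(-corr, axis=1, kind="stable")
        sets = order[:, :m]  # (p, m) similarity sets
        f = np.empty_like(x)
        for j in range(p):
            f[:, j] = np.median(quot[:, sets[j]], axis=1)
        return f


class MANormalizer(TransformerMixin, BaseEstimator):
    """Between-plate MA normalization with lowess smoothing.

    Per antibody j the global reference is the median log intensity
    g_j over all samples. Per plate p, M_pj = plate median log - g_j and
    A_pj = (plate median log + g_j)/2; a lowess fit of M on A across
    antibodies (span = ``span``) gives the plate's intensity-dependent
    offset, which is subtracted from every sample of the plate.
    """

    def __init__(self, span: float = 0.3, use_roles: bool = True):
        self.span = span
        self.use_roles = use_roles

    def fit(self, X: MFIMatrix, y=None):
        _check_positive(X)
        return self

    def transform(self, X: MFIMatrix) -> MFIMatrix:
        _check_positive(X)
        logv = np.log(X.values.to_numpy())
        n, p = logv.shape
        if p < 10:
            raise ValueError("MA normalization needs at least 10 antibodies")
        plates = X.plates.to_numpy()
        uplates = np.unique(plates)
        if len(uplates) < 2:
            raise ValueError("MA normalization needs at least 2 plates")
        ref_rows = np.ones(n, bool)
        if self.use_roles:
            ref_rows = (X.roles != "pool").to_numpy()
            if not ref_rows.any():
                ref_rows = np.ones(n, bool)
        g = np.median(logv[ref_rows], axis=0)
        out = logv.copy()
        self.curves_ = {}
        for plate in uplates:
            rows = plates == plate
            prow = rows & ref_rows
            if not prow.any():
                prow = rows
            med = np.median(logv[prow], axis=0)
            M = med - g
            A = (med + g) / 2.0
            fitted = lowess(M, A, frac=self.span, return_sorted=False)
            out[rows] -= fitted[None, :]
            self.curves_[str(plate)] = pd.DataFrame(
                {"A": A, "M": M, "fitted": fitted}, index=X.values.columns)
        return X.with_values(
            pd.DataFrame(np.exp(out), index=X.values.index, columns=X.values.columns))


def abs_pqn(matrix: MFIMatrix, n_similar: int = 50, use_roles: bool = True) -> MFIMatrix:
    """Functional wrapper over :class:`AbsPQN`."""
    return AbsPQN(n_similar=n_similar, use_roles=use_roles).fit(matrix).transform(matrix)


def ma_normalize(matrix: MFIMatrix, span: float = 0.3, use_roles: bool = True) -> MFIMatrix:
    """Functional wrapper over :class:`MANormalizer`."""
    return MANormalizer(span=span, use_roles=use_roles).fit(matrix).transform(matrix)
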