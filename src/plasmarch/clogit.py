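"""Conditional logistic regression for 1:M matched case-control sets.

Matching on age and sampling site is respected by conditioning on the
set totals: the per-set intercept drops out and the conditional
likelihood for a set s with a single case is

    L_s(beta) = exp(eta_case) / sum_{l in s} exp(eta_l),   eta = x' beta.

The total log likelihood is maximized by Newton-Raphson with
step-halving. Three exposure models mirror a typical risk-factor
build-up: model 1 adds BMI and entry date to the protein term; model 2
adds dense area, postmenopausal status and MHT ever-use; model 3 adds
smoking, alcohol and parity. Sets with any missing model covariate are
dropped whole, which keeps the conditional likelihood well-formed and
reproduces per-model sample counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = ["MatchedSet", "ConditionalLogit", "fit_clogit",
           "screen_proteins_clogit", "build_matched_sets", "MODEL_COVARIATES"]

MODEL_COVARIATES = {
    1: ["bmi", "entry_date"],
    2: ["bmi", "entry_date", "dense_area", "postmenopausal", "mht_ever"],
    3: ["bmi", "entry_date", "dense_area", "postmenopausal", "mht_ever",
        "smoking", "alcohol", "parity_ever"],
}


@dataclass
class MatchedSet:
    """One matched set: the case's exposure row first, controls after."""

    set_id: str
    X: np.ndarray  # (1 + n_controls, q) exposures; row 0 is the case
    case_index: int = 0
    members: list = field(default_factory=list)  # sample ids, case first


class ConditionalLogit(BaseEstimator):
    """Newton-Raphson conditional-likelihood estimator.

    Parameters
    ----------
    max_iter : int, default=50
    tol : float, default=1e-10
        Convergence on the change in log likelihood.

    Attributes
    ----------
    coef_, se_, pvalues_ : (q,) arrays (Wald tests, two-sided)
    loglik_, n_iter_, converged_, separated_
    """

    def __init__(self, max_iter: int = 50, tol: float = 1e-10):
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, sets: list[MatchedSet]):
        if len(sets) < 2:
            raise ValueError("need at least 2 matched sets")
        Xs = [np.asarray(s.X, dtype=float) for s in sets]
        q = Xs[0].shape[1]
        if any(x.shape[1] != q for x in Xs):
            raise ValueError("inconsistent exposure dimension across sets")
        # sets with no within-set exposure variation contribute a constant
        # -log|s|; if every set is flat the likelihood is flat and beta = 0
        # by convention (zero gradient everywhere)
        informative = [x for x in Xs if np.ptp(x, axis=0).max() > 0]
        if not informative:
            self.coef_ = np.zeros(q)
            self.se_ = np.full(q, np.inf)
            self.pvalues_ = np.ones(q)
            self.loglik_ = float(-sum(np.log(len(x)) for x in Xs))
            self.n_iter_ = 0
            self.converged_ = True
            self.separated_ = False
            self.n_sets_ = len(Xs)
            return self
        beta = np.zeros(q)
        ll = self._loglik(Xs, beta)
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            g, H = self._score_hess(Xs, beta)
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, g, rcond=None)[0]
            # Newton direction (H is negative definite): beta - H^-1 g
            new_beta = beta - step
            new_ll = self._loglik(Xs, new_beta)
            halvings = 0
            while new_ll < ll - 1e-12 and halvings < 30:
                step /= 2.0
                new_beta = beta - step
                new_ll = self._loglik(Xs, new_beta)
                halvings += 1
            beta, prev_ll, ll = new_beta, ll, new_ll
            if abs(ll - prev_ll) < self.tol:
                converged = True
                break
        if not converged:
            raise RuntimeError(f"conditional logit did not converge in {self.max_iter} iterations")
        _, H = self._score_hess(Xs, beta)
        cov = np.linalg.inv(-H)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        self.separated_ = bool(np.any(np.abs(beta) > 25) or np.any(~np.isfinite(se)))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = beta / se
        self.coef_ = beta
        self.se_ = se
        self.pvalues_ = 2 * stats.norm.sf(np.abs(z))
        self.loglik_ = float(ll)
        self.n_iter_ = it
        self.converged_ = converged
        self.n_sets_ = len(Xs)
        return self

    @staticmethod
    def _loglik(Xs, beta) -> float:
        ll = 0.0
        for x in Xs:
            eta = x @ beta
            m = eta.max()
            ll += eta[0] - (m + np.log(np.exp(eta - m).sum()))
        return float(ll)

    @staticmethod
    def _score_hess(Xs, beta):
        q = len(beta)
        g = np.zeros(q)
        H = np.zeros((q, q))
        for x in Xs:
            eta = x @ beta
            w = np.exp(eta - eta.max())
            w /= w.sum()
            xbar = w @ x
            g += x[0] - xbar
            H -= (x.T * w) @ x - np.outer(xbar, xbar)
        return g, H


def fit_clogit(sets: list[MatchedSet], max_iter: int = 50,
               tol: float = 1e-10) -> dict:
    """Functional wrapper: returns beta, se, p, loglik, converged."""
    est = ConditionalLogit(max_iter=max_iter, tol=tol).fit(sets)
    return {"beta": est.coef_, "se": est.se_, "p": est.pvalues_,
            "loglik": est.loglik_, "converged": est.converged_,
            "separated": est.separated_, "n_sets": est.n_sets_}


# ---------------------------------------------------------------------------
# covariate preparation and the per-protein screen
# ---------------------------------------------------------------------------

def _model_frame(samples: pd.DataFrame) -> pd.DataFrame:
    """Numeric covariate frame for the three models (NaN where missing)."""
    df = pd.DataFrame(index=samples.index)
    df["bmi"] = samples["bmi"].astype(float)
    df["entry_date"] = samples["entry_date"].astype(float)
    df["dense_area"] = samples["dense_area"].astype(float)
    df["postmenopausal"] = samples["menopausal"].map(
        {"post": 1.0, "pre": 0.0}).astype(float)
    df["mht_ever"] = samples["mht_status"].map(
        {"never": 0.0, "before": 1.0, "current": 1.0}).astype(float)
    df["smoking"] = samples["smoking"].astype(float)
    df["alcohol"] = samples["alcohol"].astype(float)
    df["parity_ever"] = samples["parity"].map(
        {"never": 0.0, "ever": 1.0}).astype(float)
    return df


def build_matched_sets(samples: pd.DataFrame, exposure: pd.DataFrame,
                       covariates: list[str]) -> list[MatchedSet]:
    """Assemble matched sets from an annotation table.

    ``exposure`` holds the per-sample exposure column(s) (e.g. one
    protein's log level); ``covariates`` names columns of the model
    frame to append. Sets with any missing value in any member are
    dropped whole.
    """
    mf = _model_frame(samples)
    study = samples[samples["role"] == "study"]
    sets: list[MatchedSet] = []
    for sid, grp in study.groupby("match_set_id", sort=True):
        cases = grp.index[grp["case_status"] == "case"]
        ctls = grp.index[grp["case_status"] == "control"]
        if len(cases) != 1 or len(ctls) < 1:
            continue
        order = list(cases) + list(ctls)
        x = pd.concat([exposure.loc[order], mf.loc[order, covariates]], axis=1)
        if x.isna().any().any():
            continue
        sets.append(MatchedSet(set_id=str(sid), X=x.to_numpy(float),
                               members=order))
    return sets


def screen_proteins_clogit(matrix, samples: pd.DataFrame,
                           models=(1, 2, 3), standardize: bool = True,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Per-protein, per-model conditional logistic screen with BH FDR.

    ``matrix`` is a QC-filtered MFIMatrix (logged internally) or a
    DataFrame of log levels. Returns one row per protein x model with
    beta, se, p, fdr; per-protein failures are recorded, not raised.
    """
    models = list(models)
    if not models:
        raise ValueError("empty model list")
    from .containers import MFIMatrix
    vals = matrix.log() if isinstance(matrix, MFIMatrix) else pd.DataFrame(matrix)
    vals = vals.loc[vals.index.intersection(samples.index)]
    if standardize:
        vals = (vals - vals.mean()) / vals.std(ddof=1)
    rows = []
    for model_id in models:
        covs = MODEL_COVARIATES[model_id]
        # prebuild per-set member orders once per model
        proto = build_matched_sets(samples.loc[vals.index],
                                   vals.iloc[:, [0]], covs)
        member_order = [s.members for s in proto]
        mf = _model_frame(samples)
        for prot in vals.columns:
            pvec = vals[prot]
            sets = []
            for mem, base in zip(member_order, proto):
                x = np.column_stack([pvec.loc[mem].to_numpy(), base.X[:, 1:]])
                sets.append(MatchedSet(set_id=base.set_id, X=x, members=mem))
            try:
                res = fit_clogit(sets)
                rows.append({"antibody": prot, "model": model_id,
                             "beta": res["beta"][0], "se": res["se"][0],
                             "p": res["p"][0], "n_sets": res["n_sets"],
                             "failed": bool(res["separated"])})
            except Exception as exc:  # aggregate, never abort the screen
                rows.append({"antibody": prot, "model": model_id,
                             "beta": np.nan, "se": np.nan, "p": np.nan,
                             "n_sets": len(sets), "failed": True,
                             "error": str(exc)})
    out = pd.DataFrame(rows)
    out["fdr"] = np.nan
    for model_id in models:
        sel = (out["model"] == model_id) & out["p"].notna()
        if sel.any():
            out.loc[sel, "fdr"] = multipletests(out.loc[sel, "p"],
                                                method="fdr_bh")[1]
    out["nominal"] = out["p"] < alpha
    out["fdr_significant"] = out["fdr"] < alpha
    return out
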