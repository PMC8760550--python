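"""Cluster characterization: clinical contrasts, differential abundance,
shortlisting and trait association.

Clinical variables are contrasted across clusters with Wilcoxon rank-sum
tests (continuous) and Fisher's exact test (categorical); the Fisher
test handles general r x c tables by exact enumeration over all tables
with the observed margins when that is feasible and by seeded Monte
Carlo over fixed-margin tables otherwise. Proteins driving a cluster
are ranked by Welch t-tests against the remaining samples with
Benjamini-Hochberg correction, shortlisted as the union of the
lowest-p and largest-shift proteins per direction, and the shortlist is
associated with mammographic dense area (linear model on BMI/age-
adjusted density) and MHT status (logistic model on ever-use).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.api import Logit, MNLogit, OLS, add_constant
from statsmodels.stats.multitest import multipletests

from .containers import DifferentialResult, MFIMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "fisher_exact_rxc",
    "FisherResult",
    "cluster_clinical_tests",
    "differential_abundance",
    "shortlist",
    "median_fold_change",
    "trait_association",
    "ClinicalComparison",
]


# ---------------------------------------------------------------------------
# Fisher exact test for r x c tables
# ---------------------------------------------------------------------------

@dataclass
class FisherResult:
    p: float
    method: str  # "exact" | "montecarlo"
    mc_se: float | None = None
    mc_draws: int | None = None

    def __float__(self) -> float:
        return float(self.p)


def _log_table_prob(table: np.ndarray, lg_margin: float) -> float:
    return lg_margin - gammaln(table + 1.0).sum()


def fisher_exact_rxc(table, method: str = "auto", mc_draws: int = 1_000_000,
                     seed: int | None = None,
                     max_exact_tables: float = 1e7) -> FisherResult:
    """Two-sided Fisher exact test for an r x c contingency table.

    The two-sided p-value sums the conditional (multivariate
    hypergeometric) probabilities of all fixed-margin tables no more
    probable than the observed one. Exact enumeration runs when the
    table-count bound is below ``max_exact_tables``; otherwise (or when
    ``method='montecarlo'``) fixed-margin tables are sampled with
    ``scipy.stats.random_table`` and the p-value is the add-one
    frequency estimate.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2 x 2")
    if np.any(t < 0):
        raise ValueError("table entries must be non-negative integers")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero-margin row or column")
    n = int(t.sum())
    lg_margin = (gammaln(rows + 1.0).sum() + gammaln(cols + 1.0).sum()
                 - gammaln(n + 1.0))
    log_p_obs = _log_table_prob(t, lg_margin)
    tol = 1e-7

    bound = 1.0
    for i in range(t.shape[0] - 1):
        for j in range(t.shape[1] - 1):
            bound *= min(rows[i], cols[j]) + 1
    use_exact = method == "exact" or (method == "auto" and bound <= max_exact_tables)
    if method not in ("auto", "exact", "montecarlo"):
        raise ValueError(f"unknown method {method!r}")

    if use_exact:
        total = _enumerate_pvalue(rows, cols, lg_margin, log_p_obs, tol)
        return FisherResult(p=min(total, 1.0), method="exact")

    rng = np.random.default_rng(seed)
    dist = stats.random_table(rows, cols)
    hits = 0
    done = 0
    chunk = 100_000
    while done < mc_draws:
        m = min(chunk, mc_draws - done)
        draws = dist.rvs(m, method="patefield", random_state=rng)
        lp = lg_margin - gammaln(draws + 1.0).sum(axis=(1, 2))
        hits += int((lp <= log_p_obs + tol).sum())
        done += m
    p = (hits + 1) / (mc_draws + 1)
    se = np.sqrt(p * (1 - p) / mc_draws)
    return FisherResult(p=float(p), method="montecarlo", mc_se=float(se),
                        mc_draws=mc_draws)


def _enumerate_pvalue(rows, cols, lg_margin, log_p_obs, tol) -> float:
    """Depth-first enumeration of all fixed-margin tables, accumulating
    the probability of those with log-probability <= observed."""
    r, c = len(rows), len(cols)
    lgam = gammaln(np.arange(int(rows.sum()) + 2) + 0.0 + 1.0)  # lgamma(x+1)
    total = 0.0
    cell_lg = np.zeros(r * c + 1)

    def rec(i, j, colrem, rowrem_i, acc):
        nonlocal total
        if i == r - 1:
            # last row fully determined by column remainders
            if np.any(colrem < 0):
                return
            lp = acc - lgam[colrem].sum()
            if lp <= log_p_obs + tol:
                total += np.exp(lp)
            return
        if j == c - 1:
            x = rowrem_i
            if x < 0 or x > colrem[j]:
                return
            colrem2 = colrem.copy()
            colrem2[j] -= x
            rec(i + 1, 0, colrem2, rows[i + 1], acc - lgam[x])
            return
        tail = colrem[j + 1:].sum()
        lo = max(0, rowrem_i - tail)
        hi = min(rowrem_i, colrem[j])
        for x in range(lo, hi + 1):
            colrem2 = colrem.copy()
            colrem2[j] -= x
            rec(i, j + 1, colrem2, rowrem_i - x, acc - lgam[x])

    rec(0, 0, cols.copy(), rows[0], lg_margin)
    return total


# ---------------------------------------------------------------------------
# clinical contrasts
# ---------------------------------------------------------------------------

@dataclass
class ClinicalComparison:
    variable: str
    test: str  # "wilcoxon" | "fisher"
    scope: str  # "cluster_vs_rest" | "pairwise" | "overall"
    groups: tuple
    p: float
    detail: object = None  # contingency table or group medians


def _is_categorical(series: pd.Series) -> bool:
    return series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype)


def cluster_clinical_tests(annotations: pd.DataFrame, labels: pd.Series,
                           variables, mc_seed: int = 0) -> list[ClinicalComparison]:
    """Contrast each variable across clusters.

    Continuous variables: Wilcoxon rank-sum, cluster-vs-rest and all
    cluster pairs. Categorical: Fisher's exact test on the
    cross-tabulation (overall, cluster-vs-rest and all pairs), with
    missing values ('missing' or NaN) excluded. All p two-sided.
    """
    labels = labels.loc[labels.index.intersection(annotations.index)]
    ann = annotations.loc[labels.index]
    clusters = sorted(labels.unique())
    out: list[ClinicalComparison] = []
    for var in variables:
        col = ann[var]
        if _is_categorical(col):
            valid = col.notna() & (col != "missing")
            v, lab = col[valid], labels[valid]
            cats = sorted(v.unique())
            if len(cats) < 2:
                raise ValueError(f"variable {var} has fewer than 2 observed categories")
            tab = pd.crosstab(v, lab)
            res = fisher_exact_rxc(tab.to_numpy(), seed=mc_seed)
            out.append(ClinicalComparison(var, "fisher", "overall",
                                          tuple(clusters), float(res), tab))
            for c in clusters:
                t2 = np.column_stack([
                    [int(((v == cat) & (lab == c)).sum()) for cat in cats],
                    [int(((v == cat) & (lab != c)).sum()) for cat in cats]])
                t2 = t2[t2.sum(axis=1) > 0]
                if t2.shape[0] >= 2 and (t2.sum(axis=0) > 0).all():
                    res = fisher_exact_rxc(t2, seed=mc_seed)
                    out.append(ClinicalComparison(var, "fisher", "cluster_vs_rest",
                                                  (c,), float(res), t2))
            for i, c1 in enumerate(clusters):
                for c2 in clusters[i + 1:]:
                    t2 = np.column_stack([
                        [int(((v == cat) & (lab == c1)).sum()) for cat in cats],
                        [int(((v == cat) & (lab == c2)).sum()) for cat in cats]])
                    t2 = t2[t2.sum(axis=1) > 0]
                    if t2.shape[0] >= 2 and (t2.sum(axis=0) > 0).all():
                        res = fisher_exact_rxc(t2, seed=mc_seed)
                        out.append(ClinicalComparison(var, "fisher", "pairwise",
                                                      (c1, c2), float(res), t2))
        else:
            v = col.astype(float)
            valid = v.notna()
            v, lab = v[valid], labels[valid]
            for c in clusters:
                a, b = v[lab == c], v[lab != c]
                if len(a) and len(b):
                    p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
                    out.append(ClinicalComparison(var, "wilcoxon", "cluster_vs_rest",
                                                  (c,), float(p),
                                                  (float(a.median()), float(b.median()))))
            for i, c1 in enumerate(clusters):
                for c2 in clusters[i + 1:]:
                    a, b = v[lab == c1], v[lab == c2]
                    if len(a) and len(b):
                        p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
                        out.append(ClinicalComparison(var, "wilcoxon", "pairwise",
                                                      (c1, c2), float(p),
                                                      (float(a.median()), float(b.median()))))
    return out


# ---------------------------------------------------------------------------
# differential abundance
# ---------------------------------------------------------------------------

def _log_values(X) -> pd.DataFrame:
    if isinstance(X, MFIMatrix):
        return X.log()
    return pd.DataFrame(X)


def differential_abundance(X, labels: pd.Series, cluster_id,
                           raw=None) -> DifferentialResult:
    """Welch t-test per antibody, cluster vs all other samples, with BH
    correction across antibodies.

    ``X`` is the adjusted matrix used for the tests (MFIMatrix: logged
    internally; DataFrame: used as-is). ``raw`` (linear scale, default:
    linear values of ``X``) feeds the signed median fold change.
    """
    vals = _log_values(X)
    labels = labels.loc[vals.index]
    in_cluster = (labels == cluster_id).to_numpy()
    n1, n0 = int(in_cluster.sum()), int((~in_cluster).sum())
    if n1 < 3 or n0 < 3:
        raise ValueError("cluster and rest each need >= 3 samples")
    a = vals.to_numpy()[in_cluster]
    b = vals.to_numpy()[~in_cluster]
    tt = stats.ttest_ind(a, b, axis=0, equal_var=False)
    mean_diff = a.mean(axis=0) - b.mean(axis=0)
    pvals = np.asarray(tt.pvalue)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    lin = raw if raw is not None else (
        X.values if isinstance(X, MFIMatrix) else np.exp(vals))
    lin = pd.DataFrame(lin).loc[vals.index, vals.columns]
    fc = median_fold_change(lin, labels, cluster_id)
    table = pd.DataFrame({
        "mean_diff": mean_diff,
        "t_stat": np.asarray(tt.statistic),
        "p": pvals,
        "fdr": fdr,
        "fc_signed": fc.to_numpy(),
        "direction": np.where(mean_diff > 0, "higher_in_cluster",
                              "lower_in_cluster"),
    }, index=vals.columns)
    return DifferentialResult(table=table, cluster_id=cluster_id,
                              n_cluster=n1, n_rest=n0)


def median_fold_change(X, labels: pd.Series, cluster_id) -> pd.Series:
    """Signed linear-scale median fold change, cluster vs rest: the ratio
    of medians r when r >= 1, else -1/r."""
    vals = X.values if isinstance(X, MFIMatrix) else pd.DataFrame(X)
    labels = labels.loc[vals.index]
    in_cluster = (labels == cluster_id).to_numpy()
    med1 = np.median(vals.to_numpy()[in_cluster], axis=0)
    med0 = np.median(vals.to_numpy()[~in_cluster], axis=0)
    if np.any(med1 <= 0) or np.any(med0 <= 0):
        raise ValueError("median fold change needs positive linear-scale values")
    r = med1 / med0
    return pd.Series(np.where(r >= 1, r, -1.0 / r), index=vals.columns,
                     name="fc_signed")


def shortlist(result: DifferentialResult, m: int = 25) -> dict:
    """Per direction, the union of the m lowest-p and the m largest-|shift|
    antibodies; each set has between m and 2m members (all, with a
    warning, if a direction holds fewer than m)."""
    out = {}
    for direction, key in (("higher_in_cluster", "higher"),
                           ("lower_in_cluster", "lower")):
        sub = result.table[result.table["direction"] == direction]
        if len(sub) < m:
            logger.warning("direction %s has only %d antibodies (< m=%d); "
                           "taking all", direction, len(sub), m)
            out[key] = set(sub.index)
            continue
        by_p = set(sub.nsmallest(m, "p").index)
        by_diff = set(sub.reindex(sub["mean_diff"].abs()
                                  .nlargest(m).index).index)
        out[key] = by_p | by_diff
    return out


# ---------------------------------------------------------------------------
# trait association of shortlisted proteins
# ---------------------------------------------------------------------------

def trait_association(X, shortlisted, annotations: pd.DataFrame,
                      mht_coding: str = "ever") -> pd.DataFrame:
    """Associate each shortlisted protein with mammographic dense area and
    MHT status.

    Dense area is first adjusted for BMI and age (OLS residual), then
    regressed on the (z-scored) log protein level. MHT enters a logistic
    model of ever-use (before or current vs never; ``mht_coding=
    'three_level'`` fits a multinomial instead). Proteins with complete
    separation are skipped with a warning.
    """
    vals = _log_values(X)
    ann = annotations.loc[vals.index]
    rows = []
    # BMI/age-adjusted dense area on the samples where all three exist
    da = ann[["dense_area", "bmi", "age"]].astype(float)
    da_ok = da.notna().all(axis=1)
    if not da_ok.any():
        raise ValueError("dense area / BMI / age all missing")
    D = add_constant(da.loc[da_ok, ["bmi", "age"]])
    da_fit = OLS(da.loc[da_ok, "dense_area"], D).fit()
    adj_dense = da_fit.resid

    mht = ann["mht_status"]
    mht_ok = mht.isin(["never", "before", "current"])
    if not mht_ok.any():
        raise ValueError("MHT status entirely missing")
    ever = mht[mht_ok].isin(["before", "current"]).astype(int)

    for prot in shortlisted:
        z = vals[prot]
        z = (z - z.mean()) / z.std(ddof=1)
        # linear: adjusted dense area ~ protein
        zz = z.loc[adj_dense.index]
        lin = OLS(adj_dense, add_constant(zz)).fit()
        slope, slope_p = lin.params.iloc[1], lin.pvalues.iloc[1]
        # logistic: MHT ever ~ protein
        lo_beta = lo_p = np.nan
        skipped = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if mht_coding == "three_level":
                    mod = MNLogit(pd.Categorical(mht[mht_ok],
                                                 categories=["never", "before", "current"]).codes,
                                  add_constant(z.loc[mht[mht_ok].index])).fit(disp=0)
                    lo_beta = float(mod.params.iloc[1, 0])
                    lo_p = float(mod.pvalues.iloc[1, 0])
                else:
                    mod = Logit(ever, add_constant(z.loc[ever.index])).fit(disp=0)
                    lo_beta = float(mod.params.iloc[1])
                    lo_p = float(mod.pvalues.iloc[1])
                if not np.isfinite(lo_p) or abs(lo_beta) > 50:
                    raise np.linalg.LinAlgError("separation")
        except Exception:
            logger.warning("logistic model failed (separation?) for %s; skipped", prot)
            skipped = True
        rows.append({
            "antibody": prot,
            "dense_slope": float(slope),
            "dense_p": float(slope_p),
            "mht_logodds": lo_beta,
            "mht_p": lo_p,
            "mht_skipped": skipped,
            "dense_sig": bool(slope_p < 0.05),
            "mht_sig": bool(lo_p < 0.05) if np.isfinite(lo_p) else False,
        })
    return pd.DataFrame(rows).set_index("antibody")
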