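"""Bootstrap cluster stability (mean Jaccard index) and pair concordance.

Stability: the clustering is repeated on bootstrap resamples (same k);
for every reference cluster the best-matching Jaccard overlap with the
bootstrap clustering — computed on the set of distinct drawn samples,
the clusterboot convention — is recorded, and the mean over repetitions
is the cluster's MJI. Values near 1 mean the cluster survives data
perturbation; a cluster forced onto structureless data scores low.

Concordance: replicate pairs (technical variation only) should land in
the same cluster more often than double pairs (technical + biological
drift), which in turn should beat random sample pairs. Rates are
compared pairwise with Fisher's exact test on the 2x2 same/different
tables (a permutation alternative is available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .archetypes import ArchetypeModel, fit_archetypes, predict_coefficients

__all__ = ["jaccard", "bootstrap_mji", "pair_concordance",
           "StabilityResult", "ConcordanceResult"]


def jaccard(a, b) -> float:
    """|A ∩ B| / |A ∪ B|; 0.0 when both sets are empty (convention)."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


@dataclass
class StabilityResult:
    mji_mean: np.ndarray  # per reference cluster
    mji_sd: np.ndarray
    B: int
    per_repetition: np.ndarray  # (B, k) matched Jaccard values


def bootstrap_mji(X, reference: ArchetypeModel, B: int = 150,
                  seed: int | None = None, max_iter: int = 100,
                  tol: float = 1e-5, restarts: int = 2,
                  max_fit_attempts: int = 3,
                  jaccard_on: str = "distinct") -> StabilityResult:
    """Mean Jaccard stability of each reference cluster over B bootstrap
    re-clusterings of X (resampled rows, same k).

    ``jaccard_on='distinct'`` (default, clusterboot convention) scores
    overlaps on the set of distinct drawn samples; ``'all'`` predicts
    bootstrap labels for every sample and scores overlaps on the full
    sample set.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if jaccard_on not in ("distinct", "all"):
        raise ValueError("jaccard_on must be 'distinct' or 'all'")
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    k = reference.k
    ref_labels = np.argmax(reference.alpha, axis=1)
    rng = np.random.default_rng(seed)
    per_rep = np.empty((B, k))
    for b in range(B):
        draw = rng.integers(0, n, n)
        distinct = np.unique(draw)
        model = None
        for attempt in range(max_fit_attempts):
            try:
                model = fit_archetypes(X[draw], k, max_iter=max_iter, tol=tol,
                                       restarts=restarts,
                                       seed=int(rng.integers(2 ** 31)))
                break
            except Exception:
                continue
        if model is None:
            raise RuntimeError(f"bootstrap fit failed after {max_fit_attempts} attempts")
        scored = distinct if jaccard_on == "distinct" else np.arange(n)
        boot_labels = np.argmax(predict_coefficients(model, X[scored]), axis=1)
        ref_on_scored = ref_labels[scored]
        for c in range(k):
            ref_set = scored[ref_on_scored == c]
            best = 0.0
            for c2 in range(k):
                boot_set = scored[boot_labels == c2]
                best = max(best, jaccard(ref_set, boot_set))
            per_rep[b, c] = best
    return StabilityResult(mji_mean=per_rep.mean(axis=0),
                           mji_sd=per_rep.std(axis=0, ddof=1),
                           B=B, per_repetition=per_rep)


@dataclass
class ConcordanceResult:
    counts: pd.DataFrame  # per pair type: n_pairs, n_same, rate
    pvalues: pd.DataFrame  # pairwise Fisher (or permutation) p


def _same_cluster(labels: pd.Series, pairs) -> np.ndarray:
    return np.array([labels[a] == labels[b] for a, b in pairs], dtype=bool)


def pair_concordance(labels: pd.Series, replicate_pairs, double_pairs,
                     n_random_pairs: int = 100, seed: int | None = None,
                     study_ids=None, method: str = "fisher",
                     n_permutations: int = 10000) -> ConcordanceResult:
    """Same-cluster rates for replicate, double and random pairs with
    pairwise two-sided significance tests.

    ``labels`` maps sample id -> cluster label (replicates and doubles
    via predicted coefficients). Random pairs are drawn without
    replacement among ``study_ids`` (default: all labelled samples not
    in a replicate/double pair).
    """
    if not len(replicate_pairs) or not len(double_pairs):
        raise ValueError("replicate and double pair lists must be non-empty")
    rng = np.random.default_rng(seed)
    if study_ids is None:
        in_pairs = {s for p in (*replicate_pairs, *double_pairs) for s in p}
        study_ids = [s for s in labels.index if s not in in_pairs]
    study_ids = list(study_ids)
    if len(study_ids) < 2 * n_random_pairs:
        n_random_pairs = len(study_ids) // 2
    perm = rng.permutation(study_ids)
    random_pairs = [(perm[2 * i], perm[2 * i + 1]) for i in range(n_random_pairs)]

    same = {
        "replicate": _same_cluster(labels, replicate_pairs),
        "double": _same_cluster(labels, double_pairs),
        "random": _same_cluster(labels, random_pairs),
    }
    counts = pd.DataFrame({
        t: {"n_pairs": len(v), "n_same": int(v.sum()),
            "rate": float(v.mean()) if len(v) else np.nan}
        for t, v in same.items()
    }).T
    types = list(same)
    pv = pd.DataFrame(np.nan, index=types, columns=types)
    for i, a in enumerate(types):
        for b in types[i + 1:]:
            table = [[int(same[a].sum()), int((~same[a]).sum())],
                     [int(same[b].sum()), int((~same[b]).sum())]]
            if method == "fisher":
                p = fisher_exact(table, alternative="two-sided")[1]
            elif method == "permutation":
                p = _perm_rate_test(same[a], same[b], rng, n_permutations)
            else:
                raise ValueError(f"unknown method {method!r}")
            pv.loc[a, b] = pv.loc[b, a] = p
    return ConcordanceResult(counts=counts, pvalues=pv)


def _perm_rate_test(x: np.ndarray, y: np.ndarray, rng, n_perm: int) -> float:
    obs = abs(x.mean() - y.mean())
    pooled = np.concatenate([x, y])
    nx = len(x)
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        if abs(pooled[:nx].mean() - pooled[nx:].mean()) >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)
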