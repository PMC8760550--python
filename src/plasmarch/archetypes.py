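"""Archetypal analysis: X ~ alpha . Z with Z = beta . X and the rows of
alpha and beta constrained to the probability simplex.

Archetypes are extreme points of the data's convex hull; every sample is
expressed as a convex combination of them, so the coefficient row alpha_i
reads as a membership probability vector. Fitting alternates two blocks
of simplex-constrained least squares (Cutler-Breiman):

1. given Z, each alpha row solves  min ||Z^T a - x_i||,  a in simplex;
2. given alpha, the unconstrained archetype update Z~ = argmin ||X - alpha Z||
   is projected back onto the hull by solving each beta row
   min ||X^T b - z~_a||, b in simplex, and setting Z = beta X.

The simplex constraint is enforced by non-negative least squares on an
augmented system carrying a heavily weighted sum-to-one row. The number
of archetypes is chosen by the unit-invariant knee of the (k, RSS)
curve; hard cluster labels are the argmax of alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ArchetypalAnalysis",
    "ArchetypeModel",
    "fit_archetypes",
    "select_k",
    "assign",
    "predict_coefficients",
    "knee_point",
    "simplex_lstsq",
]

_PENALTY_FACTOR = 200.0


def simplex_lstsq(A: np.ndarray, B: np.ndarray, penalty: float | None = None) -> np.ndarray:
    """Solve min ||A w - b||^2 s.t. w >= 0, sum(w) = 1 for each column b of B.

    The sum-to-one constraint is imposed through an augmented row with a
    large weight (default ``200 * max(|A|, 1)``), after which plain NNLS
    applies — the standard Cutler-Breiman device.

    Parameters
    ----------
    A : (m, q) array
    B : (m, n_rhs) or (m,) array

    Returns
    -------
    (q, n_rhs) or (q,) array of simplex weights.
    """
    B2 = B[:, None] if B.ndim == 1 else B
    m, q = A.shape
    if penalty is None:
        penalty = _PENALTY_FACTOR * max(1.0, float(np.abs(A).max()))
    aug = np.vstack([A, np.full((1, q), penalty)])
    out = np.empty((q, B2.shape[1]))
    rhs = np.empty(m + 1)
    rhs[m] = penalty
    for j in range(B2.shape[1]):
        rhs[:m] = B2[:, j]
        w, _ = nnls(aug, rhs)
        s = w.sum()
        out[:, j] = w / s if s > 0 else np.full(q, 1.0 / q)
    return out[:, 0] if B.ndim == 1 else out


def _coefficients(X: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Simplex-constrained coefficients of every row of X against the
    archetype rows Z: returns alpha (n, k)."""
    return simplex_lstsq(Z.T, X.T).T


def _furthest_sum(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Furthest-sum selection of k well-spread data rows (init heuristic)."""
    n = X.shape[0]
    sel = [int(rng.integers(n))]
    norms = (X ** 2).sum(axis=1)
    dist_sum = np.zeros(n)
    for _ in range(1, k):
        last = sel[-1]
        d = np.sqrt(np.maximum(norms + norms[last] - 2 * X @ X[last], 0.0))
        dist_sum += d
        cand = np.ma.array(dist_sum, mask=np.zeros(n, bool))
        cand.mask[sel] = True
        sel.append(int(np.argmax(cand)))
    # replace the arbitrary first pick by the row furthest from the rest
    if k > 1:
        d0 = np.zeros(n)
        for s in sel[1:]:
            d0 += np.sqrt(np.maximum(norms + norms[s] - 2 * X @ X[s], 0.0))
        d0[sel[1:]] = -np.inf
        sel[0] = int(np.argmax(d0))
    return X[np.unique(sel)[:k]] if len(set(sel)) >= k else X[rng.choice(n, k, replace=False)]


@dataclass
class ArchetypeModel:
    """Fitted archetypal decomposition (plain-data form, JSON-friendly)."""

    k: int
    Z: np.ndarray  # (k, p) archetypes
    alpha: np.ndarray  # (n, k) sample coefficients, simplex rows
    beta: np.ndarray  # (k, n) generator weights, simplex rows
    rss: float
    n_iter: int
    converged: bool
    seed: int | None = None
    restarts: int = 1
    rss_history: list = field(default_factory=list)


class ArchetypalAnalysis(TransformerMixin, BaseEstimator):
    """Archetypal analysis as an sklearn-style estimator.

    Parameters
    ----------
    n_archetypes : int
        Number of archetypes k (1 <= k < n_samples).
    max_iter : int, default=200
        Maximum alternating iterations per restart.
    tol : float, default=1e-6
        Relative RSS decrease below which iteration stops.
    n_restarts : int, default=5
        Random initializations (furthest-sum from seeded random starts);
        the best final RSS wins.
    random_state : int or None
        Seed for initialization.

    Attributes
    ----------
    archetypes_ : (k, p) ndarray — the matrix Z in log-MFI units.
    alpha_ : (n, k) ndarray — training coefficients, rows on the simplex.
    beta_ : (k, n) ndarray — generator weights, rows on the simplex.
    rss_ : float — residual sum of squares ||X - alpha Z||^2.
    n_iter_, converged_, rss_history_
    """

    def __init__(self, n_archetypes: int = 5, max_iter: int = 200,
                 tol: float = 1e-6, n_restarts: int = 5,
                 random_state: int | None = None):
        self.n_archetypes = n_archetypes
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.random_state = random_state

    # -- fitting ---------------------------------------------------------
    def fit(self, X, y=None, init_Z: np.ndarray | None = None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        n, p = X.shape
        k = self.n_archetypes
        if not 1 <= k < n:
            raise ValueError(f"need 1 <= n_archetypes < n_samples, got k={k}, n={n}")
        rng = np.random.default_rng(self.random_state)
        best = None
        starts: list[np.ndarray | None] = []
        if init_Z is not None:
            starts.append(np.asarray(init_Z, dtype=float))
        starts.extend([None] * self.n_restarts)
        for Z0 in starts:
            if Z0 is None:
                Z0 = _furthest_sum(X, k, rng)
            res = self._fit_once(X, Z0)
            if best is None or res["rss"] < best["rss"]:
                best = res
        self.archetypes_ = best["Z"]
        self.alpha_ = best["alpha"]
        self.beta_ = best["beta"]
        self.rss_ = best["rss"]
        self.n_iter_ = best["n_iter"]
        self.converged_ = best["converged"]
        self.rss_history_ = best["history"]
        self.n_features_in_ = p
        return self

    def _fit_once(self, X: np.ndarray, Z0: np.ndarray) -> dict:
        n, p = X.shape
        k = self.n_archetypes
        Z = Z0.copy()
        if k == 1:
            # closed form: the best single archetype inside the hull is the mean
            alpha = np.ones((n, 1))
            beta = np.full((1, n), 1.0 / n)
            Z = beta @ X
            rss = float(((X - alpha @ Z) ** 2).sum())
            return dict(Z=Z, alpha=alpha, beta=beta, rss=rss, n_iter=0,
                        converged=True, history=[rss])
        history = []
        rss_prev = np.inf
        alpha = beta = None
        prev_state = None
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            alpha = _coefficients(X, Z)
            # unconstrained archetype update, then hull projection
            Zt, *_ = np.linalg.lstsq(alpha, X, rcond=None)
            beta_new = simplex_lstsq(X.T, Zt.T).T
            Z_new = beta_new @ X
            rss = float(((X - alpha @ Z_new) ** 2).sum())
            if rss > rss_prev * (1 + 1e-9):
                # the hull-projection step is a heuristic and can tick RSS
                # up near the optimum; revert and stop at the last
                # accepted state
                Z, beta, rss = prev_state
                converged = True
                break
            prev_state = (Z_new, beta_new, rss)
            Z, beta = Z_new, beta_new
            history.append(rss)
            if np.isfinite(rss_prev) and rss_prev - rss <= self.tol * max(rss_prev, 1e-12):
                converged = True
                rss_prev = rss
                break
            rss_prev = rss
        # final coefficient refresh against the accepted archetypes (this
        # is an exact block minimization, so RSS can only go down)
        alpha = _coefficients(X, Z)
        rss = float(((X - alpha @ Z) ** 2).sum())
        history.append(rss)
        return dict(Z=Z, alpha=alpha, beta=beta, rss=rss, n_iter=it,
                    converged=converged, history=history)

    # -- inference -------------------------------------------------------
    def transform(self, X) -> np.ndarray:
        """Simplex coefficients of (possibly new) samples against the
        fitted archetypes."""
        check_is_fitted(self, "archetypes_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.archetypes_.shape[1]:
            raise ValueError("feature dimension mismatch")
        return _coefficients(X, self.archetypes_)

    def predict(self, X) -> np.ndarray:
        """Hard cluster labels in 1..k (argmax coefficient; ties to the
        lowest archetype index)."""
        return np.argmax(self.transform(X), axis=1) + 1

    def labels_from_alpha(self) -> np.ndarray:
        check_is_fitted(self, "alpha_")
        return np.argmax(self.alpha_, axis=1) + 1

    def to_model(self) -> ArchetypeModel:
        check_is_fitted(self, "archetypes_")
        return ArchetypeModel(
            k=self.n_archetypes, Z=self.archetypes_, alpha=self.alpha_,
            beta=self.beta_, rss=self.rss_, n_iter=self.n_iter_,
            converged=self.converged_, seed=self.random_state,
            restarts=self.n_restarts, rss_history=list(self.rss_history_))


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_archetypes(X, k: int, max_iter: int = 200, tol: float = 1e-6,
                   restarts: int = 5, seed: int | None = None,
                   init_Z: np.ndarray | None = None) -> ArchetypeModel:
    est = ArchetypalAnalysis(n_archetypes=k, max_iter=max_iter, tol=tol,
                             n_restarts=restarts, random_state=seed)
    est.fit(X, init_Z=init_Z)
    return est.to_model()


def predict_coefficients(model: ArchetypeModel, X_new) -> np.ndarray:
    """Simplex coefficients of new samples against fixed archetypes."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.shape[1] != model.Z.shape[1]:
        raise ValueError("feature dimension mismatch")
    return _coefficients(X_new, model.Z)


def assign(model: ArchetypeModel) -> np.ndarray:
    """Hard labels 1..k from the training coefficients (argmax per row,
    ties broken toward the lowest archetype index)."""
    return np.argmax(model.alpha, axis=1) + 1


def knee_point(ks, values) -> int:
    """Unit-invariant knee: scale both axes to [0, 1] and take the point
    of maximum perpendicular distance from the chord joining the curve's
    endpoints. Ties (and the degenerate all-zero case) resolve to the
    smallest interior k."""
    ks = np.asarray(ks, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(ks) < 3:
        raise ValueError("need at least 3 points to locate a knee")
    x = (ks - ks[0]) / (ks[-1] - ks[0])
    rng = v[0] - v[-1]
    y = (v - v[-1]) / rng if rng != 0 else np.zeros_like(v)
    # distance from chord (x0,y0)-(x1,y1); endpoints excluded
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    dist = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / np.hypot(dx, dy)
    interior = slice(1, len(ks) - 1)
    i = 1 + int(np.argmax(np.round(dist[interior], 12)))
    return int(ks[i])


def select_k(X, k_range=range(2, 11), max_iter: int = 200, tol: float = 1e-6,
             restarts: int = 5, seed: int | None = None,
             monotone_tol: float = 0.02):
    """Fit every k in ``k_range``, locate the knee of the RSS curve.

    Each k after the first warm-starts one restart from the previous
    solution plus one furthest new data row, which keeps the best-of-
    restarts RSS curve monotone. Raises if the curve still increases by
    more than ``monotone_tol`` (relative).

    Returns
    -------
    (k_opt, curve) where curve is a list of (k, rss, model).
    """
    ks = list(k_range)
    if ks != sorted(ks) or len(set(ks)) != len(ks):
        raise ValueError("k_range must be strictly increasing")
    X = np.asarray(X, dtype=float)
    if ks[-1] >= X.shape[0]:
        raise ValueError("max k must be < n_samples")
    curve = []
    prev_model: ArchetypeModel | None = None
    rng = np.random.default_rng(seed)
    for k in ks:
        init_Z = None
        if prev_model is not None and prev_model.k == k - 1:
            resid = X - _coefficients(X, prev_model.Z) @ prev_model.Z
            worst = int(np.argmax((resid ** 2).sum(axis=1)))
            init_Z = np.vstack([prev_model.Z, X[worst]])
        model = fit_archetypes(X, k, max_iter=max_iter, tol=tol,
                               restarts=restarts,
                               seed=int(rng.integers(2 ** 31)), init_Z=init_Z)
        curve.append((k, model.rss, model))
        prev_model = model
    rss = [c[1] for c in curve]
    for a, b in zip(rss, rss[1:]):
        if b > a * (1 + monotone_tol):
            raise RuntimeError(
                "RSS curve is non-monotone beyond tolerance; refit with more "
                "restarts or a smaller k range")
    k_opt = knee_point(ks, rss)
    return k_opt, curve
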