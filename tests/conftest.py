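import numpy as np
import pandas as pd
import pytest

from plasmarch import MFIMatrix, SimulationConfig, simulate_dataset
from plasmarch.simulate import records_to_frame


@pytest.fixture(scope="session")
def small_dataset():
    """Small but fully featured simulated dataset shared across tests."""
    cfg = SimulationConfig(
        n_cases=40, n_doubles=10, n_replicate_pairs=8, n_antibodies=120,
        n_duplicate_targets=10, n_planted_archetypes=3,
        n_bad_reproducibility=3, n_igg_correlated=3, n_high_background=3,
        seed=11,
    )
    records, matrix, ab, empty, igg, truth = simulate_dataset(cfg)
    return {
        "config": cfg, "records": records,
        "samples": records_to_frame(records), "matrix": matrix,
        "antibodies": ab, "empty": empty, "igg": igg, "truth": truth,
    }


@pytest.fixture
def simple_matrix():
    """Two plates, deterministic values, no structure."""
    rng = np.random.default_rng(0)
    n, p = 24, 30
    vals = pd.DataFrame(
        np.exp(rng.normal(7, 0.5, (n, p))),
        index=[f"S{i:03d}" for i in range(n)],
        columns=[f"AB_{j:03d}" for j in range(p)],
    )
    plates = pd.Series(["plate_1"] * 12 + ["plate_2"] * 12, index=vals.index)
    return MFIMatrix(vals, plates)


# ---------------------------------------------------------------------------
# independent oracles (never imported by the package)
# ---------------------------------------------------------------------------

def project_simplex(v):
    """Euclidean projection onto the probability simplex (Duchi et al.)."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.nonzero(u - css / np.arange(1, len(v) + 1) > 0)[0][-1]
    theta = css[rho] / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


def projected_gradient_archetypes(X, k, Z0, n_outer=60, n_inner=200, seed=0):
    """Independent archetypal-analysis solver: alternating projected
    gradient descent on the simplex for both alpha and beta blocks."""
    X = np.asarray(X, float)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    alpha = rng.dirichlet(np.ones(k), n)
    beta = rng.dirichlet(np.ones(n), k)
    Z = Z0.copy()

    def solve_rows(A, B, W0):
        # min ||W A - B||^2 rows of W on simplex; Lipschitz step
        G = A @ A.T
        L = max(np.linalg.eigvalsh(G).max(), 1e-12)
        W = W0.copy()
        for _ in range(n_inner):
            grad = (W @ G) - B @ A.T
            W_new = np.vstack([project_simplex(w) for w in W - grad / L])
            if np.abs(W_new - W).max() < 1e-10:
                W = W_new
                break
            W = W_new
        return W

    for _ in range(n_outer):
        alpha = solve_rows(Z, X, alpha)          # rows: min ||alpha Z - X||
        Zt = np.linalg.lstsq(alpha, X, rcond=None)[0]
        beta = solve_rows(X, Zt, beta)           # rows: min ||beta X - Ztilde||
        Z = beta @ X
    alpha = solve_rows(Z, X, alpha)
    rss = float(((X - alpha @ Z) ** 2).sum())
    return Z, alpha, rss


def bh_stepup_bruteforce(pvals, alpha=0.05):
    """Literal BH step-up: reject the m smallest p-values where
    m = max{i : p_(i) <= i/n * alpha}; returns adjusted p-values too."""
    p = np.asarray(pvals, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * n / rank)
        adj[i] = prev
    reject = adj <= alpha
    return reject, adj


def hungarian_cosine(A, B, center=None):
    """Mean cosine similarity between rows of A and B after optimal
    one-to-one matching; optional common centering vector."""
    from scipy.optimize import linear_sum_assignment
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    if center is not None:
        A = A - center
        B = B - center
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    cos = (A @ B.T) / np.outer(na, nb)
    r, c = linear_sum_assignment(-cos)
    return float(cos[r, c].mean())
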