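"""Independent reference implementations used to check the package.

These deliberately avoid the code paths they validate: the GLM oracle
maximizes the NB log-likelihood by coordinate-wise grid refinement using
scipy's nbinom pmf (no IRLS), and the motif oracle is a naive per-position
sliding window.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def nb_loglik_scipy(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    r = 1.0 / phi
    return float(stats.nbinom.logpmf(y, r, r / (r + mu)).sum())


def grid_search_nb_fit(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi: float,
    tol: float = 1e-6,
) -> tuple[np.ndarray, float]:
    """Maximize the NB log-likelihood by cyclic coordinate-wise grid
    search with successive grid refinement down to *tol* per coordinate."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    p = X.shape[1]
    beta = np.zeros(p)
    beta[0] = np.log(y.mean() + 0.5) - offset.mean()

    def ll(b: np.ndarray) -> float:
        return nb_loglik_scipy(y, np.exp(offset + X @ b), phi)

    best = ll(beta)
    width = 4.0
    while width > tol:
        improved = True
        while improved:
            improved = False
            for j in range(p):
                grid = beta[j] + np.linspace(-width, width, 17)
                vals = []
                for g in grid:
                    b = beta.copy()
                    b[j] = g
                    vals.append(ll(b))
                k = int(np.argmax(vals))
                if vals[k] > best + 1e-12:
                    beta[j] = grid[k]
                    best = vals[k]
                    improved = True
        width *= 0.25
    return beta, best


def grid_search_lrt(
    y: np.ndarray,
    X_full: np.ndarray,
    X_reduced: np.ndarray,
    offset: np.ndarray,
    phi: float,
) -> float:
    _, ll_full = grid_search_nb_fit(y, X_full, offset, phi)
    _, ll_red = grid_search_nb_fit(y, X_reduced, offset, phi)
    return max(0.0, 2.0 * (ll_full - ll_red))


def naive_motif_scan(seq: str) -> dict[str, list[int]]:
    """Sliding-window enumeration of UGUA singles / twins / restricted
    twins; returns 0-based start positions per kind (DNA or RNA input)."""
    s = seq.upper().replace("U", "T")
    out: dict[str, list[int]] = {"single": [], "twin": [], "twin_restricted": []}
    for i in range(len(s)):
        if s[i : i + 4] == "TGTA":
            out["single"].append(i)
        w = s[i : i + 9]
        if len(w) == 9 and w[0:4] == "TGTA" and w[5:9] == "TGTA":
            out["twin"].append(i)
            if w[4] in "CT":
                out["twin_restricted"].append(i)
    return out
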