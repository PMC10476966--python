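"""Differential PAS-usage statistics.

The pipeline here follows the standard count-based workflow for two-PAS
genes: TMM normalization of per-sample libraries, a common (optionally
tagwise-shrunk) negative-binomial dispersion estimated by Cox-Reid
adjusted profile likelihood, a per-gene GLM likelihood-ratio test of the
condition x PAS-location interaction, Storey/BH q-values, and the joint
significance rule (FDR < alpha and a >fold change of the proximal/distal
usage ratio between conditions).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datamodel import (
    DISTAL,
    PROXIMAL,
    DataError,
    ShiftTest,
    TwoPASTable,
    validate_count_matrix,
)
from .nbglm import check_full_rank, cr_adjusted_loglik, fit_nb_glm, nb_loglik

# ---------------------------------------------------------------------------
# TMM normalization


@dataclass
class NormalizationFactors:
    """Per-sample TMM factors; geometric mean is 1 after rescaling."""

    factors: pd.Series
    library_sizes: pd.Series

    @property
    def effective_library_sizes(self) -> pd.Series:
        return self.library_sizes * self.factors


def tmm_factors(
    counts: pd.DataFrame,
    library_sizes: Optional[pd.Series] = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormalizationFactors:
    """Trimmed mean of M-values normalization factors.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean upper quartile. Rows with a zero in either sample
    are dropped; the most extreme *trim_m* fraction of M values and
    *trim_a* fraction of A values are trimmed on each computation, and the
    remaining M values are averaged with inverse-asymptotic-variance
    weights.
    """
    validate_count_matrix(counts)
    if counts.shape[1] < 2:
        raise DataError("TMM requires at least two samples")
    y = counts.to_numpy(dtype=float)
    if library_sizes is None:
        lib = counts.sum(axis=0).astype(float)
    else:
        lib = library_sizes.reindex(counts.columns).astype(float)
        if lib.isna().any():
            raise DataError("library sizes missing for some samples")
    frac = y / lib.to_numpy()[None, :]
    uq = np.array([np.quantile(frac[:, j][y[:, j] > 0], 0.75) if (y[:, j] > 0).any()
                   else 0.0 for j in range(y.shape[1])])
    ref_j = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(y.shape[1])
    for j in range(y.shape[1]):
        if j == ref_j:
            continue
        factors[j] = _tmm_pair(
            y[:, j], y[:, ref_j], lib.iloc[j], lib.iloc[ref_j], trim_m, trim_a
        )
    log_f = np.log(factors)
    factors = np.exp(log_f - log_f.mean())  # geometric mean 1
    return NormalizationFactors(
        factors=pd.Series(factors, index=counts.columns, name="tmm_factor"),
        library_sizes=lib,
    )


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
    trim_m: float, trim_a: float,
) -> float:
    keep = (obs > 0) & (ref > 0)
    if keep.sum() < 2:
        warnings.warn("fewer than 2 shared nonzero rows; TMM factor set to 1")
        return 1.0
    o, r = obs[keep], ref[keep]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    # double trimming by rank, edgeR-style
    n = len(m)
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - np.floor(n * trim_a)
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    sel = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not sel.any():
        warnings.warn("all rows trimmed; TMM factor set to 1")
        return 1.0
    o, r, m = o[sel], r[sel], m[sel]
    var = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    var = np.maximum(var, 1e-12)
    f = 2.0 ** (np.sum(m / var) / np.sum(1.0 / var))
    if not np.isfinite(f) or f <= 0:
        return 1.0
    return float(f)


# ---------------------------------------------------------------------------
# design matrices


def interaction_design(design_df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Full and reduced design matrices for the 2 x n_samples observations
    of one gene, stacked proximal block first then distal block.

    Columns: intercept, batch contrasts (reference level dropped),
    condition (indicator of the second level), PAS location (1 for
    proximal), and condition x PAS interaction. The reduced model drops
    the interaction column.
    """
    cond_levels = sorted(design_df["condition"].unique())
    if len(cond_levels) != 2:
        raise DataError("exactly two condition levels required")
    cond = (design_df["condition"] == cond_levels[1]).to_numpy(dtype=float)
    batch_levels = sorted(design_df["batch"].unique())
    batch_cols = [
        (design_df["batch"] == b).to_numpy(dtype=float) for b in batch_levels[1:]
    ]
    S = len(design_df)
    ones = np.ones(S)
    per_sample = [ones] + batch_cols + [cond]
    names = ["intercept"] + [f"batch[{b}]" for b in batch_levels[1:]] + ["condition"]

    def stack(cols: list[np.ndarray]) -> np.ndarray:
        top = np.column_stack(cols + [ones, cond])  # proximal block: pas=1
        bot = np.column_stack(cols + [np.zeros(S), np.zeros(S)])  # distal block
        return np.vstack([top, bot])

    X_full = stack(per_sample)
    names_full = names + ["pas", "condition:pas"]
    X_reduced = X_full[:, :-1]
    check_full_rank(X_full, names_full)
    return X_full, X_reduced, names_full


def _gene_vectors(
    counts: pd.DataFrame, design_df: pd.DataFrame
) -> tuple[list[str], np.ndarray]:
    """Split a PAS x sample count matrix into per-gene (y_P, y_D) stacks.

    Rows must be labelled '<gene>|P' and '<gene>|D'.
    """
    samples = list(design_df.index)
    mat = counts[samples].to_numpy(dtype=float)
    ids = list(counts.index)
    by_gene: dict[str, dict[str, int]] = {}
    for i, pid in enumerate(ids):
        if "|" not in pid:
            raise DataError(f"PAS id {pid!r} is not of the form '<gene>|P/D'")
        gene, label = pid.rsplit("|", 1)
        by_gene.setdefault(gene, {})[label] = i
    genes, stacks = [], []
    for gene, rows in by_gene.items():
        if PROXIMAL not in rows or DISTAL not in rows:
            raise DataError(f"gene {gene}: needs both |P and |D rows")
        genes.append(gene)
        stacks.append(np.concatenate([mat[rows[PROXIMAL]], mat[rows[DISTAL]]]))
    return genes, np.array(stacks)


# ---------------------------------------------------------------------------
# dispersion


@dataclass
class DispersionEstimate:
    common: float
    method: str
    tagwise: Optional[pd.Series] = None
    prior_df: float = 10.0

    def for_gene(self, gene_id: str) -> float:
        if self.tagwise is not None and gene_id in self.tagwise.index:
            return float(self.tagwise[gene_id])
        return self.common


_PHI_FLOOR, _PHI_CEIL = 1e-4, 10.0


def _apl_sum(
    ys: np.ndarray, X: np.ndarray, offset: np.ndarray, phi: float,
    warm: list[Optional[np.ndarray]],
) -> float:
    total = 0.0
    for i, y in enumerate(ys):
        apl, beta = cr_adjusted_loglik(y, X, offset, phi, beta0=warm[i])
        warm[i] = beta
        total += apl
    return total


def _maximize_phi(objective, n_grid: int = 15) -> float:
    """Maximize over phi on a log grid, refined by golden-section search."""
    grid = np.logspace(np.log10(_PHI_FLOOR), np.log10(_PHI_CEIL), n_grid)
    vals = [objective(p) for p in grid]
    k = int(np.argmax(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, n_grid - 1)]
    if k in (0, n_grid - 1) and vals[k] >= max(vals):
        # maximum at the boundary; still refine within the edge bracket
        pass
    res = optimize.minimize_scalar(
        lambda lp: -objective(math.exp(lp)),
        bounds=(math.log(lo), math.log(hi)),
        method="bounded",
        options={"xatol": 1e-3},
    )
    return float(np.clip(math.exp(res.x), _PHI_FLOOR, _PHI_CEIL))


def estimate_dispersion(
    counts: pd.DataFrame,
    design_df: pd.DataFrame,
    norm: Optional[NormalizationFactors] = None,
    mode: str = "common",
    prior_df: float = 10.0,
) -> DispersionEstimate:
    """Estimate the NB dispersion by Cox-Reid adjusted profile likelihood.

    ``common`` maximizes the APL summed over genes; ``tagwise``
    additionally shrinks per-gene maximizers toward the common value on
    the log scale with weight prior_df / (prior_df + residual_df).
    """
    if mode not in ("common", "tagwise"):
        raise DataError(f"unknown dispersion mode {mode!r}")
    X_full, _, _ = interaction_design(design_df)
    n_obs, p = X_full.shape
    if n_obs <= p:
        raise DataError(
            "no residual degrees of freedom for dispersion estimation; "
            "supply a fixed dispersion instead"
        )
    if norm is None:
        norm = tmm_factors(counts)
    eff = norm.effective_library_sizes.reindex(design_df.index).to_numpy(dtype=float)
    offset = np.log(np.concatenate([eff, eff]))
    genes, ys = _gene_vectors(counts, design_df)
    # genes with all-zero counts carry no dispersion information
    keep = ys.sum(axis=1) > 0
    ys_fit = ys[keep]
    if len(ys_fit) == 0:
        raise DataError("all genes have zero counts")

    warm: list[Optional[np.ndarray]] = [None] * len(ys_fit)
    common = _maximize_phi(lambda phi: _apl_sum(ys_fit, X_full, offset, phi, warm))
    est = DispersionEstimate(common=common, method=mode, prior_df=prior_df)
    if mode == "tagwise":
        resid_df = n_obs - p
        w = prior_df / (prior_df + resid_df)
        tag = {}
        kept_genes = [g for g, k in zip(genes, keep) if k]
        for g, y in zip(kept_genes, ys_fit):
            warm_g: list[Optional[np.ndarray]] = [None]
            phi_g = _maximize_phi(
                lambda phi: _apl_sum(y[None, :], X_full, offset, phi, warm_g)
            )
            tag[g] = math.exp(w * math.log(common) + (1 - w) * math.log(phi_g))
        est.tagwise = pd.Series(tag, name="phi")
    return est


# ---------------------------------------------------------------------------
# interaction LRT


def lrt_interaction_test(
    y: np.ndarray | TwoPASTable,
    design_df: pd.DataFrame,
    norm: NormalizationFactors,
    phi: float,
    gene_id: str = "",
) -> ShiftTest:
    """Likelihood-ratio test of the condition x PAS interaction for one gene.

    *y* is either the stacked (proximal block, distal block) count vector
    or a TwoPASTable. Both nested NB GLMs are fit by IRLS at fixed *phi*;
    the statistic is 2 * (loglik_full - loglik_reduced), clipped at zero,
    referred to chi-square with 1 df.
    """
    if isinstance(y, TwoPASTable):
        gene_id = y.gene_id
        frame = y.counts_frame(list(design_df.index))
        y = np.concatenate([frame.iloc[0].to_numpy(), frame.iloc[1].to_numpy()])
    y = np.asarray(y, dtype=float)
    X_full, X_reduced, names = interaction_design(design_df)
    eff = norm.effective_library_sizes.reindex(design_df.index).to_numpy(dtype=float)
    offset = np.log(np.concatenate([eff, eff]))
    fit_full = fit_nb_glm(y, X_full, offset, phi)
    fit_red = fit_nb_glm(y, X_reduced, offset, phi)
    converged = fit_full.converged and fit_red.converged
    stat = max(0.0, 2.0 * (fit_full.loglik - fit_red.loglik))
    p = float(stats.chi2.sf(stat, df=1)) if converged else float("nan")
    return ShiftTest(
        gene_id=gene_id,
        lrt_statistic=stat,
        p_value=p,
        interaction_coef=float(fit_full.beta[-1]),
        log2_ratio_change=float("nan"),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# q-values


def estimate_qvalues(
    p_values: np.ndarray | Sequence[float], method: str = "storey"
) -> np.ndarray:
    """Storey q-values (BH when method='bh' or when fewer than 100 tests).

    pi0 is estimated on the lambda grid 0.05..0.95 and extrapolated to
    lambda=1 with a cubic smoother, then clipped to (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    m = len(p)
    if method not in ("storey", "bh"):
        raise DataError(f"unknown FDR method {method!r}")
    if method == "storey" and m >= 100:
        lam = np.arange(0.05, 0.96, 0.05)
        pi0_lam = np.array([(p > l).sum() / (m * (1 - l)) for l in lam])
        coeffs = np.polyfit(lam, pi0_lam, deg=3)
        pi0 = float(np.polyval(coeffs, 1.0))
        pi0 = min(max(pi0, 1.0 / m), 1.0)
    else:
        pi0 = 1.0
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_ord = pi0 * m * ranked / (np.arange(m) + 1)
    q_ord = np.minimum.accumulate(q_ord[::-1])[::-1]
    q_ord = np.minimum(q_ord, 1.0)
    q = np.empty(m)
    q[order] = q_ord
    return q


# ---------------------------------------------------------------------------
# ratio change & significance


def log2_ratio_change(
    counts_p: pd.Series | np.ndarray,
    counts_d: pd.Series | np.ndarray,
    design_df: pd.DataFrame,
    norm: NormalizationFactors,
    pseudo: float = 0.5,
) -> float:
    """log2 of [(P/D) in condition B] / [(P/D) in condition A] on
    TMM-normalized, replicate-pooled counts with a pseudo-count."""
    samples = list(design_df.index)
    cp = np.asarray(pd.Series(counts_p, index=samples) if not isinstance(counts_p, pd.Series) else counts_p.reindex(samples), dtype=float)
    cd = np.asarray(pd.Series(counts_d, index=samples) if not isinstance(counts_d, pd.Series) else counts_d.reindex(samples), dtype=float)
    eff = norm.effective_library_sizes.reindex(samples).to_numpy(dtype=float)
    scale = np.exp(np.mean(np.log(eff)))  # rescale to typical library depth
    np_p = cp / eff * scale
    np_d = cd / eff * scale
    cond_levels = sorted(design_df["condition"].unique())
    in_b = (design_df["condition"] == cond_levels[1]).to_numpy()
    pa = np_p[~in_b].sum() + pseudo
    da = np_d[~in_b].sum() + pseudo
    pb = np_p[in_b].sum() + pseudo
    db = np_d[in_b].sum() + pseudo
    return float(np.log2((pb / db) / (pa / da)))


def call_significant_shifts(
    tests: Sequence[ShiftTest], alpha: float = 0.05, fold: float = 2.0
) -> list[ShiftTest]:
    """Apply the joint rule: q < alpha and |log2 ratio change| > log2(fold)."""
    thr = math.log2(fold)
    for t in tests:
        t.significant = bool(
            np.isfinite(t.q_value)
            and t.q_value < alpha
            and abs(t.log2_ratio_change) > thr
        )
    return list(tests)


# ---------------------------------------------------------------------------
# convenience driver


def test_apa_shifts(
    counts: pd.DataFrame,
    design_df: pd.DataFrame,
    alpha: float = 0.05,
    fold: float = 2.0,
    dispersion: str | float = "common",
    fdr: str = "storey",
    pseudo: float = 0.5,
    norm: Optional[NormalizationFactors] = None,
) -> pd.DataFrame:
    """Run the full differential PAS-usage test on a '<gene>|P/D' count
    matrix; returns one row per gene."""
    validate_count_matrix(counts)
    counts = counts[list(design_df.index)]
    if norm is None:
        norm = tmm_factors(counts)
    if isinstance(dispersion, str):
        disp = estimate_dispersion(counts, design_df, norm, mode=dispersion)
    else:
        disp = DispersionEstimate(common=float(dispersion), method="fixed")
    genes, ys = _gene_vectors(counts, design_df)
    S = len(design_df)
    tests = []
    for g, y in zip(genes, ys):
        t = lrt_interaction_test(y, design_df, norm, disp.for_gene(g), gene_id=g)
        t.log2_ratio_change = log2_ratio_change(
            y[:S], y[S:], design_df, norm, pseudo=pseudo
        )
        tests.append(t)
    pvals = np.array([t.p_value for t in tests])
    ok = np.isfinite(pvals)
    q = np.full(len(tests), np.nan)
    if ok.any():
        q[ok] = estimate_qvalues(pvals[ok], method=fdr)
    for t, qv in zip(tests, q):
        t.q_value = float(qv)
    call_significant_shifts(tests, alpha=alpha, fold=fold)
    df = pd.DataFrame(
        {
            "gene_id": [t.gene_id for t in tests],
            "lrt_statistic": [t.lrt_statistic for t in tests],
            "p_value": [t.p_value for t in tests],
            "q_value": [t.q_value for t in tests],
            "interaction_coef": [t.interaction_coef for t in tests],
            "log2_ratio_change": [t.log2_ratio_change for t in tests],
            "direction": [t.direction for t in tests],
            "significant": [t.significant for t in tests],
            "converged": [t.converged for t in tests],
        }
    ).set_index("gene_id")
    df.attrs["dispersion"] = disp.common
    df.attrs["tmm_factors"] = norm.factors.to_dict()
    return df
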