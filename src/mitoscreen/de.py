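"""Sex-stratified negative-binomial Wald differential expression.

The model follows the standard count-based DE framework: for gene g and
sample s,

    K_gs ~ NB(mu_gs, alpha_g),        Var = mu + alpha * mu^2
    log mu_gs = log N_gs + x_s' beta_g

where N_gs is a per-gene-per-sample normalisation factor combining
median-of-ratios size factors with average-transcript-length offsets, x_s
is the design row (intercept, standardised covariates, surrogate variables,
condition last) and the AD-vs-control coefficient is tested with a Wald
statistic against the standard normal.  Fold changes are reported on the
log2 scale (beta / ln 2).

Deliberate simplifications relative to full DESeq2-style machinery, all
surfaced in the documentation: per-gene dispersions are method-of-moments
estimates (pooled within condition groups) with a small floor instead of
empirical-Bayes shrinkage; independent filtering is a fixed
mean-normalised-count threshold; no fold-change shrinkage is applied.

Fitting is an IRLS vectorised across genes (the design matrix is shared;
weights, offsets and dispersions are per-gene), so thousands of genes fit
in seconds.  Genes whose IRLS does not converge are refit as Poisson and
flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import CountMatrix, DesignSpec

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8
_ETA_CLIP = 30.0


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample, the factor is the median over genes of
    count / geometric-mean(count across samples), computed over genes with
    strictly positive counts in every sample.  No further renormalisation is
    applied.
    """
    arr = counts.to_numpy(dtype=float)
    allpos = np.all(arr > 0, axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "pre-filter very sparse genes before computing size factors"
        )
    sub = arr[allpos]
    geo = np.exp(np.log(sub).mean(axis=1))
    sf = np.median(sub / geo[:, None], axis=0)
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalization_matrix(cm: CountMatrix) -> pd.DataFrame:
    """Per-gene-per-sample normalisation factors N_gs.

    Without transcript lengths this is just the size factor broadcast over
    genes.  With lengths, each gene's lengths are divided by their row
    geometric mean to give a matrix of relative length factors; size factors
    are computed on the length-corrected counts and the two terms are
    multiplied (transcript-length offsets in the tximport style).
    """
    if cm.lengths is None:
        sf = size_factors(cm.counts)
        return pd.DataFrame(
            np.broadcast_to(sf.to_numpy(), cm.counts.shape).copy(),
            index=cm.counts.index,
            columns=cm.counts.columns,
        )
    L = cm.lengths.to_numpy(dtype=float)
    rel = L / np.exp(np.log(L).mean(axis=1, keepdims=True))
    corrected = cm.counts.to_numpy(dtype=float) / rel
    corrected_df = pd.DataFrame(corrected, index=cm.counts.index, columns=cm.counts.columns)
    # median-of-ratios tolerates the non-integral corrected counts
    sf = size_factors(corrected_df.round().clip(lower=0))
    return pd.DataFrame(rel * sf.to_numpy()[None, :], index=cm.counts.index, columns=cm.counts.columns)


# ---------------------------------------------------------------------------
# surrogate variables
# ---------------------------------------------------------------------------

def estimate_svs(cm: CountMatrix, design: DesignSpec, k: int = 2) -> pd.DataFrame:
    """Estimate k surrogate variables from residual expression structure.

    Simplified surrogate-variable analysis on log2(normalised count + 1)
    expression: (1) regress each gene on the known design (condition +
    covariates) and take residuals; (2) SVD of the residual matrix to find
    the dominant unmodelled directions and their per-gene loadings;
    (3) reconstruct each surrogate by projecting the *unresidualised*
    expression onto those gene loadings.  Step (3) matters: a surrogate
    taken straight from the residual right-singular-vectors is orthogonal
    to the condition by construction, so adding it to the design is a pure
    reparametrisation that cannot remove the condition-confounded part of a
    hidden batch effect; projecting the raw expression recovers the full
    batch axis, including its confounded component, which is what lets the
    downstream model rescue partially confounded designs.

    Each returned SV is centred, orthogonalised against the previous SVs,
    unit-norm, and sign-fixed (largest-magnitude entry positive), making
    the output invariant to global sign flips of the residuals.
    """
    if design.surrogate_variables is not None:
        raise ValueError("design already contains surrogate variables")
    X = design.matrix().to_numpy()
    n = X.shape[0]
    rank = np.linalg.matrix_rank(X)
    kmax = n - rank - 1
    if k < 1 or k > kmax:
        raise ValueError(f"k must be in [1, {kmax}] for {n} samples and design rank {rank}")
    N = normalization_matrix(cm).to_numpy()
    Y = np.log2(cm.counts.to_numpy(dtype=float) / N + 1.0)
    # residualise: R = Y (I - X (X'X)^-1 X')
    proj = X @ np.linalg.solve(X.T @ X, X.T)
    R = Y - Y @ proj
    u, s, vt = np.linalg.svd(R, full_matrices=False)
    svs = np.zeros((n, k))
    for j in range(k):
        if s[j] <= 1e-10 * max(1.0, s[0]):
            logger.warning("residual singular value %d is ~0; returning zero SV", j + 1)
            continue
        v = u[:, j] @ Y  # raw-expression projection on the residual loadings
        v = v - v.mean()
        for i in range(j):  # keep the SV block orthogonal, hence full rank
            v = v - (v @ svs[:, i]) * svs[:, i]
        nrm = np.linalg.norm(v)
        if nrm <= 1e-10:
            logger.warning("surrogate %d degenerate after orthogonalisation", j + 1)
            continue
        v = v / nrm
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        svs[:, j] = v
    return pd.DataFrame(svs, index=design.sample_ids, columns=[f"SV{j + 1}" for j in range(k)])


# ---------------------------------------------------------------------------
# dispersion and the NB fit
# ---------------------------------------------------------------------------

def _moment_dispersions(q: np.ndarray, condition: np.ndarray) -> np.ndarray:
    """Method-of-moments NB dispersions from normalised counts.

    Per condition group: alpha_g = max(s^2 - m, 0) / m^2; group estimates are
    pooled with degrees-of-freedom weights so the condition effect itself is
    not counted as dispersion.  Floored at DISPERSION_FLOOR.
    """
    G = q.shape[0]
    num = np.zeros(G)
    den = np.zeros(G)
    for level in np.unique(condition):
        sub = q[:, condition == level]
        ng = sub.shape[1]
        if ng < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        a = np.zeros(G)
        a[ok] = np.maximum(v[ok] - m[ok], 0.0) / m[ok] ** 2
        w = (ng - 1) * ok
        num += w * a
        den += w
    alpha = np.full(G, DISPERSION_FLOOR)
    pos = den > 0
    alpha[pos] = np.maximum(num[pos] / den[pos], DISPERSION_FLOOR)
    return alpha


def _nb_irls(
    y: np.ndarray,
    X: np.ndarray,
    log_offset: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched IRLS for NB log-link regression.

    y, log_offset: (G, n); X: (n, p); alpha: (G,).  Returns (beta (G, p),
    se (G, p), converged (G,)).
    """
    G, n = y.shape
    p = X.shape[1]
    init = np.log(y + 0.5) - log_offset
    beta = np.linalg.lstsq(X, init.T, rcond=None)[0].T
    last_delta = np.full(G, np.inf)
    active = np.ones(G, dtype=bool)
    XtWX = np.empty((G, p, p))
    for _ in range(max_iter):
        eta = np.clip(log_offset + beta @ X.T, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - log_offset) + (y - mu) / mu
        XtWX = np.einsum("np,gn,nq->gpq", X, W, X)
        XtWX += 1e-10 * np.eye(p)[None, :, :]
        XtWz = np.einsum("np,gn,gn->gp", X, W, z)
        new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        last_delta = np.max(np.abs(new - beta), axis=1)
        beta = new
        active = last_delta >= tol
        if not active.any():
            break
    cov = np.linalg.inv(XtWX)
    se = np.sqrt(np.clip(np.diagonal(cov, axis1=1, axis2=2), 0.0, None))
    converged = last_delta < 1e-4
    return beta, se, converged


def fit_de(cm: CountMatrix, design: DesignSpec, min_base_mean: float = 1.0) -> pd.DataFrame:
    """Fit the NB-Wald model and return the per-gene DE table.

    Columns: gene_id, base_mean, log2fc, se, wald_stat, pvalue, padj,
    is_deg, direction, fit_flag.  ``padj`` is missing for genes failing the
    mean-normalised-count filter (they are excluded from the BH family) and
    for all-zero genes.  Call :func:`call_degs` afterwards (done here with
    default thresholds) to set the DEG flags.
    """
    Xdf = design.matrix()
    if not Xdf.index.equals(cm.sample_ids):
        raise ValueError("design samples must match the count matrix columns")
    X = Xdf.to_numpy()
    y = cm.counts.to_numpy(dtype=float)
    N = normalization_matrix(cm).to_numpy()
    q = y / N
    base_mean = q.mean(axis=1)
    condition = (design.condition == "AD").to_numpy()

    nonzero = y.sum(axis=1) > 0
    alpha = _moment_dispersions(q, condition)

    G = y.shape[0]
    p = X.shape[1]
    beta = np.zeros((G, p))
    se = np.full((G, p), np.nan)
    fit_flag = np.full(G, "zero", dtype=object)
    if nonzero.any():
        b, s, conv = _nb_irls(y[nonzero], X, np.log(N[nonzero]), alpha[nonzero])
        if (~conv).any():
            # Poisson fallback for genes the NB IRLS could not settle
            bad = np.where(nonzero)[0][~conv]
            logger.info("Poisson fallback for %d non-converged genes", len(bad))
            b2, s2, conv2 = _nb_irls(y[bad], X, np.log(N[bad]), np.zeros(len(bad)))
            b[~conv], s[~conv] = b2, s2
        beta[nonzero] = b
        se[nonzero] = s
        flags = np.where(conv, "nb", "poisson_fallback")
        fit_flag[nonzero] = flags

    coef = beta[:, -1]
    coef_se = se[:, -1]
    with np.errstate(invalid="ignore", divide="ignore"):
        wald = coef / coef_se
    pvalue = 2.0 * stats.norm.sf(np.abs(wald))
    pvalue[~nonzero] = np.nan

    res = pd.DataFrame(
        {
            "gene_id": cm.gene_ids,
            "base_mean": base_mean,
            "log2fc": coef / np.log(2.0),
            "se": coef_se / np.log(2.0),
            "wald_stat": wald,
            "pvalue": pvalue,
            "dispersion": alpha,
            "fit_flag": fit_flag,
        }
    ).set_index("gene_id", drop=False)
    res.index.name = None
    mask = (base_mean >= min_base_mean) & nonzero
    padj = np.full(G, np.nan)
    padj[mask] = adjust_bh(pvalue[mask])
    res["padj"] = padj
    res.loc[~nonzero, "log2fc"] = 0.0
    return call_degs(res)


# ---------------------------------------------------------------------------
# multiple testing and DEG flags
# ---------------------------------------------------------------------------

def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with NaN pass-through.

    Missing entries stay missing and do not count towards the family size m.
    Output is monotone in sorted-p order and capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    finite = np.isfinite(p)
    m = int(finite.sum())
    if m == 0:
        return out
    vals = p[finite]
    order = np.argsort(vals, kind="mergesort")
    ranked = vals[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[finite] = res
    return out


def call_degs(results: pd.DataFrame, padj_cut: float = 0.05, lfc_cut: float = 0.1) -> pd.DataFrame:
    """Flag DEGs: padj < padj_cut AND |log2fc| > lfc_cut, both strict."""
    res = results.copy()
    padj = res["padj"].to_numpy(dtype=float)
    lfc = res["log2fc"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        is_deg = (padj < padj_cut) & (np.abs(lfc) > lfc_cut)
    is_deg = np.where(np.isfinite(padj), is_deg, False)
    res["is_deg"] = is_deg
    res["direction"] = np.where(~is_deg, "none", np.where(lfc > 0, "up", "down"))
    return res


# ---------------------------------------------------------------------------
# batch-adjusted expression for visualisation only
# ---------------------------------------------------------------------------

@dataclass
class AdjustedExpression:
    """log-scale expression with covariate/SV effects regressed out.

    For plotting (PCA, heatmaps) only: this container is deliberately not
    accepted by :func:`fit_de`, which models raw counts.
    """

    matrix: pd.DataFrame
    pca_before: pd.DataFrame
    pca_after: pd.DataFrame


def _pca_coords(Y: np.ndarray, sample_ids, k: int = 2) -> pd.DataFrame:
    centred = Y - Y.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    k = min(k, len(s))
    coords = (vt[:k].T * s[:k])
    return pd.DataFrame(coords, index=sample_ids, columns=[f"PC{i + 1}" for i in range(k)])


def adjusted_matrix_for_viz(cm: CountMatrix, design: DesignSpec) -> AdjustedExpression:
    """Remove covariate and surrogate-variable effects from log expression.

    Expression is log2(normalised count + 1) (a documented stand-in for the
    variance-stabilising transform).  Each gene is regressed on the full
    design; the fitted contributions of the nuisance columns (everything but
    intercept and condition) are subtracted.  PCA coordinates before and
    after adjustment are returned for the batch-correction diagnostic plot.
    """
    Xdf = design.matrix()
    X = Xdf.to_numpy()
    N = normalization_matrix(cm).to_numpy()
    Y = np.log2(cm.counts.to_numpy(dtype=float) / N + 1.0)
    before = _pca_coords(Y, cm.sample_ids)
    B = np.linalg.lstsq(X, Y.T, rcond=None)[0].T  # G x p
    nuisance = [i for i, c in enumerate(Xdf.columns) if c not in ("intercept", "condition_AD")]
    if nuisance:
        Yadj = Y - B[:, nuisance] @ X[:, nuisance].T
    else:
        Yadj = Y.copy()
    after = _pca_coords(Yadj, cm.sample_ids)
    matrix = pd.DataFrame(Yadj, index=cm.gene_ids, columns=cm.sample_ids)
    return AdjustedExpression(matrix=matrix, pca_before=before, pca_after=after)
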