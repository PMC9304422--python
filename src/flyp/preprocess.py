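"""Beta/M transforms, CpG filtering, quantile normalization and batch correction.

The beta scale (proportion methylated, bounded in [0,1]) is kept for
visualisation and clock scores; modelling happens on the M scale,
``M = log2(beta / (1 - beta))``, which is approximately variance-stabilised.

Batch correction re-implements the parametric empirical-Bayes
location/scale adjustment (ComBat): per-CpG batch means and variances are
shrunk toward cross-CpG priors (normal / inverse-gamma) and removed, while
protected covariates (e.g. outcome) stay in the design so real signal is
not regressed out.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

#: Default clipping bound for the beta -> M transform. Bounds M to roughly
#: +-10 without perturbing the bulk of the distribution.
DEFAULT_EPSILON = 1e-3

SEX_CHROMOSOMES = frozenset({"chrX", "chrY", "X", "Y"})


def beta_to_m(beta, epsilon: float = DEFAULT_EPSILON):
    """M = log2(b / (1-b)) with b clipped to [epsilon, 1-epsilon].

    Accepts a DataFrame or ndarray and returns the same container type.
    """
    if not 0.0 < epsilon < 0.5:
        raise ValueError("epsilon must lie in (0, 0.5)")
    vals = beta.to_numpy(dtype=float) if isinstance(beta, pd.DataFrame) else np.asarray(beta, dtype=float)
    clipped = np.clip(vals, epsilon, 1.0 - epsilon)
    m = np.log2(clipped / (1.0 - clipped))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    return m


def m_to_beta(m):
    """Inverse of :func:`beta_to_m` (exact for beta within the clip range)."""
    vals = m.to_numpy(dtype=float) if isinstance(m, pd.DataFrame) else np.asarray(m, dtype=float)
    b = 1.0 / (1.0 + np.power(2.0, -vals))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(b, index=m.index, columns=m.columns)
    return b


def filter_cpgs(beta: pd.DataFrame, ann: pd.DataFrame, maf_threshold: float = 0.01) -> pd.DataFrame:
    """Drop sex-chromosome CpGs and CpGs at SNPs with MAF above threshold.

    Every CpG in ``beta`` must be annotated; the original row order is kept
    for survivors. Idempotent. Default MAF threshold is 1%.
    """
    missing = beta.index.difference(ann.index)
    if len(missing) > 0:
        raise KeyError(f"unannotated CpG id(s), e.g. {missing[0]!r} ({len(missing)} total)")
    sub = ann.loc[beta.index]
    on_sex = sub["chrom"].astype(str).isin(SEX_CHROMOSOMES).to_numpy()
    maf = pd.to_numeric(sub["snp_maf"], errors="coerce").to_numpy()
    snp_hit = np.nan_to_num(maf, nan=0.0) > maf_threshold
    keep = ~(on_sex | snp_hit)
    logger.info(
        "filter_cpgs: dropped %d sex-chromosome and %d SNP (MAF > %g) CpGs; %d retained",
        int(on_sex.sum()), int((snp_hit & ~on_sex).sum()), maf_threshold, int(keep.sum()),
    )
    return beta.loc[keep]


def quantile_normalize(beta: pd.DataFrame) -> pd.DataFrame:
    """Force every sample onto the mean empirical quantile profile.

    Ranks within each sample are preserved; ties receive the average of the
    reference quantiles they span (average-rank convention). Missing values
    are rejected -- use a mask-aware path upstream.
    """
    vals = beta.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("quantile_normalize requires a complete matrix (no NaN)")
    n_cpg = vals.shape[0]
    reference = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    grid = np.arange(1, n_cpg + 1, dtype=float)
    for j in range(vals.shape[1]):
        ranks = rankdata(vals[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, reference)
    return pd.DataFrame(out, index=beta.index, columns=beta.columns)


# ---------------------------------------------------------------------------
# parametric empirical-Bayes batch correction
# ---------------------------------------------------------------------------

def _design_from_covariates(covariates, index) -> np.ndarray:
    if covariates is None:
        return np.empty((len(index), 0))
    cov = covariates.loc[index] if isinstance(covariates, pd.DataFrame) else pd.DataFrame(covariates, index=index)
    parts = []
    for col in cov.columns:
        s = cov[col]
        if s.dtype.kind in "biufc":
            parts.append(s.to_numpy(dtype=float)[:, None])
        else:
            dummies = pd.get_dummies(s, drop_first=True, dtype=float)
            parts.append(dummies.to_numpy())
    return np.hstack(parts) if parts else np.empty((len(index), 0))


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2.0 * s2 + m ** 2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m ** 3) / s2


def _it_sol(z_batch, gamma_hat, delta_hat, gamma_bar, t2, a, b, conv=1e-4, max_iter=500):
    """Iterative joint posterior-mode solution for the batch location/scale."""
    n = z_batch.shape[1]
    gamma_old, delta_old = gamma_hat.copy(), delta_hat.copy()
    for _ in range(max_iter):
        gamma_new = (t2 * n * gamma_hat + delta_old * gamma_bar) / (t2 * n + delta_old)
        sum2 = ((z_batch - gamma_new[:, None]) ** 2).sum(axis=1)
        delta_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.abs(gamma_new - gamma_old).max() / np.maximum(np.abs(gamma_old), 1e-12).max(),
            np.abs(delta_new - delta_old).max() / np.maximum(np.abs(delta_old), 1e-12).max(),
        )
        gamma_old, delta_old = gamma_new, delta_new
        if change < conv:
            break
    return gamma_old, delta_old


def batch_correct(m: pd.DataFrame, batches, covariates=None) -> pd.DataFrame:
    """Remove batch effects from an M-value matrix by parametric EB adjustment.

    Parameters
    ----------
    m : DataFrame, CpG x sample.
    batches : per-sample batch labels (aligned to ``m.columns``).
    covariates : optional per-sample DataFrame of protected covariates
        (e.g. outcome); retained in the design so their signal survives.

    Requires >= 2 batches with >= 2 samples each; a batch perfectly aliased
    with the protected covariates is rejected.
    """
    batches = pd.Series(np.asarray(batches), index=m.columns).astype(str)
    levels = batches.unique().tolist()
    if len(levels) < 2:
        raise ValueError("batch correction needs at least two batches")
    counts = batches.value_counts()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"singleton batch(es) {bad}: need >= 2 samples per batch")

    y = m.to_numpy(dtype=float)
    n = y.shape[1]
    batch_design = np.column_stack([(batches == lv).to_numpy(float) for lv in levels])
    cov_design = _design_from_covariates(covariates, m.columns)
    design = np.hstack([batch_design, cov_design])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("batch is confounded with the protected covariates (design not full rank)")

    b_hat = np.linalg.solve(design.T @ design, design.T @ y.T)  # (K+p) x G
    n_batches = len(levels)
    weights = counts.reindex(levels).to_numpy(float) / n
    grand_mean = weights @ b_hat[:n_batches]                     # (G,)
    resid = y - (design @ b_hat).T
    var_pooled = (resid ** 2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-12)

    stand_mean = grand_mean[:, None] + (cov_design @ b_hat[n_batches:]).T
    z = (y - stand_mean) / np.sqrt(var_pooled)[:, None]

    adjusted = z.copy()
    for i, lv in enumerate(levels):
        cols = (batches == lv).to_numpy()
        zb = z[:, cols]
        gamma_hat = zb.mean(axis=1)
        delta_hat = zb.var(axis=1, ddof=1)
        gamma_bar, t2 = gamma_hat.mean(), gamma_hat.var(ddof=1)
        if t2 < 1e-12 or delta_hat.var(ddof=1) < 1e-12:
            # degenerate priors (no spread across CpGs): fall back to the
            # direct location/scale estimates -- shrinkage has nothing to add
            gamma_star, delta_star = gamma_hat, delta_hat
        else:
            a, b = _aprior(delta_hat), _bprior(delta_hat)
            gamma_star, delta_star = _it_sol(zb, gamma_hat, delta_hat, gamma_bar, t2, a, b)
        adjusted[:, cols] = (zb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    corrected = adjusted * np.sqrt(var_pooled)[:, None] + stand_mean
    return pd.DataFrame(corrected, index=m.index, columns=m.columns)
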