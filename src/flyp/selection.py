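"""Two-step CpG selection: moderated univariate screening, then elastic net.

Stage 1 fits an ordinary least-squares model per CpG on the M scale
(outcome dummies against the control reference, plus covariates such as age
and sex) and moderates the t statistics by empirical-Bayes shrinkage of the
residual variances toward a scaled inverse-chi-square prior whose scale and
degrees of freedom are fitted by moments on the log variances. For the
three-level outcome the two contrasts (NHL_hi - control, NHL_lo - control)
are combined into a moderated F with an overall p-value.

Stage 2 condenses the stage-1 survivors with a cross-validated multinomial
(or binomial) elastic net; lambda follows the 1-SE rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from statsmodels.stats.multitest import multipletests

from .vocab import CLASS_LEVELS

logger = logging.getLogger(__name__)

#: Permutation-derived genome-wide significance threshold for 450k data,
#: used as the default fixed-p cutoff of stage 1.
GENOME_WIDE_P = 2.4e-7


# ---------------------------------------------------------------------------
# empirical-Bayes variance shrinkage
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if -dif / y < 1e-8:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment fit of the scaled inverse-chi-square prior (d0, s0^2).

    Works on the log variances: under the model, log(s2) has a shifted
    log-F distribution whose first two moments identify the prior degrees
    of freedom (via a trigamma inverse) and the prior scale.
    """
    s2 = np.asarray(s2, float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s20 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0, s20 = np.inf, np.exp(emean)
    return float(d0), float(s20)


def squeeze_variances(s2: np.ndarray, df: float, prior_df=None):
    """Shrink per-CpG variances toward the fitted (or given) prior.

    ``prior_df=0`` disables shrinkage (ordinary t); ``prior_df=None``
    estimates the prior from the data.
    """
    if prior_df is None:
        d0, s20 = fit_variance_prior(s2, df)
    else:
        d0 = float(prior_df)
        _, s20 = fit_variance_prior(s2, df) if d0 > 0 else (None, 0.0)
    if np.isinf(d0):
        return np.full_like(s2, s20), d0
    if d0 == 0:
        return s2.copy(), 0.0
    return (d0 * s20 + df * s2) / (d0 + df), d0


# ---------------------------------------------------------------------------
# stage 1: moderated linear models
# ---------------------------------------------------------------------------

def _covariate_design(covariates, index):
    if covariates is None:
        return np.empty((len(index), 0)), []
    cov = covariates.loc[index]
    cols, names = [], []
    for c in cov.columns:
        s = cov[c]
        if s.dtype.kind in "biufc":
            cols.append(s.to_numpy(float)[:, None])
            names.append(c)
        else:
            d = pd.get_dummies(s, prefix=c, drop_first=True, dtype=float)
            cols.append(d.to_numpy())
            names.extend(d.columns)
    x = np.hstack(cols) if cols else np.empty((len(index), 0))
    return x, names


def moderated_lm(m: pd.DataFrame, labels: pd.Series, covariates: pd.DataFrame | None = None,
                 prior_df=None) -> pd.DataFrame:
    """Per-CpG moderated regression of M values on the outcome.

    ``labels`` may be two-level (reference = ``control`` when present,
    otherwise the lexicographically first level) or the three-level
    {control, NHL_hi, NHL_lo} outcome. Returns a DataFrame indexed by CpG
    with per-contrast coefficients, moderated t and p, an overall p
    (moderated F for three levels), BH q, z-score and direction relative
    to the reference. Zero-variance CpGs are flagged and given p = 1.
    """
    labels = labels.loc[m.columns].astype(str)
    levels = sorted(pd.unique(labels))
    if len(levels) < 2:
        raise ValueError("outcome must have at least two levels")
    if set(levels) <= set(CLASS_LEVELS):
        ordered = [lv for lv in CLASS_LEVELS if lv in levels]
    else:
        ordered = levels
    reference = "control" if "control" in ordered else ordered[0]
    contrast_levels = [lv for lv in ordered if lv != reference]

    n = m.shape[1]
    dummies = np.column_stack([(labels == lv).to_numpy(float) for lv in contrast_levels])
    cov_x, _ = _covariate_design(covariates, m.columns)
    design = np.hstack([np.ones((n, 1)), dummies, cov_x])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError("design matrix is not full rank")
    df_res = n - rank
    if df_res < 3:
        raise ValueError(f"only {df_res} residual degrees of freedom; need >= 3")

    y = m.to_numpy(float)                       # G x n
    if not np.isfinite(y).all():
        raise ValueError("moderated_lm requires a complete matrix (no NaN); "
                         "impute or drop masked entries first")
    xtx_inv = np.linalg.inv(design.T @ design)
    coef = y @ design @ xtx_inv.T               # G x p
    resid = y - coef @ design.T
    s2 = (resid ** 2).sum(axis=1) / df_res
    zero_var = s2 <= 1e-15
    if zero_var.any():
        logger.warning("moderated_lm: %d zero-variance CpGs flagged", int(zero_var.sum()))

    s2_fit = s2[~zero_var] if zero_var.any() else s2
    s2_post_fit, d0 = squeeze_variances(s2_fit, df_res, prior_df=prior_df)
    s2_post = np.empty_like(s2)
    s2_post[~zero_var] = s2_post_fit
    s2_post[zero_var] = np.nan
    df_total = df_res + (d0 if np.isfinite(d0) else 1e6)

    cidx = np.arange(1, 1 + len(contrast_levels))
    out = pd.DataFrame(index=m.index)
    tstats = {}
    for i, lv in zip(cidx, contrast_levels):
        b = coef[:, i]
        se = np.sqrt(s2_post * xtx_inv[i, i])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = b / se
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
        out[f"coef_{lv}"] = b
        out[f"t_{lv}"] = t
        out[f"p_{lv}"] = p
        tstats[lv] = t

    if len(contrast_levels) == 1:
        lv = contrast_levels[0]
        out["p"] = out[f"p_{lv}"]
        direction_sign = coef[:, 1]
    else:
        q = len(contrast_levels)
        c_cov_inv = np.linalg.inv(xtx_inv[np.ix_(cidx, cidx)])
        b = coef[:, cidx]
        quad = np.einsum("gi,ij,gj->g", b, c_cov_inv, b)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = quad / (q * s2_post)
        out["F"] = f
        out["p"] = stats.f.sf(f, q, df_total)
        direction_sign = b.mean(axis=1)

    out.loc[zero_var, [c for c in out.columns if c.startswith(("p", "t", "F"))]] = np.nan
    out.loc[zero_var, "p"] = 1.0
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    pvals = np.clip(out["p"].to_numpy(float), 1e-300, 1.0)
    out["z"] = np.sign(direction_sign) * np.minimum(stats.norm.isf(pvals / 2.0), 38.0)
    out["direction"] = np.where(direction_sign > 0, "hyper", "hypo")
    out["zero_variance"] = zero_var
    out.attrs["prior_df"] = d0
    out.attrs["df_residual"] = df_res
    out.attrs["contrasts"] = contrast_levels
    return out


def threshold_stage1(dm: pd.DataFrame, mode: str = "fixed_p",
                     level: float = GENOME_WIDE_P) -> list[str]:
    """Stage-1 survivors, sorted by increasing p.

    ``fixed_p`` keeps raw p <= level (default the permutation-derived
    genome-wide threshold 2.4e-7); ``bh_fdr`` applies Benjamini-Hochberg at
    ``level``. An empty survivor set is returned with a warning.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    p = dm["p"]
    if mode == "fixed_p":
        keep = p <= level
    elif mode == "bh_fdr":
        keep = pd.Series(multipletests(p.to_numpy(), alpha=level, method="fdr_bh")[0],
                         index=p.index)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    survivors = p[keep].sort_values().index.tolist()
    if not survivors:
        warnings.warn("stage 1 returned no survivors; the pipeline stops before "
                      "the elastic net", stacklevel=2)
    return survivors


# ---------------------------------------------------------------------------
# stage 2: elastic-net condensation
# ---------------------------------------------------------------------------

@dataclass
class FeatureSet:
    """Elastic-net-selected CpGs with their nonzero class coefficients."""

    cpgs: list[str]
    coefficients: pd.DataFrame          # feature x class
    alpha: float
    lambda_: float
    seed: int
    n_stage1: int
    cv_table: pd.DataFrame = field(repr=False, default=None)


def _lambda_path(x, y_ind, alpha, n_lambdas, lambda_min_ratio):
    n = x.shape[0]
    priors = y_ind.mean(axis=0)
    resid = y_ind - priors
    grad = np.abs(x.T @ resid) / n
    lam_max = grad.max() / max(alpha, 1e-3)
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)


def _fit_enet(x, y, alpha, lam, seed, model=None):
    """Fit (or warm-restart) a saga elastic-net logistic fit at one lambda."""
    n = x.shape[0]
    c = 1.0 / max(lam * n, 1e-12)
    if model is None:
        model = LogisticRegression(
            solver="saga", l1_ratio=alpha, C=c, max_iter=5000, tol=1e-4,
            random_state=seed, warm_start=True)
    else:
        model.C = c
    model.fit(x, y)
    return model


def elastic_net_condense(m: pd.DataFrame, labels: pd.Series, alpha: float = 0.5,
                         folds: int = 10, seed: int = 0, n_lambdas: int = 30,
                         lambda_min_ratio: float = 0.01) -> FeatureSet:
    """Condense stage-1 survivors with a cross-validated elastic net.

    ``m`` is the survivor-restricted M matrix (CpG x sample). Features are
    standardised; lambda descends a glmnet-style geometric path and is
    chosen by the 1-SE rule on cross-validated multinomial deviance. The
    returned set is the union of CpGs with any nonzero class coefficient
    (all survivors when ``alpha=0`` -- ridge makes no exact zeros).
    """
    if m.shape[0] < 2:
        raise ValueError("need at least two stage-1 survivors")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    labels = labels.loc[m.columns].astype(str)
    classes = sorted(pd.unique(labels))
    if len(classes) < 2:
        raise ValueError("labels must contain at least two classes")

    x = m.to_numpy(float).T
    mu, sd = x.mean(axis=0), x.std(axis=0)
    sd[sd == 0] = 1.0
    x = (x - mu) / sd
    y = labels.to_numpy()
    y_ind = np.column_stack([(y == c).astype(float) for c in classes])
    lambdas = _lambda_path(x, y_ind, alpha, n_lambdas, lambda_min_ratio)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    losses = np.zeros((folds, len(lambdas)))
    eps = 1e-12
    for k, (tr, va) in enumerate(skf.split(x, y)):
        model = None
        for i, lam in enumerate(lambdas):   # descending path, warm-started
            model = _fit_enet(x[tr], y[tr], alpha, lam, seed, model=model)
            proba = np.clip(model.predict_proba(x[va]), eps, 1.0)
            col = np.searchsorted(model.classes_, y[va])
            losses[k, i] = -np.mean(np.log(proba[np.arange(len(va)), col]))
    mean_loss = losses.mean(axis=0)
    se_loss = losses.std(axis=0, ddof=1) / np.sqrt(folds)
    best = int(np.argmin(mean_loss))
    threshold = mean_loss[best] + se_loss[best]
    chosen = int(np.flatnonzero(mean_loss <= threshold)[0])  # largest lambda within 1 SE
    lam = float(lambdas[chosen])

    final = _fit_enet(x, y, alpha, lam, seed)
    if final.coef_.shape[0] == 1:   # binomial fit: one column, the second class
        coefs = pd.DataFrame(final.coef_.T, index=m.index, columns=[final.classes_[1]])
    else:
        coefs = pd.DataFrame(final.coef_.T, index=m.index, columns=final.classes_)
    nonzero = (coefs.abs() > 1e-8).any(axis=1)
    if not nonzero.any():
        raise ValueError(
            "degenerate elastic-net fit: no nonzero coefficients at the chosen "
            f"lambda ({lam:.4g}); cv loss path {np.round(mean_loss, 4).tolist()}")
    selected = coefs[nonzero]
    order = selected.abs().max(axis=1).sort_values(ascending=False).index
    cv_table = pd.DataFrame({"lambda": lambdas, "mean_deviance": mean_loss, "se": se_loss})
    return FeatureSet(cpgs=list(order), coefficients=selected.loc[order],
                      alpha=alpha, lambda_=lam, seed=seed, n_stage1=m.shape[0],
                      cv_table=cv_table)


# ---------------------------------------------------------------------------
# split stability
# ---------------------------------------------------------------------------

def split_stability(m: pd.DataFrame, labels: pd.Series, covariates=None,
                    n_splits: int = 10, seed: int = 0, train_frac: float = 0.7,
                    mode: str = "fixed_p", level: float = GENOME_WIDE_P) -> dict:
    """Stability of stage-1 statistics over repeated random splits.

    Repeats the stratified train split ``n_splits`` times (plus the
    reference split derived directly from ``seed``), refits the moderated
    model per split and reports the per-CpG z-score matrix, its pairwise
    Pearson correlations, and the Jaccard overlap of each split's survivor
    set with the reference split's.
    """
    if n_splits < 2:
        raise ValueError("n_splits must be >= 2")
    labels = labels.loc[m.columns]
    zcols, survivor_sets = {}, {}
    for name, split_seed in [("reference", seed)] + [
            (f"split_{i + 1}", seed + 1 + i) for i in range(n_splits)]:
        train, _ = train_test_split(np.asarray(m.columns), train_size=train_frac,
                                    stratify=labels.to_numpy(), random_state=split_seed)
        dm = moderated_lm(m[train], labels.loc[train],
                          covariates=None if covariates is None else covariates.loc[train])
        zcols[name] = dm["z"]
        survivor_sets[name] = set(threshold_stage1(dm, mode=mode, level=level))
    zmat = pd.DataFrame(zcols)
    ref = survivor_sets["reference"]
    jaccard = {}
    for name, s in survivor_sets.items():
        union = ref | s
        jaccard[name] = len(ref & s) / len(union) if union else np.nan
    return {
        "zscores": zmat,
        "correlations": zmat.corr(),
        "jaccard_vs_reference": pd.Series(jaccard, name="jaccard"),
        "survivor_sets": survivor_sets,
    }
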