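"""Reference-based immune-cell deconvolution of bulk methylation.

Two estimators of the per-sample cell-type fractions are provided, both
operating on a signature matrix of discriminative CpGs built from sorted
reference profiles:

* nu-SVR (the CIBERSORT recipe): per sample, a linear support-vector
  regression of the z-scored mixture on the z-scored signature, over a grid
  of nu values; the nu minimising the reconstruction RMSE wins, negative
  coefficients are clipped to zero and the rest renormalised to sum to 1.
* RPC (robust partial correlations, EpiDISH-style): per sample, an
  iteratively-reweighted Huber regression of the mixture on the signature,
  similarly clipped and renormalised.

Cell-type-specific differential methylation is estimated with a
fraction-by-outcome interaction model: for each CpG,
``beta ~ sum_k f_k + sum_k f_k * case``, where the interaction coefficient
of cell type k is that type's case effect within its compartment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import NuSVR

from .vocab import LYMPHOCYTE_TYPES

logger = logging.getLogger(__name__)


@dataclass
class SignatureMatrix:
    """Selected CpG x cell-type betas plus per-CpG selection provenance."""

    profiles: pd.DataFrame          # CpG x cell type
    provenance: pd.DataFrame        # per CpG: contrast type, delta_beta, direction
    condition_number: float

    @property
    def cpgs(self) -> pd.Index:
        return self.profiles.index

    @property
    def cell_types(self) -> list[str]:
        return list(self.profiles.columns)


@dataclass
class CellFractions:
    """Sample x cell-type proportions with per-sample fit diagnostics."""

    fractions: pd.DataFrame
    diagnostics: pd.DataFrame


def build_signature(refs: pd.DataFrame, max_per_type: int = 100,
                    delta_beta_min: float = 0.2) -> SignatureMatrix:
    """One-vs-rest marker selection from sorted-cell reference profiles.

    For each cell type the CpGs are ranked by the difference between that
    type's mean beta and the mean of all other types; up to ``max_per_type``
    hyper- and ``max_per_type`` hypo-methylated CpGs with an absolute
    difference >= ``delta_beta_min`` are kept. Ties break on larger
    |delta|, then lexicographic CpG id. The union over types forms the
    signature; a type contributing no qualifying CpG is an error.
    """
    if refs.shape[0] < 2:
        raise ValueError("signature construction needs >= 2 cell types")
    r = refs.to_numpy(float)                    # types x CpGs
    n_types = r.shape[0]
    chosen: dict[str, tuple] = {}
    for t_idx, t in enumerate(refs.index):
        others = r[np.arange(n_types) != t_idx].mean(axis=0)
        delta = r[t_idx] - others
        frame = pd.DataFrame({"delta": delta, "cpg": refs.columns})
        frame["absd"] = frame["delta"].abs()
        qual = frame[frame["absd"] >= delta_beta_min]
        if qual.empty:
            raise ValueError(f"cell type {t!r} has no CpG with |delta beta| >= {delta_beta_min}")
        picked = []
        for direction, sub in (("hyper", qual[qual["delta"] > 0]),
                               ("hypo", qual[qual["delta"] < 0])):
            sub = sub.sort_values(["absd", "cpg"], ascending=[False, True])
            picked.append((direction, sub.head(max_per_type)))
        for direction, sub in picked:
            for _, row in sub.iterrows():
                prev = chosen.get(row["cpg"])
                if prev is None or abs(row["delta"]) > abs(prev[1]):
                    chosen[row["cpg"]] = (t, row["delta"], direction)
    cpgs = sorted(chosen)
    profiles = refs[cpgs].T
    provenance = pd.DataFrame(
        {"contrast_type": [chosen[c][0] for c in cpgs],
         "delta_beta": [chosen[c][1] for c in cpgs],
         "direction": [chosen[c][2] for c in cpgs]},
        index=pd.Index(cpgs, name="cpg_id"))
    cond = float(np.linalg.cond(profiles.to_numpy(float)))
    logger.info("build_signature: %d CpGs, condition number %.2f", len(cpgs), cond)
    return SignatureMatrix(profiles=profiles, provenance=provenance, condition_number=cond)


def _align(beta: pd.DataFrame, sig: SignatureMatrix):
    present = sig.cpgs.intersection(beta.index)
    if len(present) < len(sig.cell_types):
        raise ValueError(
            f"only {len(present)} signature CpGs present; need at least "
            f"{len(sig.cell_types)} (one per cell type)")
    x = sig.profiles.loc[present].to_numpy(float)
    y = beta.loc[present].to_numpy(float)
    return x, y, present


def _finalize(coefs: np.ndarray) -> np.ndarray:
    coefs = np.clip(coefs, 0.0, None)
    total = coefs.sum()
    if total <= 0:
        warnings.warn("all-zero deconvolution coefficients; returning uniform fractions",
                      stacklevel=3)
        return np.full_like(coefs, 1.0 / len(coefs))
    return coefs / total


def estimate_fractions_svr(beta: pd.DataFrame, sig: SignatureMatrix,
                           nu_grid=(0.25, 0.5, 0.75), C: float = 1.0) -> CellFractions:
    """CIBERSORT-style nu-SVR fraction estimates.

    Signature and each mixture column are z-scored (their own mean/SD)
    before the linear SVR fit; renormalisation of the clipped coefficients
    removes the resulting scale ambiguity.
    """
    x, y, _ = _align(beta, sig)
    xs = (x - x.mean()) / x.std()
    rows, diags = [], []
    for j, sample in enumerate(beta.columns):
        yj = y[:, j]
        ys = (yj - yj.mean()) / max(yj.std(), 1e-12)
        best = None
        for nu in nu_grid:
            model = NuSVR(kernel="linear", nu=nu, C=C)
            model.fit(xs, ys)
            pred = model.predict(xs)
            rmse = float(np.sqrt(np.mean((pred - ys) ** 2)))
            if best is None or rmse < best[0]:
                best = (rmse, nu, model.coef_.ravel(), pred)
        rmse, nu, coefs, pred = best
        corr = float(np.corrcoef(pred, ys)[0, 1]) if ys.std() > 0 else np.nan
        rows.append(_finalize(coefs))
        diags.append({"rmse": rmse, "corr": corr, "nu": nu})
    fractions = pd.DataFrame(rows, index=beta.columns, columns=sig.cell_types)
    return CellFractions(fractions=fractions,
                         diagnostics=pd.DataFrame(diags, index=beta.columns))


def _huber_irls(x: np.ndarray, y: np.ndarray, k: float, max_iter: int, tol: float = 1e-6):
    """Huber M-estimation of y ~ [1, x] by iteratively reweighted LS."""
    design = np.column_stack([np.ones(len(y)), x])
    coef = np.linalg.lstsq(design, y, rcond=None)[0]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        resid = y - design @ coef
        scale = max(np.median(np.abs(resid - np.median(resid))) / 0.6745, 1e-9)
        u = np.abs(resid / scale)
        w = np.where(u <= k, 1.0, k / np.maximum(u, 1e-12))
        wx = design * w[:, None]
        new = np.linalg.solve(wx.T @ design, wx.T @ y)
        if np.max(np.abs(new - coef)) < tol:
            coef = new
            converged = True
            break
        coef = new
    return coef[1:], it, converged


def estimate_fractions_rpc(beta: pd.DataFrame, sig: SignatureMatrix,
                           max_iter: int = 100, huber_k: float = 1.345) -> CellFractions:
    """Robust-partial-correlation fractions: per-sample Huber regression of
    the mixture on the signature, clipped and renormalised."""
    x, y, _ = _align(beta, sig)
    rows, diags = [], []
    for j, sample in enumerate(beta.columns):
        coefs, iters, converged = _huber_irls(x, y[:, j], huber_k, max_iter)
        if not converged:
            logger.warning("RPC fit for %s did not converge in %d iterations",
                           sample, max_iter)
        rows.append(_finalize(coefs))
        diags.append({"iterations": iters, "converged": converged})
    fractions = pd.DataFrame(rows, index=beta.columns, columns=sig.cell_types)
    return CellFractions(fractions=fractions,
                         diagnostics=pd.DataFrame(diags, index=beta.columns))


def compare_fraction_methods(f1: CellFractions, f2: CellFractions) -> pd.Series:
    """Per-cell-type Pearson correlation of two fraction estimates."""
    a, b = f1.fractions, f2.fractions
    if not a.index.equals(b.index) or list(a.columns) != list(b.columns):
        raise ValueError("fraction tables must share samples and cell types")
    out = {}
    for t in a.columns:
        x, y = a[t].to_numpy(float), b[t].to_numpy(float)
        if x.std() == 0 or y.std() == 0:
            out[t] = np.nan
        else:
            out[t] = float(np.corrcoef(x, y)[0, 1])
    return pd.Series(out, name="pearson_r")


def celltype_specific_dm(beta: pd.DataFrame, fractions: CellFractions,
                         outcome: pd.Series, annotation: pd.DataFrame | None = None,
                         island_only: bool = True,
                         min_fraction_var: float = 1e-6) -> pd.DataFrame:
    """Cell-type-specific case effects via fraction-outcome interactions.

    Fits, per CpG, ``beta ~ sum_k f_k + sum_k f_k * case`` (no intercept;
    the fractions sum to one). The interaction coefficient of type k
    estimates the within-compartment case-vs-control methylation difference
    and gets a t-based p-value. By default only island CpGs are modelled.
    Cell types with near-zero fraction variance are dropped with a warning.
    """
    f = fractions.fractions.loc[beta.columns]
    case = (outcome.loc[beta.columns] == "future_NHL").to_numpy(float)
    keep = [t for t in f.columns if f[t].var() >= min_fraction_var]
    dropped = [t for t in f.columns if t not in keep]
    if dropped:
        warnings.warn(f"dropping near-constant fraction column(s): {dropped}", stacklevel=2)
    if not keep:
        raise ValueError("no cell type has enough fraction variance to model")

    target = beta
    if island_only:
        if annotation is None:
            raise ValueError("island_only=True requires the CpG annotation")
        island = annotation.loc[beta.index, "island_relation"].astype(str) == "Island"
        target = beta.loc[island.to_numpy()]

    fmat = f[keep].to_numpy(float)
    design = np.hstack([fmat, fmat * case[:, None]])
    n, p = design.shape
    xtx_inv = np.linalg.pinv(design.T @ design)
    hat = xtx_inv @ design.T
    y = target.to_numpy(float).T                  # samples x CpGs
    coef = hat @ y                                # p x CpGs
    resid = y - design @ coef
    dof = n - np.linalg.matrix_rank(design)
    sigma2 = (resid ** 2).sum(axis=0) / max(dof, 1)
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = coef / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=max(dof, 1))

    k = len(keep)
    out = {}
    for i, t in enumerate(keep):
        out[f"effect_{t}"] = coef[k + i]
        out[f"p_{t}"] = pvals[k + i]
    return pd.DataFrame(out, index=target.index)


def composition_summaries(fractions: CellFractions, pheno: pd.DataFrame,
                          lymphocyte_types=LYMPHOCYTE_TYPES) -> pd.DataFrame:
    """Case-vs-control rank-sum tests per cell type plus the
    neutrophil-to-lymphocyte ratio (NLR).

    NLR is neutrophil fraction over the summed lymphocyte fractions; a
    sample with zero lymphocytes gets a missing NLR.
    """
    f = fractions.fractions
    if "neutrophils" not in f.columns:
        raise ValueError("panel must include neutrophils for the NLR")
    lymph = [t for t in lymphocyte_types if t in f.columns]
    if not lymph:
        raise ValueError("panel must include at least one lymphocyte type")
    outcome = pheno.loc[f.index, "outcome"]
    case = outcome == "future_NHL"
    denom = f[lymph].sum(axis=1)
    nlr = f["neutrophils"] / denom.where(denom > 0)

    rows = []
    for name, series in list(f.items()) + [("NLR", nlr)]:
        x = series[case].dropna().to_numpy(float)
        y = series[~case].dropna().to_numpy(float)
        if len(x) == 0 or len(y) == 0 or (series.dropna().nunique() <= 1):
            stat, p = np.nan, np.nan
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append({"variable": name,
                     "case_mean": float(np.mean(x)) if len(x) else np.nan,
                     "control_mean": float(np.mean(y)) if len(y) else np.nan,
                     "statistic": stat, "p_value": p,
                     "n_missing": int(series.isna().sum())})
    return pd.DataFrame(rows).set_index("variable")
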