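"""Mitotic-clock (epiTOC) scoring and three-class outcome stratification.

The epiTOC score of a sample is the unweighted mean beta over a fixed set
of clock CpGs (canonically 385 sites that are unmethylated in fetal tissue
and gain methylation with cell division). Future cases are split at a
cutoff (by default the median score of the *training* cases, frozen for
test scoring) into high- and low-clock strata, yielding the three-level
outcome {control, NHL_hi, NHL_lo}.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .vocab import CLASS_LEVELS

logger = logging.getLogger(__name__)


def epitoc_score(beta: pd.DataFrame, clock_cpgs) -> pd.Series:
    """Per-sample mean beta over the clock CpGs present in the matrix.

    Missing clock CpGs are tolerated (coverage is logged); an empty
    intersection is an error.
    """
    clock = pd.Index(pd.unique(pd.Index(clock_cpgs)))
    present = clock.intersection(beta.index)
    if len(present) == 0:
        raise ValueError("none of the clock CpGs are present in the matrix")
    coverage = len(present) / len(clock)
    if coverage < 1.0:
        logger.info("epitoc_score: %d/%d clock CpGs present (%.1f%% coverage)",
                    len(present), len(clock), 100 * coverage)
    scores = beta.loc[present].mean(axis=0)
    scores.name = "epitoc"
    return scores


def stratify_cases(scores: pd.Series, pheno: pd.DataFrame, cutoff="median",
                   training_samples=None):
    """Three-class labels from outcome + clock stratum.

    Cases with score strictly above the cutoff become ``NHL_hi``; cases at
    or below it become ``NHL_lo``; controls stay ``control``. With
    ``cutoff="median"`` the cutoff is the median score of the cases among
    ``training_samples`` (all samples if not given) and is returned so it
    can be frozen for later scoring.

    Returns ``(labels, cutoff_used)``.
    """
    outcome = pheno.loc[scores.index, "outcome"]
    case_mask = outcome == "future_NHL"
    if not case_mask.any():
        raise ValueError("no future_NHL cases to stratify")
    if cutoff == "median":
        pool = scores[case_mask]
        if training_samples is not None:
            pool = pool.loc[pool.index.intersection(pd.Index(training_samples))]
            if pool.empty:
                raise ValueError("no training cases available to compute the median cutoff")
        cutoff_used = float(pool.median())
    else:
        cutoff_used = float(cutoff)
    labels = pd.Series("control", index=scores.index, name="three_class")
    labels[case_mask & (scores > cutoff_used)] = "NHL_hi"
    labels[case_mask & (scores <= cutoff_used)] = "NHL_lo"
    n_hi = int((labels == "NHL_hi").sum())
    n_lo = int((labels == "NHL_lo").sum())
    if n_hi == 0 or n_lo == 0:
        logger.warning("stratify_cases: degenerate split (hi=%d, lo=%d) -- "
                       "effectively a two-class problem", n_hi, n_lo)
    labels = pd.Series(pd.Categorical(labels, categories=CLASS_LEVELS),
                       index=scores.index, name="three_class")
    return labels, cutoff_used


def compare_clock_groups(scores: pd.Series, grouping: pd.Series, age: pd.Series | None = None):
    """Two-sided rank-sum comparison of clock scores between two groups.

    ``grouping`` must take exactly two values over the scored samples. If
    ``age`` is given, scores are first residualised on age (simple linear
    regression) and the test runs on the residuals. Small samples without
    ties use the exact Mann-Whitney null distribution.

    Returns a dict with the statistic, p-value, group sizes and method.
    """
    grouping = grouping.loc[scores.index]
    levels = pd.unique(grouping)
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {list(levels)}")
    values = scores.astype(float)
    if age is not None:
        a = age.loc[scores.index].astype(float)
        slope, intercept = np.polyfit(a, values, 1)
        values = values - (intercept + slope * a)
    x = values[grouping == levels[0]].to_numpy()
    y = values[grouping == levels[1]].to_numpy()
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    if np.allclose(combined, combined[0]):
        warnings.warn("constant scores in both groups; returning p = 1", stacklevel=2)
        return {"statistic": float(len(x) * len(y) / 2), "p_value": 1.0,
                "n": (len(x), len(y)), "method": "degenerate"}
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (min(len(x), len(y)) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
            "n": (len(x), len(y)), "method": method}


def cutoff_sensitivity(scores: pd.Series, pheno: pd.DataFrame, cutoffs, evaluate_fn):
    """Re-run stratification + training + evaluation over a cutoff grid.

    ``evaluate_fn(labels)`` must return a mapping with per-stratum test
    accuracies (keys ``accuracy_NHL_hi``/``accuracy_NHL_lo`` and optionally
    ``accuracy``). A cutoff that empties a stratum is kept in the table and
    marked invalid rather than silently dropped.
    """
    lo, hi = scores.min(), scores.max()
    rows = []
    for c in cutoffs:
        if not lo <= c <= hi:
            raise ValueError(f"cutoff {c} outside observed score range [{lo}, {hi}]")
        labels, _ = stratify_cases(scores, pheno, cutoff=c)
        n_hi = int((labels == "NHL_hi").sum())
        n_lo = int((labels == "NHL_lo").sum())
        row = {"cutoff": float(c), "n_NHL_hi": n_hi, "n_NHL_lo": n_lo,
               "valid": bool(n_hi > 0 and n_lo > 0)}
        if row["valid"]:
            try:
                row.update({k: float(v) for k, v in evaluate_fn(labels).items()})
            except ValueError as err:   # e.g. a stratum too small to resample
                logger.warning("cutoff %.4g: evaluation failed (%s); row marked invalid",
                               c, err)
                row["valid"] = False
                row["error"] = str(err)
        rows.append(row)
    return pd.DataFrame(rows)
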