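"""Permutation enrichment of a CpG signature over chromatin states and
island relations.

The observed per-category counts of the signature are compared with the
counts of B random CpG lists of the same size drawn without replacement
from a universe (by default all post-filter CpGs on the array -- the array
is the sampling frame, not the whole genome). Extremeness is two-sided by
distance from the null mean, and the empirical p-value carries +1
smoothing, p = (1 + #{draws as-or-more-extreme}) / (B + 1), so it can never
be zero at finite B. BH correction runs within each categorisation.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .vocab import CHROMATIN_STATES, ISLAND_RELATIONS

DEFAULT_CATEGORIZATIONS = {
    "chromatin_state": list(CHROMATIN_STATES),
    "island_relation": list(ISLAND_RELATIONS),
}

#: Hard cap on exhaustive enumeration (number of subsets).
MAX_EXHAUSTIVE = 500_000


def _draw_counts(codes: np.ndarray, n_cat: int, size: int, B: int,
                 rng: np.random.Generator, chunk: int = 200) -> np.ndarray:
    """Category counts of B random same-size subsets of the universe."""
    n = len(codes)
    counts = np.empty((B, n_cat), dtype=np.int64)
    done = 0
    while done < B:
        b = min(chunk if n > 100_000 else B - done, B - done)
        keys = rng.random((b, n))
        picks = np.argpartition(keys, size - 1, axis=1)[:, :size]
        picked_codes = codes[picks]
        flat = (np.arange(b)[:, None] * n_cat + picked_codes).ravel()
        counts[done:done + b] = np.bincount(flat, minlength=b * n_cat).reshape(b, n_cat)
        done += b
    return counts


def _exhaustive_counts(codes: np.ndarray, n_cat: int, size: int) -> np.ndarray:
    n = len(codes)
    subsets = itertools.combinations(range(n), size)
    rows = []
    for sub in subsets:
        c = np.bincount(codes[list(sub)], minlength=n_cat)
        rows.append(c)
        if len(rows) > MAX_EXHAUSTIVE:
            raise ValueError("universe too large for exhaustive enumeration")
    return np.asarray(rows, dtype=np.int64)


def permutation_enrichment(signature, ann: pd.DataFrame, universe=None,
                           B: int = 1000, seed: int = 0, exhaustive: bool = False,
                           categorizations: dict | None = None) -> pd.DataFrame:
    """Empirical enrichment of ``signature`` against random same-size lists.

    Parameters
    ----------
    signature : iterable of CpG ids, a subset of the universe.
    ann : CpG annotation with the categorisation columns.
    universe : iterable of CpG ids (default: all annotated CpGs).
    B : number of random lists (default 1000). Ignored when ``exhaustive``.
    exhaustive : enumerate every same-size subset instead of sampling;
        the empirical p then equals the exact enumeration fraction
        ``#{subsets as-or-more extreme} / #subsets`` (the observed subset is
        itself one of them, so p >= 1/#subsets).

    Returns a DataFrame indexed by (categorization, category) with observed
    count, null mean/SD, empirical p, BH q (within categorisation) and the
    direction of departure.
    """
    signature = pd.Index(pd.unique(pd.Index(list(signature))))
    universe = ann.index if universe is None else pd.Index(pd.unique(pd.Index(list(universe))))
    if not signature.isin(universe).all():
        raise ValueError("signature must be a subset of the universe")
    if len(signature) > len(universe):
        raise ValueError("signature larger than universe")
    if B < 1:
        raise ValueError("B must be >= 1")
    if categorizations is None:
        categorizations = DEFAULT_CATEGORIZATIONS
    size = len(signature)
    rng = np.random.default_rng(seed)

    results = []
    for cat_name, vocab in categorizations.items():
        values = ann.loc[universe, cat_name].astype(str)
        codes = pd.Categorical(values, categories=vocab).codes.astype(np.int64)
        if (codes < 0).any():
            bad = values[codes < 0].unique()[:3]
            raise ValueError(f"{cat_name}: labels outside the vocabulary, e.g. {list(bad)}")
        n_cat = len(vocab)
        obs = np.bincount(
            pd.Categorical(ann.loc[signature, cat_name].astype(str),
                           categories=vocab).codes.astype(np.int64),
            minlength=n_cat)
        if exhaustive:
            null = _exhaustive_counts(codes, n_cat, size)
            b_eff = null.shape[0]
            denom = float(b_eff)
            smooth = 0
        else:
            null = _draw_counts(codes, n_cat, size, B, rng)
            b_eff = B
            denom = float(B + 1)
            smooth = 1
        null_mean = null.mean(axis=0)
        null_sd = null.std(axis=0, ddof=1) if b_eff > 1 else np.zeros(n_cat)
        d_obs = np.abs(obs - null_mean)
        as_extreme = (np.abs(null - null_mean) >= d_obs - 1e-12).sum(axis=0)
        pvals = (smooth + as_extreme) / denom
        frame = pd.DataFrame({
            "categorization": cat_name,
            "category": vocab,
            "observed": obs,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "p": pvals,
            "direction": np.where(obs > null_mean, "enriched",
                                  np.where(obs < null_mean, "depleted", "none")),
            "n_permutations": b_eff,
        })
        frame["q"] = multipletests(frame["p"].to_numpy(), method="fdr_bh")[1]
        results.append(frame)
    out = pd.concat(results, ignore_index=True).set_index(["categorization", "category"])
    return out


def direction_tally(signature, dm: pd.DataFrame, ann: pd.DataFrame,
                    category: str = "chromatin_state") -> pd.DataFrame:
    """Cross-tabulate hyper/hypo direction (reference: controls) by category.

    Every signature CpG must appear in the differential-methylation table;
    its ``direction`` column supplies the sign.
    """
    signature = pd.Index(pd.unique(pd.Index(list(signature))))
    missing = signature.difference(dm.index)
    if len(missing) > 0:
        raise KeyError(f"signature CpG(s) absent from the DM table, e.g. {missing[0]!r}")
    directions = dm.loc[signature, "direction"].astype(str)
    cats = ann.loc[signature, category].astype(str)
    tab = pd.crosstab(cats, directions)
    for col in ("hyper", "hypo"):
        if col not in tab.columns:
            tab[col] = 0
    vocab = DEFAULT_CATEGORIZATIONS.get(category)
    if vocab is not None:
        tab = tab.reindex(vocab, fill_value=0)
    tab.index.name = category
    return tab[["hyper", "hypo"]]
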