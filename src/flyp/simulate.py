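"""Synthetic 450k-like cohorts with known ground truth.

The generator emulates the statistical structure of a prospective matched
case-control methylation study of future lymphoma:

* per-CpG beta values are bimodal (low ~0.1 / high ~0.9 modes);
* bulk samples are convex mixtures of 12 sorted immune-cell reference
  profiles with Dirichlet-distributed fractions;
* a clock CpG set starts unmethylated and gains methylation linearly with a
  latent mitotic age, which future cases draw higher on average;
* planted case effects (+/- delta beta) sit preferentially in island /
  Polycomb-repressed chromatin for hyper-methylation and open-sea regions
  for hypo-methylation;
* batch effects and measurement noise are added on the M scale and
  back-transformed, keeping beta bounded;
* each future case gets an age- (+-2.5 y) and sex-matched control via
  rejection sampling.

Reference profiles are recentred so every cell type has the same mean beta
over non-clock CpGs: a sample's global mean methylation is then invariant
to its cell composition, so composition shifts cannot masquerade as global
effects and the null generator is exactly null at non-clock CpGs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import beta_to_m, m_to_beta
from .vocab import CELL_TYPES, CHROMATIN_STATES, ISLAND_RELATIONS, MEAN_BLOOD_FRACTIONS

logger = logging.getLogger(__name__)

#: Island-relation proportions of the simulated array (450k-like mix).
ISLAND_RELATION_PROPS = {"Island": 0.31, "Shore": 0.23, "Shelf": 0.10, "OpenSea": 0.36}

#: Chromatin-state proportions for background CpGs. Arbitrary but fixed;
#: roughly array-like, with quiescent/weak-transcription states dominating.
CHROMATIN_STATE_PROPS = {
    "TssA": 0.15, "TssAFlnk": 0.09, "TxFlnk": 0.01, "Tx": 0.07, "TxWk": 0.14,
    "EnhG": 0.02, "Enh": 0.08, "ZNF_Rpts": 0.01, "Het": 0.02,
    "TssBiv": 0.04, "BivFlnk": 0.02, "EnhBiv": 0.02,
    "ReprPC": 0.05, "ReprPCWk": 0.08, "Quies": 0.20,
}

#: Subtype frequencies among modelled future cases (BCLL/MM excluded).
CASE_SUBTYPE_PROPS = {"B": 41, "DLBCL": 40, "FL": 33, "MCL": 10, "LYM": 8, "LPL": 7}


@dataclass
class SimConfig:
    """Study conditions of a simulated cohort.

    ``n_samples_per_class`` is the per-arm size (future cases and matched
    controls). ``delta_beta`` is the planted case effect on the proportion
    scale; ``clock_effect_coupling`` in [0, 1] scales each case's causal
    effect by its relative mitotic age (1 = fully clock-coupled effects,
    0 = uniform effects).
    """

    n_cpgs: int = 20_000
    n_samples_per_class: int = 150
    cell_types: tuple[str, ...] = CELL_TYPES
    dirichlet_concentration: float = 30.0
    mean_fractions: dict | None = None
    n_causal_cpgs: int = 200
    delta_beta: float = 0.1
    causal_direction_split: float = 0.42  # fraction of causal CpGs that are hyper
    n_clock_cpgs: int = 385
    clock_rate: float = 0.004             # beta gained per unit mitotic age
    clock_baseline: float = 0.05
    mitotic_age_control: float = 30.0
    mitotic_age_case_shift: float = 10.0
    mitotic_age_sd: float = 8.0
    clock_effect_coupling: float = 0.0
    n_batches: int = 2
    batch_sd: float = 0.2                 # M-scale batch effect SD
    noise_sd: float = 0.1                 # M-scale measurement noise SD
    n_discriminative_per_type: int = 100
    snp_frac: float = 0.02
    sex_chrom_frac: float = 0.02
    neutrophil_alpha_case_factor: float = 1.0
    ct_effect_celltype: str | None = None
    ct_effect_n_cpgs: int = 0
    ct_effect_delta: float = 0.0
    age_mean: float = 52.5
    age_sd: float = 8.15
    seed: int = 0

    def __post_init__(self):
        for name in ("n_cpgs", "n_samples_per_class", "n_clock_cpgs", "n_batches"):
            if getattr(self, name) < 1:
                raise ValueError(f"configuration error: {name} must be >= 1")
        if self.n_causal_cpgs < 0 or self.ct_effect_n_cpgs < 0:
            raise ValueError("configuration error: CpG counts must be non-negative")
        if not 0.0 <= self.delta_beta < 1.0:
            raise ValueError("configuration error: delta_beta must lie in [0, 1)")
        if self.dirichlet_concentration <= 0:
            raise ValueError("configuration error: dirichlet_concentration must be positive")
        if not 0.0 <= self.causal_direction_split <= 1.0:
            raise ValueError("configuration error: causal_direction_split must lie in [0, 1]")
        if not 0.0 <= self.clock_effect_coupling <= 1.0:
            raise ValueError("configuration error: clock_effect_coupling must lie in [0, 1]")
        if len(self.cell_types) < 1:
            raise ValueError("configuration error: need at least one cell type")
        if self.mean_fractions is None:
            if tuple(self.cell_types) == CELL_TYPES:
                self.mean_fractions = dict(MEAN_BLOOD_FRACTIONS)
            else:
                self.mean_fractions = {t: 1.0 / len(self.cell_types) for t in self.cell_types}
        missing = [t for t in self.cell_types if t not in self.mean_fractions]
        if missing:
            raise ValueError(f"configuration error: mean_fractions missing {missing}")
        if any(self.mean_fractions[t] <= 0 for t in self.cell_types):
            raise ValueError("configuration error: mean fractions must be strictly positive")
        reserved = (
            self.n_causal_cpgs + self.n_clock_cpgs + self.ct_effect_n_cpgs
            + int(round(self.snp_frac * self.n_cpgs))
            + int(round(self.sex_chrom_frac * self.n_cpgs))
            + len(self.cell_types) * self.n_discriminative_per_type
        )
        if reserved > self.n_cpgs:
            raise ValueError(
                f"configuration error: {reserved} special CpGs requested but only "
                f"{self.n_cpgs} CpGs simulated"
            )

    @property
    def cpg_ids(self) -> pd.Index:
        return pd.Index([f"cg{i:08d}" for i in range(self.n_cpgs)], name="cpg_id")


@dataclass
class CpGRoles:
    """Disjoint index sets assigning each special role to CpG positions."""

    causal: np.ndarray
    causal_hyper: np.ndarray
    causal_hypo: np.ndarray
    clock: np.ndarray
    snp: np.ndarray
    sex: np.ndarray
    ct_effect: np.ndarray
    discriminative: dict[str, np.ndarray]


@dataclass
class GroundTruth:
    """Everything the generator knows that an analyst would have to infer."""

    true_fractions: pd.DataFrame          # sample x cell type
    true_mitotic_age: pd.Series
    causal_cpg_ids: list[str]
    causal_directions: pd.Series          # 'hyper' / 'hypo' per causal CpG
    clock_cpg_ids: list[str]
    snp_cpg_ids: list[str]
    ct_effect_cpg_ids: list[str]
    batch_of: pd.Series
    pair_of: dict[str, str] = field(default_factory=dict)  # control -> case

    @property
    def signal_cpg_ids(self) -> set[str]:
        """All CpGs planted with case-associated signal (causal + clock)."""
        return set(self.causal_cpg_ids) | set(self.clock_cpg_ids)


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stream]))


def assign_roles(cfg: SimConfig) -> CpGRoles:
    """Deterministically partition CpG positions into disjoint role sets."""
    rng = _rng(cfg, 0)
    perm = rng.permutation(cfg.n_cpgs)
    n_snp = int(round(cfg.snp_frac * cfg.n_cpgs))
    n_sex = int(round(cfg.sex_chrom_frac * cfg.n_cpgs))
    pos = 0

    def take(k):
        nonlocal pos
        out = np.sort(perm[pos:pos + k])
        pos += k
        return out

    causal = take(cfg.n_causal_cpgs)
    clock = take(cfg.n_clock_cpgs)
    snp = take(n_snp)
    sex = take(n_sex)
    ct_effect = take(cfg.ct_effect_n_cpgs)
    discriminative = {t: take(cfg.n_discriminative_per_type) for t in cfg.cell_types}
    n_hyper = int(round(cfg.causal_direction_split * cfg.n_causal_cpgs))
    return CpGRoles(
        causal=causal,
        causal_hyper=causal[:n_hyper],
        causal_hypo=causal[n_hyper:],
        clock=clock,
        snp=snp,
        sex=sex,
        ct_effect=ct_effect,
        discriminative=discriminative,
    )


def generate_reference_profiles(cfg: SimConfig) -> pd.DataFrame:
    """Cell-type x CpG mean-beta reference table.

    Per CpG, cell-type means come from a bimodal prior (modes near 0.1 and
    0.9) with small between-type jitter; ``n_discriminative_per_type`` CpGs
    per cell type have that type's mean displaced by 0.5, guaranteeing a
    between-type gap >= 0.3. Clock CpGs are near-unmethylated in every cell
    type. Rows are recentred to a common non-clock mean (see module docs).
    """
    roles = assign_roles(cfg)
    rng = _rng(cfg, 1)
    n_types = len(cfg.cell_types)
    high = rng.random(cfg.n_cpgs) < 0.5
    # case-hyper CpGs start in the low mode (Polycomb-island CpGs are lowly
    # methylated in blood and gain methylation); case-hypo CpGs start high
    high[roles.causal_hyper] = False
    high[roles.causal_hypo] = True
    base = np.where(high, rng.beta(18, 2, cfg.n_cpgs), rng.beta(2, 18, cfg.n_cpgs))
    means = base[None, :] + rng.normal(0.0, 0.02, size=(n_types, cfg.n_cpgs))
    means = np.clip(means, 0.02, 0.98)

    for t_idx, t in enumerate(cfg.cell_types):
        idx = roles.discriminative[t]
        shifted = np.where(base[idx] <= 0.5, base[idx] + 0.5, base[idx] - 0.5)
        means[t_idx, idx] = np.clip(shifted, 0.02, 0.98)

    means[:, roles.clock] = cfg.clock_baseline

    # recentre on non-clock CpGs so each type has the same non-clock mean
    non_clock = np.setdiff1d(np.arange(cfg.n_cpgs), roles.clock)
    row_means = means[:, non_clock].mean(axis=1)
    means[:, non_clock] += (row_means.mean() - row_means)[:, None]

    return pd.DataFrame(means, index=pd.Index(cfg.cell_types, name="cell_type"),
                        columns=cfg.cpg_ids)


def mix_profiles(fractions: pd.DataFrame, refs: pd.DataFrame) -> pd.DataFrame:
    """Noiseless bulk betas: CpG x sample matrix of ``fractions @ refs``."""
    f = fractions[refs.index].to_numpy(float)
    bulk = (f @ refs.to_numpy(float)).T
    return pd.DataFrame(bulk, index=refs.columns, columns=fractions.index)


def _matched_controls(cfg: SimConfig, rng, case_age, case_sex):
    """Rejection-sample one control per case: age within +-2.5 y, same sex."""
    n = len(case_age)
    ctrl_age = np.empty(n)
    for i in range(n):
        accepted = None
        for _ in range(1000):
            cand = rng.normal(cfg.age_mean, cfg.age_sd)
            if abs(cand - case_age[i]) <= 2.5:
                accepted = cand
                break
        if accepted is None:  # tail case ages: draw uniformly in the window
            accepted = case_age[i] + rng.uniform(-2.5, 2.5)
        ctrl_age[i] = accepted
    return ctrl_age, case_sex.copy()


def generate_cohort(cfg: SimConfig, refs: pd.DataFrame):
    """Simulate one matched cohort.

    Returns ``(beta, pheno, annotation, truth)`` with beta a CpG x sample
    DataFrame, pheno/annotation as in :mod:`flyp.io`, and a
    :class:`GroundTruth` carrying fractions, mitotic ages and planted sets.
    """
    if not refs.columns.equals(cfg.cpg_ids):
        raise ValueError("reference profiles do not cover the configured CpGs")
    roles = assign_roles(cfg)
    rng = _rng(cfg, 2)
    n = cfg.n_samples_per_class
    case_ids = [f"case_{i + 1:04d}" for i in range(n)]
    ctrl_ids = [f"ctrl_{i + 1:04d}" for i in range(n)]
    sample_ids = case_ids + ctrl_ids

    case_age = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n), 35.0, 75.0)
    case_sex = np.where(rng.random(n) < 0.51, "M", "F")
    ctrl_age, ctrl_sex = _matched_controls(cfg, rng, case_age, case_sex)
    age = np.concatenate([case_age, ctrl_age])
    sex = np.concatenate([case_sex, ctrl_sex])
    is_case = np.array([True] * n + [False] * n)

    subtype_names = list(CASE_SUBTYPE_PROPS)
    subtype_p = np.array(list(CASE_SUBTYPE_PROPS.values()), float)
    subtype_p /= subtype_p.sum()
    subtypes = np.concatenate([
        rng.choice(subtype_names, size=n, p=subtype_p),
        np.repeat("none", n),
    ])

    alpha = np.array([cfg.dirichlet_concentration * cfg.mean_fractions[t]
                      for t in cfg.cell_types])
    alpha_case = alpha.copy()
    if cfg.neutrophil_alpha_case_factor != 1.0:
        alpha_case[list(cfg.cell_types).index("neutrophils")] *= cfg.neutrophil_alpha_case_factor
    fractions = np.vstack([rng.dirichlet(alpha_case, n), rng.dirichlet(alpha, n)])
    fractions_df = pd.DataFrame(fractions, index=pd.Index(sample_ids, name="sample_id"),
                                columns=list(cfg.cell_types))

    mu = np.where(is_case, cfg.mitotic_age_control + cfg.mitotic_age_case_shift,
                  cfg.mitotic_age_control)
    mitotic_age = np.maximum(
        rng.normal(mu, cfg.mitotic_age_sd) + 0.2 * (age - cfg.age_mean), 0.0)

    bulk = fractions @ refs.to_numpy(float)          # samples x CpGs
    bulk[:, roles.clock] += cfg.clock_rate * mitotic_age[:, None]

    if cfg.n_causal_cpgs and cfg.delta_beta > 0:
        ma_cases = mitotic_age[is_case]
        rel = mitotic_age / max(ma_cases.mean(), 1e-9)
        scale = np.where(is_case,
                         (1.0 - cfg.clock_effect_coupling) + cfg.clock_effect_coupling * rel,
                         0.0)
        bulk[:, roles.causal_hyper] += cfg.delta_beta * scale[:, None]
        bulk[:, roles.causal_hypo] -= cfg.delta_beta * scale[:, None]

    if cfg.ct_effect_celltype is not None and cfg.ct_effect_n_cpgs:
        k = list(cfg.cell_types).index(cfg.ct_effect_celltype)
        # compartment-specific effect: bulk shift proportional to that
        # cell type's fraction in each case sample
        bulk[np.ix_(is_case, roles.ct_effect)] += cfg.ct_effect_delta * fractions[is_case][:, [k]]

    out_of_range = int(((bulk <= 0.0) | (bulk >= 1.0)).sum())
    if out_of_range:
        warnings.warn(
            f"{out_of_range} simulated beta values fell outside (0,1) before "
            "clipping; effects may be saturating", stacklevel=2)
    bulk = np.clip(bulk, 0.001, 0.999)

    batch_of = rng.permutation(2 * n) % cfg.n_batches
    if cfg.batch_sd > 0 or cfg.noise_sd > 0:
        m = beta_to_m(bulk)
        if cfg.batch_sd > 0 and cfg.n_batches > 1:
            gamma = rng.normal(0.0, cfg.batch_sd, size=(cfg.n_batches, cfg.n_cpgs))
            m += gamma[batch_of]
        if cfg.noise_sd > 0:
            m += rng.normal(0.0, cfg.noise_sd, size=m.shape)
        bulk = m_to_beta(m)

    beta = pd.DataFrame(bulk.T, index=cfg.cpg_ids, columns=sample_ids)

    pheno = pd.DataFrame({
        "age": age,
        "sex": sex,
        "batch": [f"batch{b + 1}" for b in batch_of],
        "outcome": np.where(is_case, "future_NHL", "control"),
        "subtype": subtypes,
        "bmi": np.round(rng.normal(26.24, 3.88, 2 * n), 2),
    }, index=pd.Index(sample_ids, name="sample_id"))

    annotation = _annotate(cfg, roles, rng)

    ids = cfg.cpg_ids
    truth = GroundTruth(
        true_fractions=fractions_df,
        true_mitotic_age=pd.Series(mitotic_age, index=sample_ids, name="mitotic_age"),
        causal_cpg_ids=list(ids[roles.causal]),
        causal_directions=pd.Series(
            np.where(np.isin(roles.causal, roles.causal_hyper), "hyper", "hypo"),
            index=ids[roles.causal]),
        clock_cpg_ids=list(ids[roles.clock]),
        snp_cpg_ids=list(ids[roles.snp]),
        ct_effect_cpg_ids=list(ids[roles.ct_effect]),
        batch_of=pd.Series([f"batch{b + 1}" for b in batch_of], index=sample_ids),
        pair_of=dict(zip(ctrl_ids, case_ids)),
    )
    return beta, pheno, annotation, truth


def _choice(rng, props: dict, size: int) -> np.ndarray:
    keys = list(props)
    p = np.array([props[k] for k in keys], float)
    return rng.choice(keys, size=size, p=p / p.sum())


def _annotate(cfg: SimConfig, roles: CpGRoles, rng) -> pd.DataFrame:
    g = cfg.n_cpgs
    island = _choice(rng, ISLAND_RELATION_PROPS, g)
    state = _choice(rng, CHROMATIN_STATE_PROPS, g)

    # hyper-methylated causal CpGs concentrate in islands and bivalent /
    # Polycomb-repressed chromatin; hypo-methylated ones in open sea
    hyper = roles.causal_hyper
    if len(hyper):
        flip = rng.random(len(hyper)) < 0.8
        island[hyper[flip]] = "Island"
        polycomb = {"ReprPC": 0.4, "TssBiv": 0.3, "BivFlnk": 0.1, "TssA": 0.1, "Quies": 0.1}
        state[hyper] = _choice(rng, polycomb, len(hyper))
    hypo = roles.causal_hypo
    if len(hypo):
        flip = rng.random(len(hypo)) < 0.7
        island[hypo[flip]] = "OpenSea"

    chrom = rng.choice([f"chr{i}" for i in range(1, 23)], size=g)
    half = len(roles.sex) // 2
    chrom[roles.sex[:half]] = "chrX"
    chrom[roles.sex[half:]] = "chrY"

    maf = np.full(g, np.nan)
    common = rng.random(g) < 0.1
    maf[common] = rng.uniform(0.0, 0.01, common.sum())
    maf[roles.snp] = rng.uniform(0.011, 0.5, len(roles.snp))

    start = 10_000 + 500 * np.arange(g)
    ann = pd.DataFrame({
        "chrom": chrom,
        "start": start,
        "end": start + 2,
        "island_relation": pd.Categorical(island, categories=ISLAND_RELATIONS),
        "chromatin_state": pd.Categorical(state, categories=CHROMATIN_STATES),
        "snp_maf": maf,
        "genes": [f"GENE{i // 4:05d}" for i in range(g)],
    }, index=cfg.cpg_ids)
    return ann
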