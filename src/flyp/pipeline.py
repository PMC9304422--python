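"""End-to-end orchestration: simulate/load -> preprocess -> clock ->
deconvolve -> select -> train -> evaluate -> enrich.

A run is driven by one :class:`RunConfig` (YAML-loadable), uses a single
root seed fanned out to per-stage seeds by hashing the stage name into a
``numpy.random.SeedSequence``, and writes every stage output plus a
``manifest.json`` of checksums into the output directory. Reruns with the
same config are bit-identical; wall-clock timings go to ``run.log`` only,
so they never perturb the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .classifier import (FLYPModel, covariate_baseline, evaluate,
                         misclassification_analysis, predict_flyp, train_flyp)
from .clocks import epitoc_score, stratify_cases
from .deconvolution import (build_signature, composition_summaries,
                            estimate_fractions_rpc, estimate_fractions_svr)
from .enrichment import permutation_enrichment
from .preprocess import batch_correct, beta_to_m, filter_cpgs, quantile_normalize
from .selection import (GENOME_WIDE_P, elastic_net_condense, moderated_lm,
                        threshold_stage1)
from .simulate import SimConfig, generate_cohort, generate_reference_profiles

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


def derive_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: root seed + stage-name hash into a
    SeedSequence, reduced to a 31-bit integer."""
    h = int(hashlib.sha256(stage.encode()).hexdigest()[:8], 16)
    ss = np.random.SeedSequence([int(root_seed), h])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """Configuration of one pipeline run (simulation XOR file inputs)."""

    out_dir: str
    seed: int = 0
    # exactly one input source
    sim: SimConfig | None = None
    beta_path: str | None = None
    pheno_path: str | None = None
    annotation_path: str | None = None
    refs_path: str | None = None
    clock_cpgs_path: str | None = None
    # preprocessing
    epsilon: float = 1e-3
    maf_threshold: float = 0.01
    quantile_norm: bool = False
    batch_correction: bool = True
    # split / clock
    split_frac: float = 0.7
    clock_cutoff: object = "median"
    # deconvolution
    deconv_method: str = "svr"
    sig_max_per_type: int = 100
    sig_delta_beta_min: float = 0.2
    # selection
    selection_mode: str = "fixed_p"
    selection_level: float = GENOME_WIDE_P
    enet_alpha: float = 0.5
    enet_folds: int = 10
    enet_lambdas: int = 30
    enet_lambda_min_ratio: float = 0.01
    # forest
    cv_repeats: int = 3
    cv_folds: int = 10
    tune_budget: int = 30
    n_estimators: int = 300
    # enrichment
    enrichment_B: int = 1000

    def __post_init__(self):
        file_inputs = [self.beta_path, self.pheno_path, self.annotation_path, self.refs_path]
        has_files = any(p is not None for p in file_inputs)
        if (self.sim is None) == (not has_files):
            raise ValueError("config must give exactly one input source: "
                             "a simulation config XOR input files")
        if has_files and not all(p is not None for p in file_inputs):
            raise ValueError("file input needs beta, pheno, annotation and refs paths")
        if not 0.0 < self.split_frac < 1.0:
            raise ValueError("split_frac must lie in (0, 1)")
        if self.deconv_method not in ("svr", "rpc"):
            raise ValueError("deconv_method must be 'svr' or 'rpc'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = raw.pop("sim", None)
        if sim is not None:
            sim = SimConfig(**sim)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(sim=sim, **raw)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        # out_dir is environment, not analysis configuration: keeping it out of
        # the manifest makes reruns into different directories byte-identical
        d.pop("out_dir")
        if self.sim is not None:
            d["sim"] = dataclasses.asdict(self.sim)
            d["sim"]["cell_types"] = list(d["sim"]["cell_types"])
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stratified_split(labels: pd.Series, train_frac: float, seed: int):
    from sklearn.model_selection import train_test_split
    idx = np.asarray(labels.index)
    train, test = train_test_split(idx, train_size=train_frac,
                                   stratify=labels.to_numpy(), random_state=seed)
    return list(train), list(test)


def evaluate_labels(m: pd.DataFrame, labels: pd.Series, train_idx, test_idx,
                    selection_mode="fixed_p", selection_level=GENOME_WIDE_P,
                    enet_alpha=0.5, enet_folds=10, enet_lambdas=30,
                    enet_lambda_min_ratio=0.01, covariates=None,
                    seed: int = 0, **train_kwargs) -> dict:
    """Selection + forest + evaluation for one fixed labelling and split.

    The workhorse behind cutoff-sensitivity analyses: stage-1/stage-2
    selection and training see only the training split.
    """
    dm = moderated_lm(m[train_idx], labels.loc[train_idx],
                      covariates=None if covariates is None else covariates.loc[train_idx])
    survivors = threshold_stage1(dm, mode=selection_mode, level=selection_level)
    if not survivors:
        return {"accuracy": np.nan, "n_features": 0}
    features = elastic_net_condense(m.loc[survivors, train_idx], labels.loc[train_idx],
                                    alpha=enet_alpha, folds=enet_folds, seed=seed,
                                    n_lambdas=enet_lambdas,
                                    lambda_min_ratio=enet_lambda_min_ratio)
    model = train_flyp(m.loc[features.cpgs, train_idx].T, labels.loc[train_idx],
                       seed=seed, **train_kwargs)
    pred = predict_flyp(model, m.loc[features.cpgs, test_idx])
    report = evaluate(labels.loc[test_idx], pred["label"],
                      proba=pred[[c for c in pred.columns if c.startswith("p_")]])
    out = {"accuracy": report.accuracy, "n_features": len(features.cpgs)}
    for lv, acc in report.stratum_accuracy.items():
        out[f"accuracy_{lv}"] = acc
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage, persist outputs and return the manifest (plus
    in-memory results under the ``results`` key)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root_logger = logging.getLogger("flyp")
    root_logger.addHandler(handler)

    manifest: dict = {
        "version": __version__,
        "config": cfg.to_jsonable(),
        "seeds": {},
        "stages": [],
        "checksums": {},
    }
    results: dict = {}
    written: list[Path] = []

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        written.append(path)

    current_stage = "init"
    t_run = time.perf_counter()
    try:
        # ---------------- inputs ----------------
        current_stage = "inputs"
        t0 = time.perf_counter()
        if cfg.sim is not None:
            sim_seed = derive_seed(cfg.seed, "simulate")
            sim = dataclasses.replace(cfg.sim, seed=sim_seed)
            manifest["seeds"]["simulate"] = sim_seed
            refs = generate_reference_profiles(sim)
            beta, pheno, ann, truth = generate_cohort(sim, refs)
            clock_cpgs = truth.clock_cpg_ids
            header = [f"generator seed: {sim_seed}", f"root seed: {cfg.seed}"]
            emit("beta.tsv", lambda p: fio.write_beta(beta, p, header_comments=header))
            emit("pheno.tsv", lambda p: fio.write_pheno(pheno, p))
            emit("annotation.bed.tsv", lambda p: fio.write_annotation(ann, p))
            emit("refs.tsv", lambda p: fio.write_matrix(refs.T, p))
            emit("clock_cpgs.txt", lambda p: fio.write_cpg_list(clock_cpgs, p))
            emit("true_fractions.tsv", lambda p: fio.write_pheno(truth.true_fractions, p))
            emit("truth.json", lambda p: p.write_text(json.dumps({
                "causal_cpg_ids": truth.causal_cpg_ids,
                "clock_cpg_ids": truth.clock_cpg_ids,
                "snp_cpg_ids": truth.snp_cpg_ids,
                "mitotic_age": truth.true_mitotic_age.round(6).to_dict(),
            }, sort_keys=True)))
        else:
            refs = fio.read_matrix(cfg.refs_path).T  # stored CpG x type -> type x CpG
            beta = fio.read_beta(cfg.beta_path)
            pheno = fio.read_pheno(cfg.pheno_path)
            ann = fio.read_annotation(cfg.annotation_path)
            truth = None
            clock_cpgs = (fio.read_cpg_list(cfg.clock_cpgs_path)
                          if cfg.clock_cpgs_path else [])
        manifest["stages"].append("inputs")
        logger.info("stage inputs done in %.1fs", time.perf_counter() - t0)

        # ---------------- preprocess ----------------
        current_stage = "preprocess"
        t0 = time.perf_counter()
        if cfg.quantile_norm:
            beta = quantile_normalize(beta)
        beta_f = filter_cpgs(beta, ann, maf_threshold=cfg.maf_threshold)
        m = beta_to_m(beta_f, epsilon=cfg.epsilon)
        n_batches = pheno["batch"].nunique()
        if cfg.batch_correction and n_batches >= 2:
            m = batch_correct(m, pheno.loc[m.columns, "batch"],
                              covariates=pheno.loc[m.columns, ["outcome"]])
        manifest["stages"].append("preprocess")
        logger.info("stage preprocess done in %.1fs", time.perf_counter() - t0)

        # ---------------- clock & labels ----------------
        current_stage = "clock"
        t0 = time.perf_counter()
        if not clock_cpgs:
            raise ValueError("no clock CpG list available")
        scores = epitoc_score(beta_f, clock_cpgs)
        # provisional labels (all-case median) only balance the split;
        # the cutoff is then recomputed on training cases and frozen
        provisional, _ = stratify_cases(scores, pheno)
        split_seed = derive_seed(cfg.seed, "split")
        manifest["seeds"]["split"] = split_seed
        train_idx, test_idx = _stratified_split(provisional, cfg.split_frac, split_seed)
        labels, cutoff_used = stratify_cases(scores, pheno, cutoff=cfg.clock_cutoff,
                                             training_samples=train_idx)
        results["cutoff_used"] = cutoff_used
        emit("clock.tsv", lambda p: fio.write_pheno(
            pd.DataFrame({"epitoc": scores, "three_class": labels.astype(str)}), p))
        manifest["stages"].append("clock")
        logger.info("stage clock done in %.1fs (cutoff %.4f)", time.perf_counter() - t0,
                    cutoff_used)

        # ---------------- deconvolution ----------------
        current_stage = "deconvolution"
        t0 = time.perf_counter()
        sig = build_signature(refs, max_per_type=cfg.sig_max_per_type,
                              delta_beta_min=cfg.sig_delta_beta_min)
        estimator = estimate_fractions_svr if cfg.deconv_method == "svr" else estimate_fractions_rpc
        fractions = estimator(beta_f, sig)
        composition = composition_summaries(fractions, pheno)
        emit("signature.tsv", lambda p: fio.write_matrix(sig.profiles, p))
        emit("fractions.tsv", lambda p: fio.write_pheno(fractions.fractions, p))
        emit("composition.tsv", lambda p: composition.to_csv(p, sep="\t"))
        manifest["stages"].append("deconvolution")
        logger.info("stage deconvolution done in %.1fs", time.perf_counter() - t0)

        # ---------------- selection ----------------
        current_stage = "selection"
        t0 = time.perf_counter()
        sel_seed = derive_seed(cfg.seed, "selection")
        manifest["seeds"]["selection"] = sel_seed
        covariates = pheno.loc[m.columns, ["age", "sex"]]
        dm = moderated_lm(m[train_idx], labels.loc[train_idx],
                          covariates=covariates.loc[train_idx])
        survivors = threshold_stage1(dm, mode=cfg.selection_mode, level=cfg.selection_level)
        if not survivors:
            raise RuntimeError("stage 1 selected no CpGs; cannot continue to the elastic net")
        features = elastic_net_condense(m.loc[survivors, train_idx], labels.loc[train_idx],
                                        alpha=cfg.enet_alpha, folds=cfg.enet_folds,
                                        seed=sel_seed, n_lambdas=cfg.enet_lambdas,
                                        lambda_min_ratio=cfg.enet_lambda_min_ratio)
        emit("dm.tsv", lambda p: dm.round(6).to_csv(p, sep="\t"))
        emit("features.tsv", lambda p: features.coefficients.round(6).to_csv(p, sep="\t"))
        manifest["stages"].append("selection")
        logger.info("stage selection done in %.1fs (%d survivors -> %d features)",
                    time.perf_counter() - t0, len(survivors), len(features.cpgs))

        # ---------------- training & evaluation ----------------
        current_stage = "training"
        t0 = time.perf_counter()
        train_seed = derive_seed(cfg.seed, "train")
        manifest["seeds"]["train"] = train_seed
        model = train_flyp(m.loc[features.cpgs, train_idx].T, labels.loc[train_idx],
                           cv_repeats=cfg.cv_repeats, cv_folds=cfg.cv_folds,
                           tune_budget=cfg.tune_budget, n_estimators=cfg.n_estimators,
                           seed=train_seed)
        pred = predict_flyp(model, m.loc[features.cpgs, test_idx])
        report = evaluate(labels.loc[test_idx], pred["label"],
                          proba=pred[[c for c in pred.columns if c.startswith("p_")]])
        misclass = misclassification_analysis(labels.loc[test_idx], pred["label"],
                                              scores, age=pheno["age"])
        _, baseline = covariate_baseline(pheno, fractions.fractions, labels,
                                         train_idx, test_idx, seed=train_seed,
                                         cv_repeats=cfg.cv_repeats, cv_folds=cfg.cv_folds,
                                         tune_budget=min(cfg.tune_budget, 14),
                                         n_estimators=cfg.n_estimators)
        model.save(out / "model.joblib")
        written.append(out / "model.joblib")
        emit("predictions.tsv", lambda p: pred.round(6).to_csv(p, sep="\t"))
        metrics_payload = {
            "flyp": report.to_dict(),
            "covariate_baseline": baseline.to_dict(),
            "misclassification": None if misclass is None else misclass.to_dict(),
            "cutoff_used": cutoff_used,
        }
        emit("metrics.json", lambda p: p.write_text(
            json.dumps(metrics_payload, sort_keys=True, indent=2, default=float)))
        manifest["stages"].append("training")
        logger.info("stage training done in %.1fs (test accuracy %.3f)",
                    time.perf_counter() - t0, report.accuracy)

        # ---------------- enrichment ----------------
        current_stage = "enrichment"
        t0 = time.perf_counter()
        enrich_seed = derive_seed(cfg.seed, "enrichment")
        manifest["seeds"]["enrichment"] = enrich_seed
        enrich = permutation_enrichment(features.cpgs, ann, universe=m.index,
                                        B=cfg.enrichment_B, seed=enrich_seed)
        emit("enrichment.tsv", lambda p: enrich.round(6).to_csv(p, sep="\t"))
        manifest["stages"].append("enrichment")
        logger.info("stage enrichment done in %.1fs", time.perf_counter() - t0)

        results.update({
            "train_idx": train_idx, "test_idx": test_idx,
            "scores": scores, "labels": labels, "survivors": survivors,
            "features": features, "model": model, "report": report,
            "baseline": baseline, "fractions": fractions, "enrichment": enrich,
            "truth": truth, "dm": dm,
        })
    except Exception:
        manifest["failed_stage"] = current_stage
        (out / "manifest.json").write_text(
            json.dumps(manifest, sort_keys=True, indent=2, default=str))
        root_logger.removeHandler(handler)
        handler.close()
        raise

    for path in written:
        manifest["checksums"][path.name] = _sha256(path)
    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2, default=str))
    logger.info("pipeline finished in %.1fs", time.perf_counter() - t_run)
    root_logger.removeHandler(handler)
    handler.close()
    manifest["results"] = results
    return manifest
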