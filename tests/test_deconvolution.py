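"""Signature construction and fraction recovery against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import nnls

from flyp.deconvolution import (build_signature, celltype_specific_dm,
                                compare_fraction_methods, composition_summaries,
                                estimate_fractions_rpc, estimate_fractions_svr)
from flyp.simulate import SimConfig, generate_cohort, generate_reference_profiles, mix_profiles


@pytest.fixture(scope="module")
def refs_and_sig():
    cfg = SimConfig(n_cpgs=2500, n_discriminative_per_type=40, seed=21)
    refs = generate_reference_profiles(cfg)
    sig = build_signature(refs, max_per_type=40, delta_beta_min=0.2)
    return refs, sig


def nnls_fractions(bulk: pd.DataFrame, sig) -> pd.DataFrame:
    """Brute-force oracle: non-negative least squares, renormalised."""
    x = sig.profiles.to_numpy(float)
    rows = []
    for s in bulk.columns:
        coef, _ = nnls(x, bulk.loc[sig.cpgs, s].to_numpy(float))
        rows.append(coef / coef.sum())
    return pd.DataFrame(rows, index=bulk.columns, columns=sig.cell_types)


class TestBuildSignature:
    def test_perfectly_discriminative_construction(self):
        """One constructed marker CpG per type -> the signature is exactly those."""
        types = ["t1", "t2", "t3"]
        cpgs = ["m1", "m2", "m3"]
        vals = np.full((3, 3), 0.1)
        np.fill_diagonal(vals, 0.9)
        refs = pd.DataFrame(vals, index=types, columns=cpgs)
        sig = build_signature(refs, max_per_type=5, delta_beta_min=0.3)
        assert sorted(sig.cpgs) == cpgs
        assert set(sig.provenance["contrast_type"]) == set(types)

    def test_identical_profiles_rejected(self):
        refs = pd.DataFrame(np.full((2, 10), 0.5), index=["t1", "t2"],
                            columns=[f"cg{i}" for i in range(10)])
        with pytest.raises(ValueError, match="t1"):
            build_signature(refs)

    def test_every_type_contributes(self, refs_and_sig):
        refs, sig = refs_and_sig
        assert set(sig.provenance["contrast_type"]) == set(refs.index)
        assert sig.cpgs.is_unique
        assert np.isfinite(sig.condition_number)

    def test_deterministic(self, refs_and_sig):
        refs, sig = refs_and_sig
        again = build_signature(refs, max_per_type=40, delta_beta_min=0.2)
        pd.testing.assert_frame_equal(sig.profiles, again.profiles)


class TestFractionRecovery:
    @pytest.fixture(scope="class")
    def noiseless(self, refs_and_sig):
        refs, sig = refs_and_sig
        gen = np.random.default_rng(3)
        fr = gen.dirichlet(np.full(12, 3.0), 12)
        fr_df = pd.DataFrame(fr, index=[f"s{i}" for i in range(12)], columns=refs.index)
        bulk = mix_profiles(fr_df, refs)
        return refs, sig, fr_df, bulk

    def test_pure_sample_identity(self, refs_and_sig):
        refs, sig = refs_and_sig
        pure = sig.profiles[["neutrophils"]].rename(columns={"neutrophils": "p1"})
        for est in (estimate_fractions_svr, estimate_fractions_rpc):
            out = est(pure, sig)
            assert out.fractions.loc["p1", "neutrophils"] == pytest.approx(1.0, abs=1e-3)

    def test_noiseless_mixture_recovery_all_methods(self, noiseless):
        refs, sig, fr_df, bulk = noiseless
        truth = fr_df.to_numpy()
        svr = estimate_fractions_svr(bulk, sig).fractions.to_numpy()
        rpc = estimate_fractions_rpc(bulk, sig).fractions.to_numpy()
        oracle = nnls_fractions(bulk, sig).to_numpy()
        assert np.abs(oracle - truth).max() < 1e-8
        assert np.abs(svr - truth).max() < 1e-2
        assert np.abs(rpc - truth).max() < 1e-2
        assert np.abs(svr - rpc).max() < 1e-2

    def test_estimates_invariant_to_signature_cpg_order(self, noiseless):
        refs, sig, fr_df, bulk = noiseless
        import dataclasses
        perm = np.random.default_rng(1).permutation(len(sig.cpgs))
        shuffled = dataclasses.replace(
            sig, profiles=sig.profiles.iloc[perm], provenance=sig.provenance.iloc[perm])
        a = estimate_fractions_rpc(bulk, sig).fractions
        b = estimate_fractions_rpc(bulk, shuffled).fractions
        assert np.abs(a.to_numpy() - b.to_numpy()).max() < 1e-9

    def test_rpc_beats_ols_under_corruption(self, noiseless):
        """Flipping 5% of signature CpG betas: the Huber fit stays closer."""
        refs, sig, fr_df, bulk = noiseless
        gen = np.random.default_rng(7)
        corrupted = bulk.copy()
        flip = gen.choice(len(sig.cpgs), size=int(0.05 * len(sig.cpgs)), replace=False)
        flip_ids = sig.cpgs[flip]
        corrupted.loc[flip_ids] = 1.0 - corrupted.loc[flip_ids]
        rpc = estimate_fractions_rpc(corrupted, sig).fractions.to_numpy()
        # OLS oracle on corrupted data (clipped + renormalised like the others)
        x = np.column_stack([np.ones(len(sig.cpgs)), sig.profiles.to_numpy(float)])
        ols_rows = []
        for s in corrupted.columns:
            coef = np.linalg.lstsq(x, corrupted.loc[sig.cpgs, s].to_numpy(), rcond=None)[0][1:]
            coef = np.clip(coef, 0, None)
            ols_rows.append(coef / coef.sum())
        ols = np.asarray(ols_rows)
        truth = fr_df.to_numpy()
        assert np.abs(rpc - truth).mean() < np.abs(ols - truth).mean()

    def test_cohort_recovery_with_noise(self, small_cohort):
        refs, truth = small_cohort["refs"], small_cohort["truth"]
        sig = build_signature(refs, max_per_type=30)
        est = estimate_fractions_rpc(small_cohort["beta"], sig)
        corr = [np.corrcoef(est.fractions[t], truth.true_fractions[t])[0, 1]
                for t in refs.index]
        assert min(corr) > 0.9


class TestCompareFractionMethods:
    def test_identical_inputs_give_one(self, small_cohort, refs_and_sig):
        refs, sig = refs_and_sig
        gen = np.random.default_rng(0)
        from flyp.deconvolution import CellFractions
        fr = pd.DataFrame(gen.dirichlet(np.full(12, 3.0), 30),
                          index=[f"s{i}" for i in range(30)], columns=refs.index)
        cf = CellFractions(fractions=fr, diagnostics=pd.DataFrame(index=fr.index))
        assert (compare_fraction_methods(cf, cf).round(12) == 1.0).all()

    def test_independent_fractions_near_zero(self):
        from flyp.deconvolution import CellFractions
        gen = np.random.default_rng(1)
        idx = [f"s{i}" for i in range(200)]
        cols = [f"t{i}" for i in range(5)]
        f1 = CellFractions(pd.DataFrame(gen.dirichlet(np.ones(5), 200), index=idx, columns=cols),
                           pd.DataFrame(index=idx))
        f2 = CellFractions(pd.DataFrame(gen.dirichlet(np.ones(5), 200), index=idx, columns=cols),
                           pd.DataFrame(index=idx))
        assert compare_fraction_methods(f1, f2).abs().max() < 0.2

    def test_anticorrelated_pair(self):
        from flyp.deconvolution import CellFractions
        a = pd.DataFrame({"t1": [0.1, 0.5, 0.9], "t2": [0.9, 0.5, 0.1]}, index=list("abc"))
        b = pd.DataFrame({"t1": [0.9, 0.5, 0.1], "t2": [0.1, 0.5, 0.9]}, index=list("abc"))
        out = compare_fraction_methods(CellFractions(a, pd.DataFrame(index=a.index)),
                                       CellFractions(b, pd.DataFrame(index=b.index)))
        assert np.allclose(out, -1.0)


class TestCellTypeSpecificDM:
    @pytest.fixture(scope="class")
    def planted(self):
        cfg = SimConfig(n_cpgs=3000, n_samples_per_class=100, n_causal_cpgs=0,
                        n_clock_cpgs=50, n_discriminative_per_type=30, delta_beta=0.0,
                        noise_sd=0.03, batch_sd=0.0, clock_rate=0.0,
                        ct_effect_celltype="memory_B", ct_effect_n_cpgs=30,
                        ct_effect_delta=0.8, seed=9)
        refs = generate_reference_profiles(cfg)
        beta, pheno, ann, truth = generate_cohort(cfg, refs)
        sig = build_signature(refs, max_per_type=30)
        fr = estimate_fractions_rpc(beta, sig)
        return beta, pheno, ann, truth, fr

    def test_memory_b_effect_recovered_with_correct_sign(self, planted):
        beta, pheno, ann, truth, fr = planted
        ct = celltype_specific_dm(beta, fr, pheno["outcome"], annotation=ann,
                                  island_only=False)
        hit = ct.loc[truth.ct_effect_cpg_ids]
        assert (hit["effect_memory_B"] > 0).all()
        assert hit["p_memory_B"].max() < 1e-6
        null = ct.drop(index=truth.ct_effect_cpg_ids)
        assert (null["p_memory_B"] < 0.05).mean() < 0.10

    def test_permuted_outcome_gives_uniform_p(self, planted):
        from scipy.stats import kstest
        beta, pheno, ann, truth, fr = planted
        gen = np.random.default_rng(2)
        permuted = pd.Series(gen.permutation(pheno["outcome"].to_numpy()),
                             index=pheno.index)
        ct = celltype_specific_dm(beta, fr, permuted, annotation=ann, island_only=False)
        pcols = [c for c in ct.columns if c.startswith("p_")]
        pooled = ct[pcols].to_numpy().ravel()
        assert (pooled < 0.05).mean() < 0.08

    def test_island_only_default_scope(self, planted):
        beta, pheno, ann, truth, fr = planted
        ct = celltype_specific_dm(beta, fr, pheno["outcome"], annotation=ann)
        assert (ann.loc[ct.index, "island_relation"] == "Island").all()


class TestCompositionSummaries:
    def test_nlr_hand_arithmetic_and_missing_guard(self):
        from flyp.deconvolution import CellFractions
        fr = pd.DataFrame({
            "neutrophils": [0.5, 0.4], "memory_B": [0.25, 0.0], "NK": [0.0, 0.0],
            "naive_B": [0.0, 0.0], "naive_T_helper": [0.0, 0.0],
            "memory_T_helper": [0.0, 0.0], "regulatory_T": [0.0, 0.0],
            "naive_cytotoxic_CD8": [0.0, 0.0], "memory_cytotoxic_CD8": [0.0, 0.0],
            "monocytes": [0.25, 0.6], "eosinophils": [0.0, 0.0], "basophils": [0.0, 0.0],
        }, index=["s1", "s2"])
        pheno = pd.DataFrame({"outcome": ["future_NHL", "control"]}, index=fr.index)
        cf = CellFractions(fr, pd.DataFrame(index=fr.index))
        out = composition_summaries(cf, pheno)
        # s1: 0.5 / 0.25 = 2; s2 has zero lymphocytes -> missing
        assert out.loc["NLR", "case_mean"] == pytest.approx(2.0)
        assert out.loc["NLR", "n_missing"] == 1

    def test_elevated_case_nlr_detected(self):
        cfg = SimConfig(n_cpgs=1200, n_samples_per_class=150, n_causal_cpgs=0,
                        n_clock_cpgs=30, n_discriminative_per_type=10, delta_beta=0.0,
                        noise_sd=0.05, batch_sd=0.0, clock_rate=0.0,
                        neutrophil_alpha_case_factor=1.5, seed=13)
        refs = generate_reference_profiles(cfg)
        beta, pheno, ann, truth = generate_cohort(cfg, refs)
        from flyp.deconvolution import CellFractions
        cf = CellFractions(truth.true_fractions, pd.DataFrame(index=pheno.index))
        out = composition_summaries(cf, pheno)
        assert out.loc["NLR", "p_value"] < 0.05
        assert out.loc["NLR", "case_mean"] > out.loc["NLR", "control_mean"]
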