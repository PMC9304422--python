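"""Shared fixtures: small simulated cohorts reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from flyp.simulate import SimConfig, generate_cohort, generate_reference_profiles


@pytest.fixture(scope="session")
def small_cfg():
    """A small but fully featured cohort configuration."""
    return SimConfig(
        n_cpgs=3000, n_samples_per_class=40, n_causal_cpgs=60, n_clock_cpgs=100,
        n_discriminative_per_type=30, delta_beta=0.2, clock_rate=0.004,
        noise_sd=0.1, batch_sd=0.2, seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    refs = generate_reference_profiles(small_cfg)
    beta, pheno, ann, truth = generate_cohort(small_cfg, refs)
    return {"cfg": small_cfg, "refs": refs, "beta": beta, "pheno": pheno,
            "ann": ann, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_matrix():
    """20 CpGs x 16 samples of heteroskedastic Gaussian M values."""
    gen = np.random.default_rng(42)
    vals = gen.normal(0.0, 1.0, (20, 16)) * gen.uniform(0.5, 2.0, 20)[:, None]
    m = pd.DataFrame(vals, index=[f"cg{i:05d}" for i in range(20)],
                     columns=[f"s{j}" for j in range(16)])
    labels = pd.Series(["case"] * 8 + ["control"] * 8, index=m.columns)
    return m, labels
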