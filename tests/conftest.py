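import numpy as np
import pandas as pd
import pytest

from sexhet.synthetic_data import SimConfig, simulate_annotations, simulate_sumstats


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale scenario shared across module tests."""
    return SimConfig(n_snps=20_000, n_traits=3, seed=11)


@pytest.fixture(scope="session")
def small_scenario(small_config):
    tables, truth = simulate_sumstats(small_config)
    ann, ld = simulate_annotations(small_config, truth)
    return {"config": small_config, "tables": tables, "truth": truth,
            "ann": ann, "ld": ld}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_sumstats(n=10, seed=0, **overrides):
    """Small well-formed canonical summary-statistics table."""
    r = np.random.default_rng(seed)
    maf = r.uniform(0.05, 0.5, n)
    df = pd.DataFrame({
        "snp_id": [f"rs{i}" for i in range(n)],
        "chrom": "chr1",
        "pos": np.arange(1, n + 1) * 1000,
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": maf,
        "beta": r.normal(0, 0.02, n),
        "se": r.uniform(0.005, 0.02, n),
        "pvalue": r.uniform(1e-6, 1, n),
        "n": 10_000,
    })
    for k, v in overrides.items():
        df[k] = v
    return df
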