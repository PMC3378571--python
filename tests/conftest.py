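import numpy as np
import pytest

from bimr.synthetic import (
    ScenarioConfig,
    SnpDef,
    TrueParams,
    default_scenario,
    simulate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def small_cohort():
    """QC-clean cohort, raw-scale units, forward-causal truth."""
    return simulate_cohort(default_scenario(n_samples=1500, seed=42))


@pytest.fixture(scope="session")
def recovery_params():
    """Generative truth used in the parameter-recovery scenarios."""
    return TrueParams(
        direction="adiposity_to_sua",
        beta_causal=0.30,
        conf_adiposity=0.45,
        conf_sua=0.45,
        r2_adip_instrument=0.006,
        r2_sua_instrument=0.0316,
        trait_loadings={"weight": 1.0},
    )


def make_recovery_config(params, n=5000, seed=0, **overrides):
    snps = (
        SnpDef("snpA", "FTO", 0.25),
        SnpDef("snpB", "FTO", 0.30),
        SnpDef("snpC", "TMEM18", 0.40),
        SnpDef("snpG", "SLC2A9", 0.30),
    )
    kwargs = dict(
        n_samples=n,
        snps=snps,
        true_params=params,
        seed=seed,
        raw_scale=False,
        adiposity_score_snps=("snpA", "snpB", "snpC"),
        sua_snp="snpG",
    )
    kwargs.update(overrides)
    return ScenarioConfig(**kwargs)
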