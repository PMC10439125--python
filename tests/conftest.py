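import numpy as np
import pytest

from flowgwas.synthdata import (
    Block,
    SimConfig,
    simulate_covariates,
    simulate_genotypes,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 2000-sample cohort with one causal variant per LD block."""
    cfg = SimConfig(
        n_samples=2000,
        seed=42,
        blocks=[
            Block("1", 20, (0.3, 0.5), 0.6),
            Block("2", 20, (0.3, 0.5), 0.6),
            Block("3", 20, (0.3, 0.5), 0.6),
        ],
        causal_effects=[
            ("1:1050000:A:G", "trait1", 0.3),
            ("2:1100000:A:G", "trait1", 0.3),
            ("3:1150000:A:G", "trait1", 0.3),
        ],
        noise_sd=1.0,
    )
    g = simulate_genotypes(cfg)
    cov = simulate_covariates(cfg.n_samples, seed=43)
    pheno, truth = simulate_phenotypes(g, cov, cfg)
    return g, cov, pheno, truth, cfg


def standardize(y):
    y = np.asarray(y, dtype=float)
    return (y - y.mean()) / y.std()
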