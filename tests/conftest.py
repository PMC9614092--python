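import numpy as np
import pytest

import sketchgs as sg


@pytest.fixture(scope="session")
def small_trial():
    """A small multi-environment trial with genomic and GxE signal."""
    cfg = sg.SimConfig(
        n_lines=60,
        n_markers=200,
        n_envs=4,
        block_size=20,
        within_block_rho=0.6,
        n_causal=30,
        seed=11,
        var_components=sg.TrueVariances(
            mu=5.0, var_E=1.0, var_g=1.0, var_gE=0.5, var_eps=1.0
        ),
    )
    geno = sg.simulate_genotypes(cfg)
    pheno, truth = sg.simulate_phenotypes(geno, cfg)
    X = sg.standardize(sg.clean_markers(geno)[0])
    return cfg, geno, pheno, truth, X


@pytest.fixture(scope="session")
def small_kernels(small_trial):
    _, _, pheno, _, X = small_trial
    return sg.build_kernels(X, pheno)
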