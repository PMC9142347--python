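import numpy as np
import pandas as pd
import pytest

import metstab as ms


@pytest.fixture(scope="session")
def small_met():
    """Balanced 8-genotype, 2-location, 3-year, 2-rep MET with known truth."""
    cfg = ms.SimulationConfig(
        n_genotypes=8, n_locations=2, n_years=3, n_replicates=2,
        mu=100.0, sigma2_g=4.0, sigma2_l=2.0, sigma2_a=3.0, sigma2_la=2.0,
        sigma2_block=1.0, sigma2_gl=1.0, sigma2_ga=1.5, sigma2_gla=2.0,
        sigma2_e=3.0, seed=11)
    plots, truth = ms.simulate_met(cfg)
    return cfg, plots, truth


@pytest.fixture()
def rcbd_env():
    """One environment of a balanced RCBD trial, as a tidy frame."""
    cfg = ms.SimulationConfig(
        n_genotypes=10, n_locations=1, n_years=1, n_replicates=3,
        mu=50.0, sigma2_g=4.0, sigma2_l=0, sigma2_a=0, sigma2_la=0,
        sigma2_block=2.0, sigma2_gl=0, sigma2_ga=0, sigma2_gla=0,
        sigma2_e=2.0, seed=7)
    plots, _ = ms.simulate_met(cfg)
    return plots


def _random_blue_matrix(rng, n_gen, n_env):
    vals = rng.normal(50.0, 10.0, (n_gen, n_env))
    gens = [f"g{i:02d}" for i in range(n_gen)]
    envs = [ms.EnvironmentKey("E", 2000 + j) for j in range(n_env)]
    return ms.BlueMatrix(pd.DataFrame(vals, index=gens, columns=envs))


@pytest.fixture()
def blue_matrix_factory():
    return _random_blue_matrix


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
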