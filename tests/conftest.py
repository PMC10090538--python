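import numpy as np
import pytest

from triclass.synthetic import GeneratorConfig, generate


@pytest.fixture(scope="session")
def tiny_config():
    """Small all-dimensions-shrunk config; structure identical to the default."""
    return GeneratorConfig(n_lines=40, n_envs=8, n_secondary=6, n_weather_vars=4,
                           n_days=60, n_snps=80, window=(20, 34),
                           snp_support=(3, 11, 27), snp_effects=(0.4, 0.4, 0.4),
                           seed=11)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return generate(tiny_config)


@pytest.fixture(scope="session")
def desk_dataset():
    """Desk-scale dataset (150 lines, 500 SNPs) shared across slower tests."""
    return generate(GeneratorConfig.test_scale(seed=1))


def logistic_sample(rng, n, coefs, n_noise=0):
    """Binary response from a logistic model on standardized predictors."""
    T = len(coefs) + n_noise
    Z = rng.normal(size=(n, T))
    Z = (Z - Z.mean(0)) / Z.std(0, ddof=1)
    eta = Z[:, :len(coefs)] @ np.asarray(coefs)
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return Z, y
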