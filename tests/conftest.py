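import pytest

from ricenni.synthetic import NoiseSpec, TrialConfig, generate_trial


@pytest.fixture(scope="session")
def noisefree_config():
    return TrialConfig(noise=NoiseSpec.none(), seed=11)


@pytest.fixture(scope="session")
def noisefree_trial(noisefree_config):
    return generate_trial(noisefree_config)


@pytest.fixture(scope="session")
def indica_config():
    return TrialConfig(
        true_curve=(2.78, 0.46),
        plateau_true=(2.266, 0.86, 0.82, 0.99),
        y_max=9505.8,
        apgn_true=2.13,
        cultivar="JY-6135",
        noise=NoiseSpec.none(),
        seed=12,
    )


@pytest.fixture(scope="session")
def noisy_trial():
    return generate_trial(TrialConfig(seed=13))
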