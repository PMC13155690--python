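import numpy as np
import pytest

from avci.design import ExperimentDesign, sample_experiment
from avci.engine import ObserverModel
from avci.shapes import ContextParams, NoiseModel, PriorModel


def make_vanilla(sigma_V=2.0, sigma_A=4.0, sigma_s=10.0, strategy="PM", **ctx):
    """Const noise + SingleGaussian prior observer (conjugate-Gaussian oracle
    territory)."""
    defaults = dict(lapse=0.0, sigma_motor=0.8, rho_A=1.0, p_same=0.5)
    defaults.update(ctx)
    return ObserverModel(
        prior=PriorModel("SingleGaussian", {"sigma_s": sigma_s}),
        noise_V=NoiseModel("Const", {"sigma0": sigma_V}, "V"),
        noise_A=NoiseModel("Const", {"sigma0": sigma_A}, "A"),
        strategy=strategy,
        context=ContextParams(**defaults),
    )


@pytest.fixture
def vanilla_model():
    return make_vanilla()


@pytest.fixture(scope="session")
def small_design():
    return ExperimentDesign(n_participants=2,
                            trials_per_task={"UV": 30, "UA": 30, "B": 40, "BC": 40})


@pytest.fixture(scope="session")
def small_stimuli(small_design):
    return sample_experiment(small_design, seed=7)


@pytest.fixture(scope="session")
def rich_model():
    """A heteroskedastic, mixture-prior observer with every context effect on."""
    return ObserverModel(
        prior=PriorModel("GaussianLaplace", {"sigma_s": 8.0, "b": 2.0, "omega": 0.5}),
        noise_V=NoiseModel("Exp", {"sigma0": 1.0, "k1": 3.0, "k2": 0.3}, "V"),
        noise_A=NoiseModel("Exp", {"sigma0": 2.5, "k1": 4.0, "k2": 0.2}, "A"),
        strategy="PM",
        context=ContextParams(alpha_med=1.8, alpha_low=3.0, beta_V=1.15, beta_A=1.5,
                              rho_A=4.0 / 3.0, p_same=0.55, lapse=0.05,
                              sigma_motor=1.0),
    )
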