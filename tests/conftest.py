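import numpy as np
import pytest

import itcbayes as ib


class ToyModel:
    """Minimal model-API stub (param_names / priors / log_posterior) for
    exercising the ensemble-sampler driver on analytically known targets."""

    def __init__(self, priors: ib.PriorSet, log_post):
        self.priors = priors
        self._log_post = log_post

    @property
    def param_names(self):
        return self.priors.names()

    @property
    def n_params(self):
        return len(self.priors.names())

    def log_posterior(self, theta):
        theta2 = np.atleast_2d(np.asarray(theta, dtype=float))
        lp = self.priors.log_prior(theta2, self.param_names)
        out = np.where(np.isfinite(lp), lp + self._log_post(theta2), -np.inf)
        return float(out[0]) if np.ndim(theta) == 1 else out


@pytest.fixture(scope="session")
def toy_model_cls():
    return ToyModel


@pytest.fixture(scope="session")
def validation_isotherm():
    """One noisy synthetic two-site isotherm at the standard validation
    conditions (dG=-7, ddG=-1, dH=-10, ddH=-1.5; 17/500 uM; sd 0.2 ucal)."""
    return ib.simulate_fixture("validation2site", seed=1)


@pytest.fixture(scope="session")
def validation_fit(validation_isotherm):
    """Posterior fit of the validation isotherm with +/-10% uniform
    concentration priors; shared across posterior-summary tests."""
    model = ib.ITCModel(validation_isotherm, kind="two_site",
                        cell_fraction=0.10, syringe_fraction=0.10)
    return model.fit(n_steps=40000, n_walkers=50, seed=1, n_replicas=1)
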