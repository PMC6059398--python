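import matplotlib
import numpy as np
import pytest
from hypothesis import settings

matplotlib.use("Agg")
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from curveboot import ConcRespSeries, fit_curve
from curveboot.synthetic import TruthSpec, make_design, simulate_series


@pytest.fixture(scope="session")
def tox21_design():
    return make_design("TOX21-like")


@pytest.fixture(scope="session")
def atg_design():
    return make_design("ATG-like")


@pytest.fixture(scope="session")
def noisy_hill_series(tox21_design):
    """A clearly active hill curve: tp = 10*bmad, noise sd = bmad = 5."""
    truth = TruthSpec(model="hill", tp=50.0, ga=0.0, gw=1.2, noise_sd=5.0)
    return simulate_series(tox21_design, truth, seed=11)


@pytest.fixture(scope="session")
def noisy_hill_fit(noisy_hill_series):
    return fit_curve(noisy_hill_series, bmad=5.0, cutoff=15.0)


@pytest.fixture(scope="session")
def flat_elevated_series():
    """All responses at the same elevated level (transition below range)."""
    conc = np.linspace(-1.7, 2.0, 8)
    return ConcRespSeries("flat", "assay", conc, np.full(8, 100.0))


def make_series(conc, resp, chem="chem", assay="assay"):
    return ConcRespSeries(chem, assay, np.asarray(conc, float),
                          np.asarray(resp, float))
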