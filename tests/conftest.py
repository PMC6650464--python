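import warnings

import pytest

import switchsir as sw

# the reference parameterization uses h = 0.002 < 1; the model warns once
# per construction, which would otherwise drown the test output
warnings.filterwarnings(
    "ignore", message="incidence exponent h=.* lies outside")


def _example_model(case):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return sw.example31(case).build_model()


@pytest.fixture(scope="session")
def model_a():
    """Two-regime reference model, noise case a (persistent)."""
    return _example_model("a")


@pytest.fixture(scope="session")
def model_b():
    """Two-regime reference model, noise case b (large-noise extinction)."""
    return _example_model("b")


@pytest.fixture(scope="session")
def model_c():
    """Two-regime reference model, noise case c."""
    return _example_model("c")


@pytest.fixture(scope="session")
def regime1(model_a):
    """Regime-1 parameters (R0 = 1.6)."""
    return model_a.regimes[0]


@pytest.fixture(scope="session")
def regime2(model_a):
    """Regime-2 parameters (R0 = 1.0)."""
    return model_a.regimes[1]


# fixed once for every stochastic check in the suite
SEED = 20190723
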