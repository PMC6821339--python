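import numpy as np
import pytest

from gainsel import (
    CovarianceSpec,
    Gain,
    GeneticParameters,
    Scenario,
    TraitPanel,
    build_covariances,
    default_panel,
)


@pytest.fixture
def panel2():
    """Minimal two-trait panel; trait B is the economic reference."""
    return TraitPanel(names=["A", "B"], units=["d", "g"],
                      means=np.array([10.0, 100.0]), reference="B")


@pytest.fixture
def params2():
    """Hand-checkable 2x2 parameters used throughout the engine tests."""
    return GeneticParameters(G=np.array([[0.4, 0.1], [0.1, 0.3]]),
                             P=np.array([[1.0, 0.5], [0.5, 1.0]]))


@pytest.fixture
def identity2():
    return GeneticParameters(G=np.eye(2), P=np.eye(2))


@pytest.fixture(scope="session")
def miscanthus():
    """The default 16-trait emulation panel with assembled covariances."""
    panel, spec = default_panel()
    return panel, spec, build_covariances(spec)


@pytest.fixture
def scenario_s1():
    """Yield +20 % of mean together with a 44-day flowering delay."""
    return Scenario("S1", [Gain("DryMatter.9", 20.0, "percent"),
                           Gain("DOYFS1.9", 44.0, "absolute")])


@pytest.fixture
def scenario_s2():
    """Yield +20 %, cellulose +5 %, lignin -5 % (all percent of mean)."""
    return Scenario("S2", [Gain("DryMatter.9", 20.0, "percent"),
                           Gain("Cellulose.8", 5.0, "percent"),
                           Gain("Lignin.8", -5.0, "percent")])


def random_psd_instance(rng, n, m=None):
    """A random valid (params, Q, mask) instance with bounded conditioning.

    G and E are Wishart-style positive definite with a ridge, so
    heritabilities land strictly inside (0, 1) and all solves are
    well-posed; used by property tests and the optimization-oracle checks.
    """
    A = rng.normal(size=(n, n))
    G = A @ A.T / n + 0.3 * np.eye(n)
    B = rng.normal(size=(n, n))
    E = B @ B.T / n + 0.3 * np.eye(n)
    params = GeneticParameters(G=G, P=G + E)
    if m is None:
        m = int(rng.integers(1, n + 1))
    mask = np.sort(rng.choice(n, size=m, replace=False))
    Q = rng.normal(size=m)
    return params, Q, mask
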