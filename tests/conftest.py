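import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import argkit as ak
from argkit.wf import SimParams, simulate

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def fig1():
    return ak.fig_pedigree()


@pytest.fixture
def fig2():
    return ak.fig_earg_small()


@pytest.fixture
def fig3():
    return ak.fig_earg_wiuf_hein()


@pytest.fixture
def fig5():
    return ak.fig_levels()


def random_sim_params(rng: np.random.Generator, **overrides) -> SimParams:
    """Small random Wright-Fisher parameter draws for property tests."""
    defaults = dict(
        n_diploids=int(rng.integers(2, 6)),
        n_generations=int(rng.integers(2, 7)),
        L=10.0,
        recomb_rate=float(rng.uniform(0.0, 2.0)),
        seed=int(rng.integers(1, 2**31)),
    )
    defaults.update(overrides)
    return SimParams(**defaults)


@pytest.fixture
def random_gargs():
    """20 small simulated gARGs with assorted parameters."""
    rng = np.random.default_rng(1729)
    return [simulate(random_sim_params(rng))[0] for _ in range(20)]


def labels(g):
    return {u: n.metadata for u, n in g.nodes.items()}
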