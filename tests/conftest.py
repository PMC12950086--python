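import logging

import numpy as np
import pytest

from dtcrdesign.model import ModelSpec, TimeGrid

logging.getLogger("dtcrdesign").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def spec_j2_q3():
    """Small saturated multinomial model: J=2, q_max=3, scalar treatment."""
    return ModelSpec(n_risks=2, link="multinomial", time_grid=TimeGrid.unit(3))


@pytest.fixture
def spec_cumulative_j2_q3():
    return ModelSpec(n_risks=2, link="cumulative", time_grid=TimeGrid.unit(3))


def random_theta(spec, rng, q=None, scale=0.8):
    """A valid random parameter vector (ordered intercepts for cumulative)."""
    q = spec.q_max if q is None else q
    J = spec.n_risks
    base = rng.normal(-1.0, scale, size=(q, J))
    if spec.link == "cumulative":
        base = np.sort(base, axis=1)
    eff = rng.normal(0.0, scale, size=spec.p)
    return np.concatenate([base.ravel(), eff, [0.0]])


def make_spec(n_risks, link, q_max):
    return ModelSpec(n_risks=n_risks, link=link, time_grid=TimeGrid.unit(q_max))
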