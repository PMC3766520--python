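import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from mfesim import NeuronParams, SynapticKernels


@pytest.fixture(scope="session")
def params():
    return NeuronParams()


@pytest.fixture(scope="session")
def kernels():
    return SynapticKernels()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_cascade_instance(rng, n_max=6):
    """One random small cascade instance: voltages below threshold except a
    supra-threshold initiator, random sparse weights, random E/I labels.

    Margins keep instances away from the measure-zero boundary where the
    instantaneous-synapse limit is discontinuous (a target landing exactly
    at threshold), so the finite-timescale oracle and the cascade resolver
    are comparable at finite precision.
    """
    N = int(rng.integers(2, n_max + 1))
    is_E = rng.random(N) < 0.6
    is_E[0] = True
    V = rng.uniform(-0.2, 0.93, size=N)
    V[0] = 1.0 + rng.uniform(0.0, 0.05)
    W = np.where(rng.random((N, N)) < 0.7,
                 rng.uniform(0.05, 0.9, size=(N, N)), 0.0)
    np.fill_diagonal(W, 0.0)
    return V, is_E, W


def nondegenerate_cascade_instance(rng, params, n_max=6, margin=5e-3):
    """A random cascade instance whose outcome is stable under small
    perturbations: every firing crosses threshold with at least ``margin``
    surplus (except the initiator, which is supra by construction) and
    every non-firing neuron ends at least ``margin`` below threshold.

    The instantaneous-synapse limit is discontinuous exactly on the
    measure-zero set where a voltage lands on the threshold; excluding a
    small neighborhood of that set makes the finite-timescale oracle
    comparison well posed at finite integration accuracy.
    """
    from mfesim import resolve_cascade

    while True:
        V, is_E, W = random_cascade_instance(rng, n_max)
        res = resolve_cascade(V.copy(), is_E, W, np.zeros_like(W),
                              params, rng)
        fired = res.order
        not_fired = np.setdiff1d(np.arange(len(V)), fired)
        if res.surpluses[1:] and min(res.surpluses[1:]) < margin:
            continue
        if not_fired.size and (params.V_T - res.V_post[not_fired]).min() < margin:
            continue
        return V, is_E, W, res
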