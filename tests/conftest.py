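"""Shared fixtures.

The expensive simulations (full-size network, 10-block oddball runs, the
amplitude x ISI regime grids) are session-scoped so that the unit tests and
the acceptance tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import a1ssa as A

#: network randomization seed used by the shared default network
NET_SEED = 1

#: seeds for the across-network comparisons
NET_SEEDS_MULTI = (100, 101, 102, 103)


@pytest.fixture(scope="session")
def default_network():
    """Full-size heterogeneous network with the published parameters."""
    return A.build_network(seed=NET_SEED)


@pytest.fixture(scope="session")
def small_fixture():
    """Reduced 7-column network + 20-trial oddball (plumbing tests only)."""
    return A.make_test_fixture("small", seed=3)


@pytest.fixture(scope="session")
def default_oddball(default_network):
    """Both oddball conditions, 10 blocks each, defaults (P=10%, f1=10,
    f2=12, A=5, ISI=350 ms), with per-neuron counts for the middle column."""
    return A.run_oddball_pair(default_network, blocks=10, seed=11,
                              per_neuron=True)


@pytest.fixture(scope="session")
def single_tone_table(default_network):
    """Per-column response table for one 50 ms tone at A=5 on column 11."""
    return A.single_tone_response(default_network)


def _grid(base_params):
    spec = A.SweepSpec(
        grid={"amplitude": [1, 3, 5, 10], "isi": [0.15, 0.3, 0.6, 1.2]},
        n_trials=50, master_seed=5, base_params=base_params)
    return A.run_sweep(spec)


@pytest.fixture(scope="session")
def regime_grid_default():
    """Coarse amplitude x ISI sweep of the default network (regime map)."""
    return _grid(A.NetworkParams())


@pytest.fixture(scope="session")
def regime_grid_no_thc_depression():
    """Same sweep with static thalamocortical synapses."""
    return _grid(A.NetworkParams(thc_depression=False))
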