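"""Network construction: tonotopy, tuning curves, background inputs.

Columns are numbered 1..n_columns and double as frequency values: the
frequency grid defaults to the column centres, and a neuron's triangular
input tuning curve peaks at its (possibly shifted) best frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .params import NetworkParams


def triangular_tuning(f: np.ndarray, bf: float, lam: float) -> np.ndarray:
    """Relative thalamocortical input amplitude at frequencies ``f`` for a
    neuron with best frequency ``bf`` and tuning half-width ``lam``:
    ``max(0, 1 - |f - bf| / lam)`` (support is the open interval |f-bf| < lam).
    """
    return np.maximum(0.0, 1.0 - np.abs(np.asarray(f, dtype=float) - bf) / lam)


def shift_quota(n_e: int) -> dict[int, int]:
    """Number of neurons per best-frequency shift for one column.

    Roughly 1/16, 1/8, 1/8 and 1/16 of the excitatory neurons are shifted by
    -2, -1, +1 and +2 columns; realized as fixed rounded counts so that every
    seed draws exactly the same partition (6, 12, 12, 6 of 100).
    """
    return {
        -2: round(n_e / 16),
        -1: round(n_e / 8),
        +1: round(n_e / 8),
        +2: round(n_e / 16),
    }


@dataclass
class TuningMatrix:
    """Thalamocortical tuning of every excitatory neuron.

    ``t`` has shape (n_columns, n_e, n_channels) with values in [0, 1];
    ``bf_shift`` the per-neuron integer best-frequency shift; ``active_mask``
    flags neurons that receive any thalamocortical input at all (neurons that
    are silent at rest have their input zeroed, see ``mark_inactive``).
    """

    t: np.ndarray
    bf_shift: np.ndarray
    active_mask: np.ndarray
    frequency_grid: np.ndarray


@dataclass
class Network:
    """A realized network instance: parameters + tuning + background inputs."""

    params: NetworkParams
    tuning: TuningMatrix
    e_e: np.ndarray           # background input to excitatory neurons, (C, N_E)
    e_i: np.ndarray           # background input to inhibitory neurons, (C, N_I)
    seed: int
    frequency_grid: np.ndarray
    rest_state: Optional[object] = None   # cached silent steady state (NetworkState)

    @property
    def n_columns(self) -> int:
        return self.params.n_columns

    def channel_of(self, frequency: float, tol: float = 1e-9) -> int:
        """Index of ``frequency`` in the frequency grid (exact up to ``tol``)."""
        idx = int(np.argmin(np.abs(self.frequency_grid - frequency)))
        if abs(self.frequency_grid[idx] - frequency) > tol:
            raise ValueError(
                f"frequency {frequency} is not a channel of this network's grid")
        return idx


def assign_tuning(
    params: NetworkParams,
    seed: int,
    frequency_grid: Optional[Sequence[float]] = None,
) -> TuningMatrix:
    """Draw per-neuron best-frequency shifts and evaluate the triangular
    tuning curves on the frequency grid.

    Shifted neurons are selected without replacement with the exact per-column
    quota of ``shift_quota``; with ``heterogeneous=False`` all shifts are zero.
    All neurons start as active; ``mark_inactive`` prunes the silent ones.
    """
    params.validate()
    if frequency_grid is None:
        frequency_grid = np.arange(1, params.n_columns + 1, dtype=float)
    grid = np.asarray(frequency_grid, dtype=float)
    rng = np.random.default_rng(seed)

    c, n_e = params.n_columns, params.n_e
    shifts = np.zeros((c, n_e), dtype=np.int64)
    if params.heterogeneous:
        quota = shift_quota(n_e)
        for q in range(c):
            order = rng.permutation(n_e)
            pos = 0
            for s in (-2, -1, +1, +2):
                k = quota[s]
                shifts[q, order[pos:pos + k]] = s
                pos += k

    t = np.zeros((c, n_e, grid.size))
    for q in range(c):
        bf = (q + 1) + shifts[q]                       # columns are 1-based
        t[q] = np.maximum(0.0, 1.0 - np.abs(grid[None, :] - bf[:, None]) / params.lambda_)
    active = np.ones((c, n_e), dtype=bool)
    return TuningMatrix(t=t, bf_shift=shifts, active_mask=active, frequency_grid=grid)


def _background_inputs(params: NetworkParams) -> tuple[np.ndarray, np.ndarray]:
    # Deterministic linear ramp over the within-column neuron index, endpoints
    # at the configured bounds; identical across columns and populations.
    lo, hi = params.e_range
    e_e = np.tile(np.linspace(lo, hi, params.n_e), (params.n_columns, 1))
    e_i = np.tile(np.linspace(lo, hi, params.n_i), (params.n_columns, 1))
    return e_e, e_i


def build_network(
    params: NetworkParams = NetworkParams(),
    seed: int = 0,
    frequency_grid: Optional[Sequence[float]] = None,
    prune_inactive: bool = True,
    relax_duration: float = 8.0,
) -> Network:
    """Construct a network: tuning, background inputs, and (by default) the
    silent steady state used to zero thalamocortical input onto neurons that
    do not fire at rest.

    Deterministic given ``(params, seed)``.
    """
    params.validate()
    tuning = assign_tuning(params, seed, frequency_grid)
    e_e, e_i = _background_inputs(params)
    net = Network(
        params=params,
        tuning=tuning,
        e_e=e_e,
        e_i=e_i,
        seed=seed,
        frequency_grid=tuning.frequency_grid,
    )
    if prune_inactive:
        mark_inactive(net, duration=relax_duration)
    return net


def mark_inactive(
    network: Network,
    duration: float = 8.0,
    tol: float = 1e-6,
) -> Network:
    """Zero the thalamocortical input of every excitatory neuron whose firing
    rate is 0 spikes/s at the silent steady state ("non-active" neurons).

    Runs a silent relaxation of ``duration`` seconds (the default, ten
    recurrent recovery time constants, lets the slow resource variables
    settle after the switch-on transient), flags neurons with ``E < tol``
    spikes/s, zeroes their tuning rows, and caches the relaxed state on the
    network for reuse by protocol runs.  Returns the network.
    """
    from . import dynamics  # deferred: dynamics depends on network types

    state = dynamics.relax(network, duration=duration, use_cached_rest=False)
    silent = state.e < tol
    network.tuning.active_mask = ~silent
    network.tuning.t[silent, :] = 0.0
    # rates/resources at silence do not depend on the tuning, but the z
    # bookkeeping does: re-key z (all fully recovered) to the pruned tuning
    ptr, _, _ = dynamics.z_layout(network)
    state.z = np.ones(ptr[-1])
    network.rest_state = state
    return network
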