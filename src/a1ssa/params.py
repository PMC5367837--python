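"""Model parameters for the columnar rate network.

The defaults reproduce the published configuration of the depressing-synapse
rate model of the auditory-cortex input layer: 21 tonotopic columns of 100
excitatory and 100 inhibitory neurons each, Wilson–Cowan-style rate dynamics
with Tsodyks–Markram short-term depression on every excitatory synapse class
(recurrent, inhibitory-to-excitatory, and thalamocortical).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple


@dataclass(frozen=True)
class NetworkParams:
    """Immutable bundle of all network constants.

    Rates are in spikes/s, times in seconds.  Synaptic efficacies ``j_ee``
    and ``j_ie`` are indexed by inter-column distance |R| = 0, 1, 2.
    """

    n_columns: int = 21
    n_e: int = 100
    n_i: int = 100
    lambda_: float = 5.0          # tuning half-width, in column units
    u: float = 0.5                # utilization of recurrent & inhibitory synapses
    u_s: float = 0.7              # utilization of thalamocortical synapses
    tau_e: float = 1e-3
    tau_i: float = 1e-3
    tau_ref_e: float = 3e-3
    tau_ref_i: float = 3e-3
    tau_rec: float = 0.8          # recovery of recurrent & inhibitory resources
    tau_rec_s: float = 0.3        # recovery of thalamocortical resources
    j_ee: Tuple[float, float, float] = (6.0, 4.5e-2, 1.5e-2)
    j_ie: Tuple[float, float, float] = (0.5, 3.5e-3, 1.5e-3)
    j_ei: float = -4.0
    j_ii: float = -0.5
    e_max: float = 300.0          # gain-function ceiling, spikes/s
    dt: float = 1e-4              # Euler step, s
    e_range: Tuple[float, float] = (-10.0, 10.0)   # background input bounds
    # variant switches
    heterogeneous: bool = True        # per-neuron best-frequency scatter
    thc_depression: bool = True       # depressing thalamocortical synapses (z)
    feedback_inhibition: bool = True  # include the I -> E term

    def validate(self) -> None:
        """Raise ``ValueError`` naming the first invalid field."""
        positive = [
            "n_columns", "n_e", "n_i", "lambda_", "tau_e", "tau_i",
            "tau_ref_e", "tau_ref_i", "tau_rec", "tau_rec_s", "e_max", "dt",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)!r}")
        for name in ("u", "u_s"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {v!r}")
        for name in ("j_ee", "j_ie"):
            v = getattr(self, name)
            if len(v) != 3:
                raise ValueError(f"{name} must have length 3 (|R| = 0, 1, 2), got {v!r}")
        for name in ("j_ei", "j_ii"):
            if getattr(self, name) > 0:
                raise ValueError(f"{name} must be <= 0, got {getattr(self, name)!r}")
        lo, hi = self.e_range
        if not lo < hi:
            raise ValueError(f"e_range must be increasing, got {self.e_range!r}")

    def with_(self, **overrides) -> "NetworkParams":
        """Return a copy with the given fields replaced (validated)."""
        p = replace(self, **overrides)
        p.validate()
        return p


DEFAULT_PARAMS = NetworkParams()
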