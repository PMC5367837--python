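"""Closed-form treatment of thalamocortical depression under periodic tones.

The resource fraction z of a single thalamocortical synapse obeys
``dz/dt = (1 - z)/tau_rec_s - U_s * z * s * T``, a scalar linear ODE that is
independent of the rest of the network.  For a periodic train of square
pulses (drive ``sT`` on for ``duration``, off for ``gap``) the values of z
at successive stimulus onsets and offsets follow affine iterated maps with
the contraction factors

    z_ss  = 1 / (1 + tau_rec_s * U_s * sT)       (depleted steady state)
    k_dur = exp(-duration / (tau_rec_s * z_ss))  (depletion over one pulse)
    k_isi = exp(-gap / tau_rec_s)                (recovery over one gap)

whose joint stable fixed points give the steady-state onset and offset
resources reached after many identical stimuli.  The closed form assumes
square pulses; the simulator ramps its envelopes, so cross-validation
against it tolerates a few percent (the exact-pulse ODE agrees to < 1e-3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class MapParams:
    """Parameters of the periodic-stimulation resource map.

    ``s_t`` is the product of drive amplitude and tuning, s_f * T (spikes/s);
    ``gap`` is the offset-to-onset silent interval, i.e. ISI - duration (s).
    """

    u_s: float = 0.7
    tau_rec_s: float = 0.3
    s_t: float = 5.0
    duration: float = 0.05
    gap: float = 0.3

    def __post_init__(self) -> None:
        for name in ("u_s", "tau_rec_s", "duration", "gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.s_t < 0:
            raise ValueError("s_t must be >= 0")

    @property
    def z_ss(self) -> float:
        """Depleted steady state under sustained drive."""
        return 1.0 / (1.0 + self.tau_rec_s * self.u_s * self.s_t)

    @property
    def k_dur(self) -> float:
        """Contraction toward ``z_ss`` over one stimulus."""
        return float(np.exp(-self.duration / (self.tau_rec_s * self.z_ss)))

    @property
    def k_isi(self) -> float:
        """Recovery factor over one silent gap."""
        return float(np.exp(-self.gap / self.tau_rec_s))


@dataclass(frozen=True)
class MapFixedPoint:
    """Joint stable fixed point of the onset/offset maps."""

    z_onset: float
    z_offset: float

    @property
    def recovered_per_cycle(self) -> float:
        """Fraction of resources recovered during each silent gap."""
        return self.z_onset - self.z_offset


def map_step(z_onset: float, params: MapParams) -> tuple[float, float]:
    """One stimulation cycle: deplete over the pulse, recover over the gap.

    Returns ``(z_onset_next, z_offset)``: the offset value after the pulse
    that started at ``z_onset``, and the onset value of the next pulse.
    """
    if not 0.0 < z_onset <= 1.0:
        raise ValueError(f"z_onset must lie in (0, 1], got {z_onset}")
    z_ss = params.z_ss
    z_offset = z_ss + params.k_dur * (z_onset - z_ss)
    z_next = 1.0 - params.k_isi * (1.0 - z_offset)
    return z_next, z_offset


def fixed_points(params: MapParams) -> MapFixedPoint:
    """Closed-form steady-state onset and offset resource fractions.

    The map is affine with slope ``k_dur * k_isi`` in (0, 1), so this fixed
    point is unique and globally stable.
    """
    z_ss, k_dur, k_isi = params.z_ss, params.k_dur, params.k_isi
    denom = 1.0 - k_dur * k_isi
    z_on = (1.0 - k_isi * (1.0 - z_ss * (1.0 - k_dur))) / denom
    z_off = (z_ss * (1.0 - k_dur) + k_dur * (1.0 - k_isi)) / denom
    return MapFixedPoint(z_onset=z_on, z_offset=z_off)


def iterate_map(params: MapParams, z0: float = 1.0, n: int = 100) -> np.ndarray:
    """Onset-value trajectory of the map from ``z0`` (length ``n + 1``)."""
    out = np.empty(n + 1)
    out[0] = z = z0
    for k in range(n):
        z, _ = map_step(z, params)
        out[k + 1] = z
    return out


def integrate_pulse_train(params: MapParams, n_cycles: int = 50,
                          dt: float = 1e-5) -> MapFixedPoint:
    """Euler integration of the resource ODE under a square-pulse train,
    starting fully recovered; returns the last cycle's onset/offset values.

    Independent numerical check of :func:`fixed_points`.
    """
    z = 1.0
    a = 1.0 / params.tau_rec_s
    b_on = a + params.u_s * params.s_t
    n_dur = round(params.duration / dt)
    n_gap = round(params.gap / dt)
    z_on = z_off = z
    for _ in range(n_cycles):
        z_on = z
        for _ in range(n_dur):
            z += dt * (a - b_on * z)
        z_off = z
        for _ in range(n_gap):
            z += dt * (a - a * z)
    return MapFixedPoint(z_onset=z_on, z_offset=z_off)


def z_plane(amplitudes, isis, duration: float = 0.05, u_s: float = 0.7,
            tau_rec_s: float = 0.3, tuning: float = 1.0):
    """Steady-state onset z, offset z and recovered fraction across an
    amplitude x ISI grid (ISI onset-to-onset; tuning scales the drive).

    Returns three arrays of shape (len(amplitudes), len(isis)).
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    isis = np.asarray(isis, dtype=float)
    z_on = np.empty((amplitudes.size, isis.size))
    z_off = np.empty_like(z_on)
    for i, a in enumerate(amplitudes):
        for j, isi in enumerate(isis):
            if isi <= duration:
                raise ValueError("ISI must exceed the stimulus duration")
            fp = fixed_points(MapParams(
                u_s=u_s, tau_rec_s=tau_rec_s, s_t=a * tuning,
                duration=duration, gap=isi - duration))
            z_on[i, j], z_off[i, j] = fp.z_onset, fp.z_offset
    return z_on, z_off, z_on - z_off
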