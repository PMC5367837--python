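"""Stimulus protocols: oddball, Equal, Deviant Alone, Diverse, probe pairs.

A stimulus sequence is an ordered list of trials, each a pure tone presented
in one frequency channel with a trapezoidal envelope (5 ms linear onset ramp,
plateau, 5 ms offset ramp, summing to the nominal duration).  The per-channel
thalamic drive is ``s_f(t) = xi_f(t) * A``.  Onsets are spaced exactly by the
inter-stimulus interval (ISI), defined onset-to-onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

RAMP = 5e-3  # envelope ramp duration, s

#: condition labels used throughout
CONDITIONS = ("standard", "deviant", "equal", "alone", "diverse", "probe", "silence")


@dataclass(frozen=True)
class Trial:
    onset: float        # s
    duration: float     # s
    frequency: float    # channel value (column units); ignored for silence
    amplitude: float    # peak drive, spikes/s (0 for silence)
    condition: str


@dataclass
class StimulusSequence:
    """Ordered trials plus protocol bookkeeping.

    ``isi`` is onset-to-onset; silence trials (Deviant Alone) keep their slot
    so timing matches the parent oddball exactly.
    """

    trials: list[Trial]
    isi: float
    protocol: str
    p: Optional[float] = None
    f1: Optional[float] = None
    f2: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        onsets = [tr.onset for tr in self.trials]
        if any(b - a <= 0 for a, b in zip(onsets, onsets[1:])):
            raise ValueError("trial onsets must be strictly increasing")
        for tr in self.trials:
            if tr.amplitude > 0 and tr.duration >= self.isi:
                raise ValueError(
                    f"stimulus duration {tr.duration} must be < isi {self.isi} "
                    "(overlapping trials)")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def t_end(self) -> float:
        """Recording horizon: one full ISI after the last onset."""
        return self.trials[-1].onset + self.isi

    @property
    def frequencies(self) -> np.ndarray:
        """Distinct tone frequencies used (silence excluded), sorted."""
        return np.unique([tr.frequency for tr in self.trials if tr.amplitude > 0])

    def to_frame(self) -> pd.DataFrame:
        """Tidy trial table (index, onset, duration, frequency, amplitude, condition)."""
        return pd.DataFrame(
            {
                "trial": np.arange(len(self.trials)),
                "onset": [tr.onset for tr in self.trials],
                "duration": [tr.duration for tr in self.trials],
                "frequency": [tr.frequency for tr in self.trials],
                "amplitude": [tr.amplitude for tr in self.trials],
                "condition": [tr.condition for tr in self.trials],
            }
        )


def envelope(t: float | np.ndarray, duration: float, ramp: float = RAMP) -> np.ndarray:
    """Trapezoidal envelope value xi(t) for t measured from stimulus onset.

    Linear 0->1 over ``ramp``, plateau, linear 1->0 over the final ``ramp``;
    zero outside [0, duration).
    """
    t = np.asarray(t, dtype=float)
    up = t / ramp
    down = (duration - t) / ramp
    xi = np.minimum(1.0, np.minimum(up, down))
    return np.where((t >= 0) & (t < duration), np.maximum(xi, 0.0), 0.0)


def drive_at(
    sequence: StimulusSequence, t: float, frequency_grid: Sequence[float]
) -> np.ndarray:
    """Per-channel thalamic drive s_f at time ``t`` (spikes/s).

    At most one trial is active at any time (duration < ISI is enforced).
    """
    grid = np.asarray(frequency_grid, dtype=float)
    s = np.zeros(grid.size)
    for tr in sequence.trials:
        if tr.onset <= t < tr.onset + tr.duration and tr.amplitude > 0:
            idx = int(np.argmin(np.abs(grid - tr.frequency)))
            if abs(grid[idx] - tr.frequency) > 1e-9:
                raise ValueError(
                    f"trial frequency {tr.frequency} not on the frequency grid")
            s[idx] = float(envelope(t - tr.onset, tr.duration)) * tr.amplitude
            break
    return s


def _permuted_labels(freqs: Sequence[float], counts: Sequence[int], seed: int) -> np.ndarray:
    """Block construction: concatenate ``counts[i]`` copies of ``freqs[i]``
    and apply one uniform random permutation."""
    block = np.repeat(np.asarray(freqs, dtype=float), counts)
    rng = np.random.default_rng(seed)
    return rng.permutation(block)


def make_oddball(
    f_standard: float,
    f_deviant: float,
    p: float = 0.1,
    n_trials: int = 100,
    amplitude: float = 5.0,
    isi: float = 0.35,
    duration: float = 0.05,
    seed: int = 0,
    deviant_alone: bool = False,
) -> StimulusSequence:
    """Oddball sequence: deviant tone at probability ``p``, standard at 1-p.

    Exactly ``round(p * n_trials)`` deviants; the order is a uniform random
    permutation of the standard/deviant block, so deviants may be adjacent.
    With ``deviant_alone=True`` every standard is replaced by a silent trial
    of identical timing (the Deviant Alone control).  ``p = 0.5`` gives the
    Equal protocol (labels become "equal").
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must lie in (0, 1), got {p}")
    n_dev = round(p * n_trials)
    labels = _permuted_labels(
        [f_deviant, f_standard], [n_dev, n_trials - n_dev], seed)
    trials = []
    for k, f in enumerate(labels):
        is_dev = f == f_deviant
        if deviant_alone and not is_dev:
            cond, amp = "silence", 0.0
        elif p == 0.5:
            cond, amp = "equal", amplitude
        elif deviant_alone:
            cond, amp = "alone", amplitude
        else:
            cond, amp = ("deviant" if is_dev else "standard"), amplitude
        trials.append(Trial(k * isi, duration, float(f), amp, cond))
    name = "deviant_alone" if deviant_alone else ("equal" if p == 0.5 else "oddball")
    return StimulusSequence(
        trials=trials, isi=isi, protocol=name, p=p,
        f1=min(f_standard, f_deviant), f2=max(f_standard, f_deviant), seed=seed)


def diverse_tones(kind: str, f1: float, f2: float) -> np.ndarray:
    """The 10 equiprobable tones of a Diverse (many-standards) protocol.

    Narrow: spacing (f2-f1)/5 with two tones below f1, four between f1 and f2,
    two above f2 (f1 and f2 are the 3rd and 8th tones).  Broad: spacing f2-f1
    with four tones below f1 and four above f2.
    """
    df = f2 - f1
    if df <= 0:
        raise ValueError("require f2 > f1")
    if kind == "narrow":
        step = df / 5.0
        return f1 + step * np.arange(-2, 8)
    if kind == "broad":
        return f1 + df * np.arange(-4, 6)
    raise ValueError(f"kind must be 'narrow' or 'broad', got {kind!r}")


def make_diverse(
    kind: str,
    f1: float,
    f2: float,
    n_trials: int = 100,
    amplitude: float = 5.0,
    isi: float = 0.35,
    duration: float = 0.05,
    seed: int = 0,
    frequency_bounds: Optional[tuple[float, float]] = None,
) -> StimulusSequence:
    """Diverse Narrow / Diverse Broad control: 10 tones, 10% probability each,
    block-balanced (each tone occurs exactly n_trials/10 times when divisible).

    ``frequency_bounds`` (lo, hi) raises if any tone falls off the tonotopic
    strip (Broad spans columns f1-4*df .. f2+4*df).
    """
    tones = diverse_tones(kind, f1, f2)
    if frequency_bounds is not None:
        lo, hi = frequency_bounds
        if tones.min() < lo or tones.max() > hi:
            raise ValueError(
                f"diverse {kind} tones {tones.min()}..{tones.max()} fall outside "
                f"the tonotopic strip [{lo}, {hi}]")
    base, extra = divmod(n_trials, len(tones))
    counts = [base + (1 if i < extra else 0) for i in range(len(tones))]
    labels = _permuted_labels(tones, counts, seed)
    trials = [
        Trial(k * isi, duration, float(f), amplitude, "diverse")
        for k, f in enumerate(labels)
    ]
    return StimulusSequence(
        trials=trials, isi=isi, protocol=f"diverse_{kind}", p=0.1,
        f1=f1, f2=f2, seed=seed)


def make_probe_pair(
    amp1: float,
    amp2: float,
    delay: float,
    frequency: float = 11.0,
    duration: float = 0.05,
) -> StimulusSequence:
    """Two tones at one frequency for threshold / refractoriness probes.

    ``delay`` is onset-to-onset and must exceed the duration; ``amp2 = 0``
    degenerates to a single-stimulus probe.
    """
    if delay <= duration:
        raise ValueError("probe delay must exceed the stimulus duration")
    trials = [Trial(0.0, duration, frequency, amp1, "probe")]
    if amp2 > 0:
        trials.append(Trial(delay, duration, frequency, amp2, "probe"))
    return StimulusSequence(trials=trials, isi=delay, protocol="probe_pair")


def make_single_tone(
    frequency: float = 11.0,
    amplitude: float = 5.0,
    duration: float = 0.05,
    tail: float = 0.3,
) -> StimulusSequence:
    """One tone followed by ``tail`` seconds of silence."""
    return StimulusSequence(
        trials=[Trial(0.0, duration, frequency, amplitude, "probe")],
        isi=duration + tail, protocol="single_tone")
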