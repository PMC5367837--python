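"""Stimulus protocols: envelopes, drive vectors, sequence bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

import a1ssa as A
from a1ssa.stimuli import envelope


def test_envelope_shape():
    dur = 0.05
    assert envelope(0.0025, dur) == pytest.approx(0.5)    # half-way up the ramp
    assert envelope(0.025, dur) == pytest.approx(1.0)     # plateau
    assert envelope(dur - 0.0025, dur) == pytest.approx(0.5)
    assert envelope(-0.001, dur) == 0.0
    assert envelope(dur + 0.001, dur) == 0.0


@settings(derandomize=True, deadline=None, max_examples=20)
@given(dur=st.floats(min_value=0.011, max_value=0.5))
def test_envelope_integral_is_duration_minus_one_ramp(dur):
    # trapezoid area: plateau + two half-ramps = duration - 5 ms
    area, _ = quad(lambda t: float(envelope(t, dur)), 0, dur,
                   points=[0.005, dur - 0.005], limit=200)
    assert area == pytest.approx(dur - 0.005, abs=1e-12)


def test_drive_at_examples():
    grid = np.arange(1.0, 22.0)
    seq = A.make_oddball(10, 12, p=0.1, n_trials=10, amplitude=5.0, seed=0)
    tr = seq.trials[0]
    mid = A.drive_at(seq, tr.onset + 0.025, grid)
    ch = int(tr.frequency - 1)
    assert mid[ch] == pytest.approx(5.0)
    assert np.all(np.delete(mid, ch) == 0)
    ramp = A.drive_at(seq, tr.onset + 0.0025, grid)
    assert ramp[ch] == pytest.approx(2.5)
    assert np.all(A.drive_at(seq, tr.onset - 1e-4, grid) == 0)


def test_silent_trials_have_zero_drive_but_keep_their_slots():
    grid = np.arange(1.0, 22.0)
    odd = A.make_oddball(10, 12, p=0.1, n_trials=20, seed=4)
    alone = A.make_oddball(10, 12, p=0.1, n_trials=20, seed=4, deviant_alone=True)
    for t_odd, t_al in zip(odd.trials, alone.trials):
        assert t_al.onset == t_odd.onset
        if t_odd.condition == "standard":
            assert t_al.condition == "silence" and t_al.amplitude == 0
            assert np.all(A.drive_at(alone, t_al.onset + 0.025, grid) == 0)
        else:
            assert t_al.condition == "alone" and t_al.amplitude == t_odd.amplitude


@pytest.mark.parametrize("p, n, n_dev", [(0.1, 100, 10), (0.3, 100, 30),
                                         (0.1, 45, 4), (0.5, 100, 50)])
def test_oddball_deviant_counts_are_exact(p, n, n_dev):
    seq = A.make_oddball(10, 12, p=p, n_trials=n, seed=1)
    freqs = np.array([t.frequency for t in seq.trials])
    assert (freqs == 12).sum() == n_dev
    assert (freqs == 10).sum() == n - n_dev
    onsets = np.array([t.onset for t in seq.trials])
    assert np.allclose(np.diff(onsets), seq.isi)


def test_equal_protocol_is_p_half():
    seq = A.make_oddball(10, 12, p=0.5, n_trials=100, seed=2)
    assert seq.protocol == "equal"
    assert all(t.condition == "equal" for t in seq.trials)


def test_sequences_are_deterministic_and_seed_sensitive():
    a = A.make_oddball(10, 12, n_trials=50, seed=9)
    b = A.make_oddball(10, 12, n_trials=50, seed=9)
    c = A.make_oddball(10, 12, n_trials=50, seed=10)
    fa = [t.frequency for t in a.trials]
    assert fa == [t.frequency for t in b.trials]
    assert fa != [t.frequency for t in c.trials]


def test_diverse_tone_sets():
    np.testing.assert_allclose(A.diverse_tones("broad", 10, 12),
                               [2, 4, 6, 8, 10, 12, 14, 16, 18, 20])
    narrow = A.diverse_tones("narrow", 10, 12)
    np.testing.assert_allclose(narrow, np.arange(9.2, 12.9, 0.4))
    assert 10.0 in np.round(narrow, 9) and 12.0 in np.round(narrow, 9)
    # 2 below f1, 4 strictly between, 2 above f2
    assert (narrow < 10).sum() == 2 and (narrow > 12).sum() == 2


def test_diverse_sequence_is_balanced():
    seq = A.make_diverse("broad", 10, 12, n_trials=100, seed=0)
    freqs = np.array([t.frequency for t in seq.trials])
    values, counts = np.unique(freqs, return_counts=True)
    assert len(values) == 10 and np.all(counts == 10)


def test_diverse_broad_outside_strip_raises():
    with pytest.raises(ValueError, match="outside"):
        A.make_diverse("broad", 4, 6, frequency_bounds=(1.0, 21.0))


def test_overlapping_trials_rejected():
    with pytest.raises(ValueError, match="< isi"):
        A.make_oddball(10, 12, n_trials=5, isi=0.04, duration=0.05)
    with pytest.raises(ValueError, match="delay"):
        A.make_probe_pair(5, 5, delay=0.03, duration=0.05)


def test_probe_pair_degenerates_to_single_stimulus():
    pair = A.make_probe_pair(5.0, 5.0, delay=0.35)
    assert pair.n_trials == 2
    single = A.make_probe_pair(5.0, 0.0, delay=0.35)
    assert single.n_trials == 1
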