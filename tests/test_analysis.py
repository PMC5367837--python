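"""Response quantification on synthetic traces with known counts, CSI
arithmetic, and regime labelling logic."""

import numpy as np
import pandas as pd
import pytest

import a1ssa as A
from a1ssa.dynamics import TraceRecording


def synthetic_trace(bumps, n_trials=10, isi=0.35, duration=0.05,
                    baseline=2.0, n_columns=2, extra_bumps=()):
    """Trace with a flat baseline plus rectangular rate bumps.

    ``bumps[k]`` adds a 20 ms bump of the given spike-count area starting
    10 ms after trial k's onset (well inside the response window);
    ``extra_bumps`` are (start_time, area) pairs outside trial windows.
    """
    seq = A.make_oddball(1, 2, p=0.2, n_trials=n_trials, isi=isi,
                         duration=duration, seed=0)
    times = np.arange(-0.01, seq.t_end, 1e-3)
    e = np.full((times.size, n_columns), baseline)
    width = 0.02
    n_w = round(width / 1e-3)

    def add(start, area):
        i0 = round((start - times[0]) / 1e-3)   # sample-aligned: exact area
        e[i0:i0 + n_w, 0] += area / width

    for k, area in enumerate(bumps):
        if area != 0:
            add(seq.trials[k].onset + 0.01, area)
    for start, area in extra_bumps:
        add(start, area)
    return TraceRecording(
        times=times, e_col=e, i_col=np.zeros_like(e), x_col=np.ones_like(e),
        y_col=np.ones_like(e), markers=seq.to_frame(), dt_sample=1e-3)


def test_spike_count_is_baseline_corrected_integral():
    tr = synthetic_trace([1.0, 0.0, 0.6])
    assert A.spike_count(tr, 0, 1) == pytest.approx(1.0, abs=1e-9)
    assert A.spike_count(tr, 1, 1) == pytest.approx(0.0, abs=1e-9)
    assert A.spike_count(tr, 2, 1) == pytest.approx(0.6, abs=1e-9)
    # untouched column integrates to zero everywhere
    assert A.spike_count(tr, 0, 2) == pytest.approx(0.0, abs=1e-9)


def test_spike_count_may_be_negative_for_suppression():
    tr = synthetic_trace([-0.3])
    assert A.spike_count(tr, 0, 1) == pytest.approx(-0.3, abs=1e-9)


def test_window_outside_recording_raises():
    tr = synthetic_trace([1.0])
    m = tr.markers.copy()
    m.loc[0, "onset"] = tr.times[-1]
    tr.markers = m
    with pytest.raises(ValueError, match="exceeds the recording"):
        A.spike_count(tr, 0, 1)


def test_detect_ps_threshold():
    assert A.detect_ps(1.1, threshold=0.8)
    assert not A.detect_ps(0.05, threshold=0.8)
    assert A.detect_ps(0.6) and not A.detect_ps(0.4)   # package default 0.5


def _tables(d1, d2, s1, s2):
    def tab(dev_freq, dev_val, std_freq, std_val):
        return pd.DataFrame({
            "trial": range(4), "column": 1,
            "frequency": [dev_freq, std_freq, std_freq, std_freq],
            "condition": ["deviant", "standard", "standard", "standard"],
            "count": [dev_val, std_val, std_val, std_val],
        })
    return [tab(1.0, d1, 2.0, s2)], [tab(2.0, d2, 1.0, s1)]


def test_csi_formula_and_limits():
    t1, t2 = _tables(1.0, 1.0, 1.0, 1.0)
    assert A.compute_csi(t1, t2, 1.0, 2.0, column=1).csi == pytest.approx(0.0)
    t1, t2 = _tables(1.0, 1.0, 0.0, 0.0)
    assert A.compute_csi(t1, t2, 1.0, 2.0, column=1).csi == pytest.approx(1.0)
    t1, t2 = _tables(0.8, 0.6, 0.2, 0.1)
    res = A.compute_csi(t1, t2, 1.0, 2.0, column=1)
    assert res.csi == pytest.approx((0.8 + 0.6 - 0.2 - 0.1) / (0.8 + 0.6 + 0.2 + 0.1))
    assert -1.0 <= res.csi <= 1.0


def test_degenerate_csi_denominator_raises():
    t1, t2 = _tables(0.0, 0.0, 0.0, 0.0)
    with pytest.raises(ValueError, match="denominator"):
        A.compute_csi(t1, t2, 1.0, 2.0, column=1)


def _classify(bumps, extra=()):
    tr = synthetic_trace(bumps, extra_bumps=extra)
    tab = A.build_response_table(tr, columns=(1,))
    return A.classify_regime([tab], [tr], column=1)


def test_regime_labels():
    seq = A.make_oddball(1, 2, p=0.2, n_trials=10, seed=0)
    is_dev = np.array([t.condition == "deviant" for t in seq.trials])
    none = np.zeros(10)
    assert _classify(none).label == "NoPS"
    first_only = none.copy(); first_only[0] = 1.0
    assert _classify(first_only).label == "NoPS"      # single initial PS allowed
    assert _classify(np.ones(10)).label == "Reliable"
    deviants_only = np.where(is_dev, 1.0, 0.0)
    assert _classify(deviants_only).label == "Selective"
    periodic = np.where(np.arange(10) % 2 == 0, 1.0, 0.0)
    assert _classify(periodic).label == "Periodic"
    # a PS-scale excursion between trials wins over everything
    assert _classify(np.ones(10), extra=[(0.18, 1.2)]).label == "Bursting"


def test_spontaneous_scan_ignores_stimulus_windows():
    tr = synthetic_trace([1.0] * 10)
    assert A.spontaneous_ps_count(tr, column=1) == 0
    tr2 = synthetic_trace([0.0] * 10, extra_bumps=[(0.18, 1.2), (1.23, 1.2)])
    assert A.spontaneous_ps_count(tr2, column=1) >= 2


def test_per_neuron_counts_average_to_column_count(small_fixture):
    net, seq = small_fixture
    tr = A.run(net, seq, record_columns=(4,))
    per_neuron = A.per_neuron_counts(tr, 4)
    tab = A.build_response_table(tr, columns=(4,))
    assert np.allclose(per_neuron.mean(axis=1), tab["count"].to_numpy(),
                       atol=1e-9)


def test_per_column_csi_is_mirror_symmetric_for_homogeneous_network():
    """With homogeneous tuning, identical background ramps and mirrored
    oddball sequences, the CSI profile is symmetric about the middle column.

    Run below the PS threshold so the dynamics stay smooth and the mirror
    symmetry of the construction is preserved to rounding accuracy.
    """
    net = A.build_network(A.NetworkParams(heterogeneous=False), seed=0)
    kw = dict(p=0.1, n_trials=20, amplitude=2.0, seed=21)
    tr_dev_f2 = A.run(net, A.make_oddball(10, 12, **kw))
    tr_dev_f1 = A.run(net, A.make_oddball(12, 10, **kw))
    t2 = A.build_response_table(tr_dev_f2)
    t1 = A.build_response_table(tr_dev_f1)
    res = A.per_column_csi([t1], [t2], 10.0, 12.0, n_columns=21)
    csi = np.array([r.csi for r in res])
    for k in range(1, 7):
        assert csi[10 + k] == pytest.approx(csi[10 - k], abs=1e-9)


def test_middle_column_csi_exceeds_stimulus_columns(default_oddball):
    """SSA is strongest midway between the tone columns (local maximum)."""
    res = default_oddball
    cols = A.per_column_csi(res.tables_dev_f1, res.tables_dev_f2,
                            10.0, 12.0, n_columns=21)
    csi = {r.column: r.csi for r in cols}
    assert csi[11] > csi[10] and csi[11] > csi[12]
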