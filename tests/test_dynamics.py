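"""Integration engine: gain, reference-vs-kernel agreement, resource bounds,
population-spike phenomenology."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import a1ssa as A
from a1ssa import dynamics, stimuli


@pytest.mark.parametrize("w, expected", [(-1.0, 0.0), (0.0, 0.0),
                                         (150.0, 150.0), (300.0, 300.0),
                                         (400.0, 300.0)])
def test_gain_is_piecewise_linear(w, expected):
    assert A.gain(w) == expected


def test_reference_step_matches_compiled_kernel(small_fixture):
    """The numpy single-step and the numba kernel implement the same map."""
    net, seq = small_fixture
    trace = A.run(net, seq, record_stride=1, lead_in=0.0)
    state = A.relax(net)
    state.t = 0.0
    n = 2000   # covers several trials including ramps and silence
    for k in range(n):
        s = stimuli.drive_at(seq, k * net.params.dt, net.frequency_grid)
        state = A.step(net, state, s)
    assert np.allclose(state.e.mean(axis=1), trace.e_col[n], atol=1e-10)
    assert np.allclose(state.x.mean(axis=1), trace.x_col[n], atol=1e-10)
    assert np.allclose(state.i.mean(axis=1), trace.i_col[n], atol=1e-10)


def test_silent_steady_state_is_a_fixed_point(small_fixture):
    net, _ = small_fixture
    state = A.relax(net)
    nxt = A.step(net, state, np.zeros(net.frequency_grid.size))
    assert np.max(np.abs(nxt.e - state.e)) < 1e-9


def test_z_recovers_along_the_exact_exponential(small_fixture):
    """With no drive, 1 - z decays as exp(-t / tau_rec_s) exactly."""
    net, _ = small_fixture
    state = A.relax(net)
    state.z[:] = 0.4
    z0 = state.z.copy()
    t_rec = 0.123
    seq = stimuli.StimulusSequence(
        trials=[stimuli.Trial(t_rec, 0.01, 4.0, 0.0, "silence")],
        isi=0.35, protocol="probe")
    trace = A.run(net, seq, initial=state, lead_in=0.0)
    expected = 1.0 - (1.0 - z0) * np.exp(-trace.final_state.t / net.params.tau_rec_s)
    assert np.allclose(trace.final_state.z, expected, atol=1e-12)


def test_z_stays_one_without_thc_depression():
    params = A.NetworkParams(n_columns=7, n_e=20, n_i=20, lambda_=2.0,
                             thc_depression=False)
    net = A.build_network(params, seed=3)
    seq = A.make_oddball(3, 5, n_trials=10, seed=1)
    trace = A.run(net, seq)
    assert np.all(trace.final_state.z == 1.0)


@settings(derandomize=True, deadline=None, max_examples=6)
@given(amplitude=st.floats(min_value=0.5, max_value=30.0),
       seed=st.integers(min_value=0, max_value=10_000))
def test_resources_and_rates_stay_bounded(small_fixture, amplitude, seed):
    """0 < x, y, z <= 1 and 0 <= E, I <= E_max at every recorded sample."""
    net, _ = small_fixture
    seq = A.make_oddball(3, 5, n_trials=6, amplitude=amplitude, seed=seed)
    tr = A.run(net, seq)
    emax = net.params.e_max
    for col in (tr.e_col, tr.i_col):
        assert col.min() >= 0.0 and col.max() <= emax
    for res in (tr.x_col, tr.y_col):
        assert res.min() > 0.0 and res.max() <= 1.0
    st_ = tr.final_state
    assert st_.z.min() > 0.0 and st_.z.max() <= 1.0
    assert st_.x.min() > 0.0 and st_.y.min() > 0.0


def test_runs_are_bit_identical(small_fixture):
    net, seq = small_fixture
    a = A.run(net, seq)
    b = A.run(net, seq)
    assert np.array_equal(a.e_col, b.e_col)
    assert np.array_equal(a.x_col, b.x_col)
    assert np.array_equal(a.final_state.z, b.final_state.z)


def test_relax_reaches_low_spontaneous_rates(default_network):
    state = default_network.rest_state
    col_mean = state.e.mean(axis=1)
    assert 0.5 < col_mean.mean() < 10.0        # a few spikes/s
    assert state.i.mean() < 20.0
    assert np.all(state.x > 0) and np.all(state.x <= 1)


def test_single_tone_evokes_population_spike_with_lagging_inhibition(default_network):
    seq = A.make_single_tone()
    tr = A.run(default_network, seq)
    e = tr.e_col[:, 10]
    i = tr.i_col[:, 10]
    assert e.max() > 40.0                      # sharp transient excursion
    assert tr.times[e.argmax()] < 0.05
    assert tr.times[i.argmax()] > tr.times[e.argmax()]   # I lags E
    # resource depletion followed by recovery
    x = tr.x_col[:, 10]
    assert x.min() < 0.55 and x[-1] > x.min()


def test_subthreshold_tone_evokes_no_ps_anywhere(default_network):
    table = A.single_tone_response(default_network, amplitude=1.0)
    assert not table.ps.any()
    assert table["count"].max() < 0.15


def test_lead_in_prepends_recorded_silence(small_fixture):
    net, seq = small_fixture
    tr = A.run(net, seq, lead_in=0.02)
    assert tr.times[0] == pytest.approx(-0.02)
    rest = net.rest_state.e.mean(axis=1)
    assert np.allclose(tr.e_col[0], rest, atol=1e-9)


def test_nonfinite_state_raises_numerical_error(small_fixture):
    net, seq = small_fixture
    bad = A.relax(net)
    bad.e[0, 0] = np.nan
    with pytest.raises(A.NumericalError, match="E"):
        A.run(net, seq, initial=bad)


def test_refractoriness_recovers_with_delay(default_network):
    """After an evoked PS, the second-stimulus response grows with the
    inter-stimulus delay (resource recovery)."""
    counts = []
    for delay in (0.15, 0.35, 0.8):
        seq = A.make_probe_pair(5.0, 5.0, delay=delay)
        tr = A.run(default_network, seq)
        counts.append(A.spike_count(tr, trial=1, column=11))
    assert counts[0] < counts[1] < counts[2]
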