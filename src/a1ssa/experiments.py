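"""Figure-level experiments: oddball CSI runs, parameter sweeps, regime maps,
condition comparisons, and test fixtures.

All randomness is routed through a single master seed: network tuning draws
and sequence permutations receive named substreams derived from it, so any
individual run can be reconstructed from the result table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, fields as dc_fields
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import analysis, dynamics, stimuli
from .network import Network, build_network
from .params import NetworkParams

MIDDLE = 11  # middle column of the default 21-column strip


def _substream(master_seed: int, *tags: int) -> int:
    """Deterministic child seed (< 2**31) from a master seed and tag path."""
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, *tags])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def middle_column(params: NetworkParams) -> int:
    return (params.n_columns + 1) // 2


def centered_pair(params: NetworkParams, df: float) -> tuple[float, float]:
    """Tone pair of separation ``df`` centered on the middle column."""
    mid = middle_column(params)
    return mid - df / 2.0, mid + df / 2.0


@dataclass
class OddballResult:
    """Both oddball conditions of one network, with CSI summaries."""

    csi: analysis.CSIResult                  # column-mean CSI of `column`
    column: int
    tables_dev_f1: list[pd.DataFrame]
    tables_dev_f2: list[pd.DataFrame]
    traces_dev_f1: list[dynamics.TraceRecording]
    traces_dev_f2: list[dynamics.TraceRecording]
    neuron_csi: Optional[np.ndarray] = None  # per-neuron CSI (NaN = undefined)
    regime: Optional[analysis.RegimeLabel] = None


def run_oddball_pair(
    network: Network,
    f1: float = 10.0,
    f2: float = 12.0,
    p: float = 0.1,
    n_trials: int = 100,
    blocks: int = 1,
    amplitude: float = 5.0,
    isi: float = 0.35,
    duration: float = 0.05,
    seed: int = 0,
    per_neuron: bool = False,
    classify: bool = False,
    keep_traces: bool = False,
    analysis_column: Optional[int] = None,
) -> OddballResult:
    """Run the oddball protocol in both conditions (deviant = f2, then roles
    reversed) for ``blocks`` independent sequence randomizations each, and
    compute the CSI of the analysis column (default: the middle column).

    Each block starts from the network's relaxed silent steady state.
    """
    col = analysis_column or middle_column(network.params)
    rec_cols = (col,) if per_neuron else ()
    tables = {f1: [], f2: []}
    traces = {f1: [], f2: []}
    # per-neuron spike counts are reduced run-by-run so that the (large)
    # per-neuron traces never accumulate across blocks
    ncounts = {f1: [], f2: []}
    nmarkers = {f1: [], f2: []}
    for b in range(blocks):
        for ci, (f_std, f_dev) in enumerate(((f1, f2), (f2, f1))):
            seq = stimuli.make_oddball(
                f_std, f_dev, p=p, n_trials=n_trials, amplitude=amplitude,
                isi=isi, duration=duration,
                seed=_substream(seed, b, ci))
            tr = dynamics.run(network, seq, record_columns=rec_cols)
            tables[f_dev].append(analysis.build_response_table(tr))
            if per_neuron:
                ncounts[f_dev].append(analysis.per_neuron_counts(tr, col))
                nmarkers[f_dev].append(tr.markers)
                tr.e_full.clear()
            if keep_traces or classify:
                traces[f_dev].append(tr)
    try:
        csi = analysis.compute_csi(tables[f1], tables[f2], f1, f2, column=col)
    except ValueError:
        # degenerate denominator (e.g. ongoing spontaneous bursting):
        # keep the condition means, report the index as undefined
        csi = analysis.CSIResult(np.nan, np.nan, np.nan, np.nan, np.nan,
                                 column=col)
    neuron_csi = None
    if per_neuron:
        neuron_csi = analysis.per_neuron_csi_from_counts(
            ncounts[f1], nmarkers[f1], ncounts[f2], nmarkers[f2], f1, f2)
    regime = None
    if classify:
        regime = analysis.classify_regime(
            tables[f1] + tables[f2], traces[f1] + traces[f2], col)
    if not keep_traces:
        traces = {f1: [], f2: []}
    return OddballResult(
        csi=csi, column=col,
        tables_dev_f1=tables[f1], tables_dev_f2=tables[f2],
        traces_dev_f1=traces[f1], traces_dev_f2=traces[f2],
        neuron_csi=neuron_csi, regime=regime)


def single_tone_response(
    network: Network,
    frequency: Optional[float] = None,
    amplitude: float = 5.0,
    duration: float = 0.05,
    threshold: float = analysis.PS_THRESHOLD,
) -> pd.DataFrame:
    """Present one tone to the fully recovered network and return the
    per-column response table (count, PS flag) of that single trial."""
    if frequency is None:
        frequency = float(middle_column(network.params))
    seq = stimuli.make_single_tone(frequency=frequency, amplitude=amplitude,
                                  duration=duration)
    tr = dynamics.run(network, seq)
    return analysis.build_response_table(tr, threshold=threshold)


def ps_threshold_amplitude(
    network: Network,
    frequency: Optional[float] = None,
    lo: float = 0.1,
    hi: float = 20.0,
    tol: float = 0.05,
    column: Optional[int] = None,
) -> float:
    """Minimal single-tone amplitude that evokes a population spike in the
    stimulated column (bisection; the PS threshold is sharp)."""
    col = column or middle_column(network.params)

    def evokes(a: float) -> bool:
        t = single_tone_response(network, frequency, amplitude=a)
        return bool(t[t.column == col].ps.iloc[0])

    if evokes(lo):
        return lo
    if not evokes(hi):
        raise ValueError(f"no PS evoked up to amplitude {hi}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if evokes(mid):
            hi = mid
        else:
            lo = mid
    return hi


@dataclass
class SweepSpec:
    """Grid specification for parameter sweeps.

    ``grid`` maps parameter names to value lists.  Network-level names are
    any ``NetworkParams`` field (u, tau_rec, u_s, tau_rec_s, lambda_, variant
    flags, ...); protocol-level names: amplitude, isi, p, df, duration, gap
    (gap sets isi = duration + gap).
    """

    grid: dict
    seeds: tuple[int, ...] = (0,)
    n_trials: int = 100
    blocks: int = 1
    base_params: NetworkParams = field(default_factory=NetworkParams)
    protocol_defaults: dict = field(default_factory=lambda: {
        "amplitude": 5.0, "isi": 0.35, "duration": 0.05, "p": 0.1, "df": 2.0})
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("sweep grid must be non-empty")


_PARAM_FIELDS = {f.name for f in dc_fields(NetworkParams)}
_PROTOCOL_FIELDS = {"amplitude", "isi", "p", "df", "duration", "gap"}


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Run both oddball conditions at every grid point x seed; returns a tidy
    table with one row per point and seed (CSI, regime label, PS fractions,
    condition means).  Failed points are flagged, not fatal.
    """
    names = list(spec.grid)
    unknown = set(names) - _PARAM_FIELDS - _PROTOCOL_FIELDS
    if unknown:
        raise ValueError(f"unknown sweep parameters: {sorted(unknown)}")
    rows = []
    net_cache: dict = {}
    for values in itertools.product(*(spec.grid[n] for n in names)):
        point = dict(zip(names, values))
        p_over = {k: v for k, v in point.items() if k in _PARAM_FIELDS}
        proto = dict(spec.protocol_defaults)
        proto.update({k: v for k, v in point.items() if k in _PROTOCOL_FIELDS})
        if "gap" in proto:
            proto["isi"] = proto["duration"] + proto.pop("gap")
        params = spec.base_params.with_(**p_over) if p_over else spec.base_params
        for seed in spec.seeds:
            key = (params, seed)
            if key not in net_cache:
                net_cache[key] = build_network(params, seed=_substream(
                    spec.master_seed, 0, seed))
            net = net_cache[key]
            f1, f2 = centered_pair(params, proto["df"])
            row = dict(point)
            row["seed"] = seed
            try:
                res = run_oddball_pair(
                    net, f1=f1, f2=f2, p=proto["p"], n_trials=spec.n_trials,
                    blocks=spec.blocks, amplitude=proto["amplitude"],
                    isi=proto["isi"], duration=proto["duration"],
                    seed=_substream(spec.master_seed, 1, seed),
                    classify=True, keep_traces=False)
                row.update(
                    csi=res.csi.csi, d_f1=res.csi.d_f1, d_f2=res.csi.d_f2,
                    s_f1=res.csi.s_f1, s_f2=res.csi.s_f2,
                    regime=res.regime.label,
                    std_ps_fraction=res.regime.standard_ps_fraction,
                    dev_ps_fraction=res.regime.deviant_ps_fraction,
                    spontaneous_ps=res.regime.spontaneous_ps,
                    failed=False, error="")
            except (ValueError, dynamics.NumericalError,
                    dynamics.ConvergenceError) as exc:
                row.update(csi=np.nan, d_f1=np.nan, d_f2=np.nan, s_f1=np.nan,
                           s_f2=np.nan, regime="", std_ps_fraction=np.nan,
                           dev_ps_fraction=np.nan, spontaneous_ps=0,
                           failed=True, error=str(exc))
            rows.append(row)
    return pd.DataFrame(rows)


def run_duration_interval_map(durations: Sequence[float],
                              gaps: Sequence[float],
                              **kwargs) -> pd.DataFrame:
    """CSI and regime across stimulus duration x offset-to-onset interval."""
    return run_sweep(SweepSpec(
        grid={"duration": list(durations), "gap": list(gaps)}, **kwargs))


#: the six conditions in which a tone can be presented
SIX_CONDITIONS = ("standard", "deviant", "equal", "alone",
                  "diverse_narrow", "diverse_broad")


def run_six_conditions(
    n_networks: int = 12,
    blocks: int = 10,
    conditions: Sequence[str] = SIX_CONDITIONS,
    params: NetworkParams = NetworkParams(),
    df: float = 2.0,
    p: float = 0.1,
    n_trials: int = 100,
    amplitude: float = 5.0,
    isi: float = 0.35,
    duration: float = 0.05,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Mean response to each test tone (f1, f2) under the requested subset of
    the six presentation conditions, per network.

    Returns a tidy frame (network, condition, frequency, response, and the
    response normalized to the Deviant Alone condition when it was run).
    The frequency grid is extended with the Diverse Narrow tones so that all
    protocols run on the same network instance.
    """
    f1, f2 = centered_pair(params, df)
    grid = np.arange(1, params.n_columns + 1, dtype=float)
    if "diverse_narrow" in conditions:
        grid = np.union1d(grid, stimuli.diverse_tones("narrow", f1, f2))
    rows = []
    for k in range(n_networks):
        net = build_network(params, seed=_substream(master_seed, 0, k),
                            frequency_grid=grid)
        col = middle_column(params)
        means: dict[tuple[str, float], list[float]] = {}

        def record(cond, freq, table):
            sel = table[(table.column == col)
                        & (np.abs(table.frequency - freq) < 1e-9)]
            means.setdefault((cond, freq), []).extend(sel["count"].tolist())

        for b in range(blocks):
            bs = _substream(master_seed, 1, k, b)
            if "standard" in conditions or "deviant" in conditions:
                for ci, (f_std, f_dev) in enumerate(((f1, f2), (f2, f1))):
                    seq = stimuli.make_oddball(
                        f_std, f_dev, p=p, n_trials=n_trials,
                        amplitude=amplitude, isi=isi, duration=duration,
                        seed=_substream(bs, 0, ci))
                    t = analysis.build_response_table(
                        dynamics.run(net, seq), columns=(col,))
                    record("deviant", f_dev, t[t.condition == "deviant"])
                    record("standard", f_std, t[t.condition == "standard"])
            if "equal" in conditions:
                seq = stimuli.make_oddball(
                    f1, f2, p=0.5, n_trials=n_trials, amplitude=amplitude,
                    isi=isi, duration=duration, seed=_substream(bs, 1))
                t = analysis.build_response_table(dynamics.run(net, seq),
                                                  columns=(col,))
                record("equal", f1, t)
                record("equal", f2, t)
            if "alone" in conditions:
                for ci, (f_std, f_dev) in enumerate(((f1, f2), (f2, f1))):
                    seq = stimuli.make_oddball(
                        f_std, f_dev, p=p, n_trials=n_trials,
                        amplitude=amplitude, isi=isi, duration=duration,
                        seed=_substream(bs, 0, ci), deviant_alone=True)
                    t = analysis.build_response_table(dynamics.run(net, seq),
                                                      columns=(col,))
                    record("alone", f_dev, t[t.condition == "alone"])
            for kind in ("narrow", "broad"):
                if f"diverse_{kind}" not in conditions:
                    continue
                seq = stimuli.make_diverse(
                    kind, f1, f2, n_trials=n_trials, amplitude=amplitude,
                    isi=isi, duration=duration, seed=_substream(bs, 2),
                    frequency_bounds=(1.0, float(params.n_columns))
                    if kind == "broad" else None)
                t = analysis.build_response_table(dynamics.run(net, seq),
                                                  columns=(col,))
                record(f"diverse_{kind}", f1, t)
                record(f"diverse_{kind}", f2, t)

        for (cond, freq), vals in means.items():
            rows.append({"network": k, "condition": cond, "frequency": freq,
                         "response": float(np.mean(vals))})
    out = pd.DataFrame(rows)
    if "alone" in conditions:
        norm = out[out.condition == "alone"].set_index(
            ["network", "frequency"]).response
        out["normalized"] = [
            r.response / norm.loc[(r.network, r.frequency)]
            for r in out.itertuples()]
    return out


def deviant_vs_diverse_test(six: pd.DataFrame) -> dict:
    """Paired two-sided t-test of Deviant vs Diverse Broad responses across
    networks (pairs are (network, frequency) cells)."""
    piv = six.pivot_table(index=["network", "frequency"], columns="condition",
                          values="response")
    res = stats.ttest_rel(piv["deviant"], piv["diverse_broad"])
    return {"t": float(res.statistic), "p": float(res.pvalue),
            "mean_deviant": float(piv["deviant"].mean()),
            "mean_diverse_broad": float(piv["diverse_broad"].mean()),
            "n_pairs": int(len(piv))}


def make_test_fixture(scale: str = "small", seed: int = 0):
    """(network, oddball sequence) pair for tests and demos.

    ``small``: 7 columns x 20+20 neurons, lambda = 2, 20-trial oddball —
    fast plumbing fixture, NOT parameter-matched to the published model.
    ``default``: the full published configuration with a 100-trial oddball.
    """
    if scale == "small":
        params = NetworkParams(n_columns=7, n_e=20, n_i=20, lambda_=2.0)
        f1, f2 = 3.0, 5.0
        n_trials = 20
    elif scale == "default":
        params = NetworkParams()
        f1, f2 = 10.0, 12.0
        n_trials = 100
    else:
        raise ValueError(f"scale must be 'small' or 'default', got {scale!r}")
    net = build_network(params, seed=_substream(seed, 0))
    seq = stimuli.make_oddball(f1, f2, n_trials=n_trials,
                               seed=_substream(seed, 1))
    return net, seq
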