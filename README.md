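# a1ssa — population spikes and stimulus-specific adaptation in a depressing-synapse rate model of auditory cortex

`a1ssa` simulates the input layer of primary auditory cortex (A1) as a strip
of 21 tonotopic columns of excitatory and inhibitory rate neurons whose
excitatory synapses — recurrent, inhibitory-feedback and thalamocortical —
all show short-term depression.  The package is for computational
neuroscientists studying how *stimulus-specific adaptation* (SSA, the
hallmark of deviance processing in the oddball paradigm) can emerge from
synaptic depression and the propagation of *population spikes* (PSs) between
columns, without any dedicated novelty circuitry.

## Model

Each column holds N_E = 100 excitatory and N_I = 100 inhibitory neurons.
Neuron rates follow Wilson–Cowan-type equations with a piecewise-linear gain
g(w) = min(max(w, 0), E_max) and a refractory factor:

    tau_E dE_i/dt = -E_i + (1 - tau_ref E_i) g( sum_R (J_EE^|R|/N_E) sum_j U x_j E_j
                    + (J_EI/N_I) sum_l U y_l I_l + e_i + sum_f U_s z_i^f s_f T_i^f )
    tau_I dI_l/dt = -I_l + (1 - tau_ref I_l) g( sum_R (J_IE^|R|/N_E) sum_j E_j
                    + (J_II/N_I) sum_l I_l + e_l )

Every excitatory synapse class carries Tsodyks–Markram-style resources that
deplete with presynaptic activity at utilization fraction U (U_s for
thalamocortical) and recover exponentially (tau_rec = 0.8 s, tau_rec_s = 0.3 s):

    dx/dt = (1 - x)/tau_rec   - U   x E        (recurrent)
    dy/dt = (1 - y)/tau_rec   - U   y I        (inhibitory -> excitatory)
    dz/dt = (1 - z)/tau_rec_s - U_s z s_f T    (thalamocortical, per channel)

Tones drive per-frequency thalamic channels s_f = xi(t) A with trapezoidal
envelopes; each neuron's input tuning is a triangle of half-width lambda = 5
columns, with a heterogeneous scatter of best frequencies inside each column
(±1, ±2 columns for 1/8, 1/16 of the neurons).  Neurons that are silent at
rest receive no thalamic input.

Responses are quantified as baseline-corrected spike counts (rate integral
from tone onset to 45 ms after offset), and SSA with the common-contrast
SSA index over the two oddball conditions,

    CSI = (d(f1) + d(f2) - s(f1) - s(f2)) / (d(f1) + d(f2) + s(f1) + s(f2)),

evaluated in the column tonotopically midway between the two tones.  A
closed-form iterated map (`a1ssa.analytics`) gives the steady-state
thalamocortical resources under periodic stimulation.

## Worked example

```bash
python examples/oddball_csi.py
```

builds the default network, runs two blocks of both oddball conditions
(P = 10%, f1 = 10, f2 = 12, A = 5 spikes/s, ISI = 350 ms) and prints:

```
responses of column 11 (spikes/neuron per trial):
  f1 = 10: deviant 0.639   standard 0.140
  f2 = 12: deviant 0.699   standard 0.133
column-mean CSI = 0.661  (strong SSA; deviants evoke population spikes, standards mostly fail)
single-neuron CSI: mean 0.710, sd 0.192 (100 neurons; broad bimodal spread ...)
regime: Selective (PS fraction deviants 0.80, standards 0.01)
```

Each deviant tone evokes a PS (~0.7 spikes/neuron above baseline) in the
middle column while standards mostly fail to: the CSI of ~0.66 quantifies
adaptation that is specific to the frequent tone.  Other examples:
`population_spike_probe.py` (PS threshold and 3-column propagation),
`regime_classification.py` (NoPS / Selective / Periodic / Reliable along the
amplitude axis), `thalamocortical_depression_map.py` (analytic resource
fixed points).

The library surface mirrors the analysis pipeline: `build_network` →
`make_oddball` / `make_diverse` / `make_probe_pair` → `run` →
`build_response_table` / `compute_csi` / `classify_regime`, with
`run_oddball_pair`, `run_sweep`, `run_six_conditions` orchestrating the
multi-run experiments.

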