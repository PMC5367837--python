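# Methods

## Model

The network is a one-dimensional tonotopic strip of `n_columns = 21`
columns, each a fully connected recurrent population of `N_E = 100`
excitatory and `N_I = 100` inhibitory rate neurons.  State variables per
neuron are the firing rate (E or I, spikes/s, capped by the gain ceiling
`E_max = 300`) and the fraction of available resources of the synapses the
neuron makes onto excitatory targets (x for excitatory sources, y for
inhibitory sources, in (0, 1]).  Synapses onto inhibitory neurons are
static.  Each excitatory neuron additionally owns one thalamocortical
resource variable z per frequency channel it is tuned to.

Rate equations use a refractory factor `(1 - tau_ref * rate)` in front of
the piecewise-linear gain; with `tau_ref = 3 ms` this caps rates near the
333 spikes/s that the refractory period alone would allow, consistent with
`E_max = 300`.  Membrane time constants are 1 ms, so rates track their
inputs quickly; the slow dynamics — and everything interesting in this
model — live in the resource variables (`tau_rec = 0.8 s` recurrent and
inhibitory, `tau_rec_s = 0.3 s` thalamocortical; utilization `U = 0.5`,
`U_s = 0.7`).

Connectivity couples columns up to two steps apart with strongly decaying
efficacies (`J_EE = 6, 0.045, 0.015`; `J_IE = 0.5, 0.0035, 0.0015`;
intra-column `J_EI = -4`, `J_II = -0.5`).  Out-of-strip neighbors are
simply dropped (finite strip, no wraparound).  Inhibition is purely
feedback: inhibitory neurons receive no thalamic input, which lets the
inhibitory rate lag the excitatory rate and gate population spikes.

**Population spikes.** Because recurrent excitation is strong while its
resources are intact, a sufficient thalamic kick ignites a regenerative
transient in which most neurons of a column fire about one spike within a
few milliseconds, depleting x and leaving the column refractory for a time
of order `tau_rec`.  PSs propagate to neighboring columns that are primed
by their own (weaker) thalamic input — about 3 columns to each side for a
tone at A = 5 spikes/s with tuning half-width `lambda = 5`.  Deviant
selectivity follows: the column midway between two oddball tones is kept
depressed by the frequent standard, yet a rare deviant arrives after enough
recovery to ignite and propagate a PS.

## Network construction

* **Tuning.** Triangular tuning `T = max(0, 1 - |f - f_BF| / lambda)`
  evaluated on a real-valued frequency grid (column centres 1..21, extended
  by protocol tones such as the Diverse Narrow set when needed).  Per
  column, exactly 6, 12, 12 and 6 of the 100 excitatory neurons have their
  best frequency shifted by -2, -1, +1, +2 columns (the rounded 1/16, 1/8,
  1/8, 1/16 partition), drawn without replacement; the homogeneous variant
  sets all shifts to zero.
* **Background input.** Each population's background drive is a fixed
  linear ramp over the within-column neuron index from -10 to +10 spikes/s
  (endpoints inclusive), identical across columns — the deterministic
  realization of "uniformly distributed, linear in index".
* **Non-active neurons.** After relaxing the network under silence, every
  excitatory neuron whose steady rate is below 1e-6 spikes/s has its
  thalamic input zeroed.  With the default ramp about 55% of neurons remain
  active; the silent steady state has column-mean rates of ~3 spikes/s and
  no spontaneous PSs.
* **Rest state.** The silent relaxation runs for 8 s (10 `tau_rec`).  The
  switch-on transient from the fully recovered initial condition evokes an
  initial PS whose resource debt decays with `tau_rec`; at 2 s the
  recurrent resources are still ~3% below steady state, which measurably
  weakens evoked PSs (propagation shrinks to ±2 columns).  The relaxed
  state is cached on the network and reused by every protocol run.

## Stimuli

Tones are trapezoidal envelopes (5 ms linear ramps, total support equal to
the nominal 50 ms duration) scaled by the amplitude A; at most one tone is
active at a time and ISI is onset-to-onset (350 ms default).  Protocols are
generated as balanced blocks with one uniform random permutation: oddball
(deviant probability P = 10%, exactly round(P n) deviants in n = 100
trials), Equal (P = 50%), Deviant Alone (standards replaced by silent
trials of identical timing), Diverse Narrow (10 tones at spacing df/5, two
below f1, four between, two above f2) and Diverse Broad (10 tones at
spacing df, four below f1, four above f2).  Probe pairs support threshold
and refractoriness measurements.

These generated sequences, together with the seeded tuning randomization,
*are* the study conditions: there is no external data.  What the generator
does not emulate — trial-to-trial physiological noise, spike timing,
experimental measurement error — limits what agreement with the package's
own reference numbers says about real cortex; the model is deterministic,
so all variability across repeats comes from sequence permutations and
tuning draws.

## Numerics

* Forward Euler at `dt = 1e-4 s` (a tenth of the fastest time constant),
  all derivatives evaluated on the pre-step state (Jacobi update).  Halving
  dt changes single-PS spike counts by < 0.1%.
* The production integrator is a numba-compiled kernel; a plain-numpy
  `step()` with identical semantics serves as the readable reference and is
  tested to agree with the kernel to ~1e-10 over thousands of steps.
* Thalamocortical z of channels receiving no drive follows the exact
  exponential recovery solution (applied lazily per channel); driven
  channels take the same Euler step as everything else.  This is exact for
  the linear silent phase and removes the dominant cost of tracking ~20k
  z variables.
* Rates below 1e-12 spikes/s are flushed to exactly zero after each step.
  Silent neurons otherwise decay into denormal floating-point numbers,
  which stall the FPU (a ~50x slowdown); the flush is far below any
  physical rate and below the 1e-6 activity threshold.
* Rate and resource bounds (0 <= rate <= E_max, 0 < x, y, z <= 1) are
  consequences of the update map at this dt and are asserted in tests, not
  enforced by clipping.
* Runs are bit-identical given (network seed, sequence seed); all
  randomness flows through named substreams of one master seed.

## Analysis definitions

* **Spike count**: trapezoid integral of the (column-mean or per-neuron)
  rate minus its 5 ms pre-onset baseline, from onset to 45 ms after offset,
  at the 1 ms recording resolution.  Counts can be slightly negative for
  suppressed responses.  Each protocol run starts with 10 ms of recorded
  silence so the first trial has its baseline window.
* **PS detection**: count >= 0.5 spikes/neuron (configurable).  In this
  implementation the per-trial count distribution is bimodal with non-PS
  responses below ~0.4 even at strong drive and attenuated steady-state
  PSs (Periodic/Reliable regimes, refractory propagation) at 0.55–0.8;
  fully recovered PSs integrate to ~0.9–1.  A threshold at 1 would split
  the PS mode.
* **CSI**: condition means pooled over all occurrences and blocks,
  including deviants weakened by recent deviants.  Per-neuron CSI uses the
  same window on each neuron's own trace; neurons with non-positive
  denominator are reported NaN and excluded from summaries (none occur at
  defaults).
* **Regimes**: pooled over both oddball conditions.  Bursting if any
  sliding-window (95 ms) count outside all stimulus windows reaches the PS
  threshold; else NoPS if no PS after each run's first trial; else Reliable
  if the PS fraction is >= 0.9 for standards and deviants; else Selective
  if the deviant fraction is >= 0.5 with standard fraction <= 0.1; else
  Periodic.  The numeric cut-offs are operational choices, exposed as
  arguments and reported with their supporting fractions.
* Oddball blocks are independent runs from the cached rest state, so block
  averages are i.i.d. given the tuning draw.

## Analytic resource map

For periodic square pulses the thalamocortical resource ODE is affine, so
z at successive onsets/offsets follows an iterated affine map with slope
`k_dur * k_isi < 1`; its unique fixed point is evaluated in closed form
(`fixed_points`, `z_plane`).  The closed form ignores the 5 ms envelope
ramps; against square-pulse ODE integration it agrees to |dz| < 1e-4
typically (1e-3 asserted over random parameter draws), and against the full
simulator to a few percent.

## Problem sizes used by tests and the acceptance script

Column-mean CSI uses one network with 10 blocks of both oddball conditions;
the across-network mean uses 4 networks x 3 blocks (the published setting
averaged 12 networks x 10 blocks; the across-network spread is ~0.015, so
4 networks determine the mean to well within the reported tolerance).  The
regime map is probed on a 4 x 4 amplitude x ISI grid with 50-trial
sequences; the deviance-sensitivity comparison uses 4 networks x 3 blocks.
These sizes were chosen as the smallest that leave the assertions far from
their noise floor.

## Limitations

* No input noise, synaptic delays, conductances, or cell-type diversity
  beyond one E and one I population; purely feedback inhibition.
* Regime *boundaries* in parameter planes are reproduced qualitatively
  (ordering and topology), not cell-by-cell; they depend on the PS count
  threshold and on exact resource levels.
* Spontaneous bursting appears for `tau_rec` roughly in 0.1–0.25 s; at
  still faster recovery (0.05 s) the silent state becomes a stable
  high-rate fixed point without discrete PS events.
* CSI growth with frequency separation (df = 2 -> 6) and the deviant >
  Diverse-Broad contrast are modest effects that require averaging over
  full-length sequences and several blocks/networks; single 50-trial runs
  can show the opposite sign.
* The 45 ms post-offset response window overlaps the next trial when the
  offset-to-onset gap is shorter than 45 ms (by construction, as in the
  original analysis); baselines may then sit on the previous response tail.
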