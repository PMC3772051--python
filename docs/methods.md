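# Model and methods

This note documents the model implemented in `ellcancel`, the choices made
where the design was genuinely open, and what the shipped tests do and do not
establish. Defaults quoted here are the package defaults; everything is
configurable through the dataclasses in each module.

## Circuit and stimulus

The electrosensory lateral-line lobe (ELL) receives two copies of every
global amplitude modulation (AM): a direct feedforward copy through the
P-unit electroreceptor afferents, and an indirect copy through deep pyramidal
cells, the nucleus praeminentialis, the granule cells of the eminentia
granularis posterior, and their parallel fibers (PFs) back onto the
superficial pyramidal (SP) cell. Local AMs drive only the feedforward path.
The model collapses each stage to its functional role:

* A sinusoidal AM of frequency `f` (Hz) and contrast `c` (% of the carrier
  amplitude) is encoded by the P-unit population as a rate modulation
  `S(t) = a(f) * b(c) * sin(2*pi*f*t)` in the dimensionless voltage units of
  the neuron model. `b(c)` is piecewise-linear through calibrated points,
  non-decreasing and concave (the encoder is quasi-linear to roughly 10 %
  contrast and saturates above), clamped above the last calibrated contrast.
  `a(f)` is a constant adaptation factor (default 0.9) applied at and below
  the lowest studied frequency band (2 Hz). Stimulus contrasts are accepted
  up to 25 %; both `b(c)` and the feedback saturation clamp above 20 %, so a
  25 % stimulus drives the circuit at the saturated 20 % level.
* The PF population is reduced to one frequency-specific channel per AM
  frequency: the stimulus cycle is tiled by phase segments of ~2 ms
  (retimed exactly so an integer number of segments covers the period), one
  PF active per segment, each with a plastic weight `w_j in [0, w_max]`.

## SP neuron

Membrane dynamics (threshold 1, reset 0, times in seconds):

```
tau_m dV/dt = -V + [I + S(t)]_+  + sigma*xi(t) + B(t) + G*(w_j(t) - g*V)
```

with `tau_m = 7 ms`, `tau_ref = 0.7 ms`, `I = 0.59`, `sigma = 0.768`,
`g = 1.44`. The feedforward drive is rectified (electroreceptor input is
strictly excitatory). `xi` is Gaussian noise of zero mean and unit variance
after first-order low-pass filtering at `f_cut = 500 Hz`; the AR(1)
innovation variance is chosen so the stationary variance is exactly one, and
`sigma` scales it at the point of use.

**DAP bursting.** After each spike the soma receives a depolarizing
after-potential modeled as a rectified difference of alpha functions,
`B(t) = alpha * q * [a(t - t0; beta) - a(t - t0; gamma)]_+` with
`a(x; tau) = (x/tau) exp(-x/tau)`, `alpha = 20`, `beta = 2.45 ms`,
`gamma = 1.4 ms`, and a per-spike impulse `q = 1` feeding the two alpha
cascades. Because `gamma < beta` the difference is zero for ~1.8 ms and then
a positive bump peaking ~5 ms after the spike, which reliably triggers a
follow-up spike. The DAP is suppressed whenever the preceding inter-spike
interval is shorter than a *dynamic dendritic refractory period* `r(t)`,
which relaxes to `r_s = 0.7 ms` with `tau_b = 7 ms` and is incremented at
every spike by `mu3 * (mu1 + mu2 * exp(-ISI / mu4))`
(`mu1 = 0.6, mu2 = 2, mu3 = 0.7 ms, mu4 = 24.5 ms`). Short intra-burst
intervals pump `r` above the intra-burst ISI, silencing the DAP and
terminating the burst; baseline activity is a mixture of isolated spikes and
2–5-spike bursts with a clearly bimodal ISI distribution.

The waveform normalisation (`q`) and the exact coupling of the refractory
increments are not uniquely determined by the published coefficient tables;
the forms above are the package's choices, with every coefficient exposed.
`q = 1` was fixed so that baseline activity bursts robustly (2–5 spikes per
burst) without entering self-sustained chain firing; both failure modes
occur within a factor of ~3 of this value.

**Integration.** Fixed-step Euler–Maruyama at `dt = 0.025 ms` (≪ `tau_ref`
and ≪ `1/f_cut`), threshold crossings handled at grid points, spike times
strictly increasing with ISIs ≥ `tau_ref`. The DAP cascades, the noise
filter and `r(t)` use exact exponential updates per step. A convergence test
verifies the constant-drive firing period approaches the closed form
`tau_m ln(D/(D - 1)) + tau_ref` as `dt` shrinks. The inner loop is
JIT-compiled (numba); the python-level `feedback_term`, `dap_step` and
`register_spike` define the reference semantics and are cross-checked
against the kernel in the tests.

## Feedback pathway

The active segment contributes `G(c) * (w_j - g*V)`: excitation proportional
to the segment weight, minus disynaptic (stellate-cell) shunting inhibition.
The inhibitory reversal potential sits near rest, so inhibition enters as an
extra conductance (a term proportional to `-V`) rather than a
hyperpolarising current. Both components carry the global strength

```
G(c) = G0 * s(c) * b(c) * a(f) * h(f)
```

because the interneurons are recruited by the same PF activity as the
excitation; this keeps the excitation/inhibition balance — and the mean
firing rate under global stimulation — approximately contrast-invariant, and
it is the mechanism behind contrast-invariant cancellation: feedforward and
feedback modulation both scale with `b(c)`, so weights learned at one
contrast remain matched at others. `s(c)` is the feedback saturation factor
(1 up to 10 %, 0.95 at 15 %, 0.9 at 20 %, clamped outside, linear between;
disable with `saturation_enabled=False`); `h(f)` reduces the gain by 0.9 at
the top studied frequency (16 Hz), where granule cells begin to fail to
burst every cycle. `G` is identically zero for local stimuli.

An alternative, weight-coupled grouping `G * w_j * (1 - g*V)` is available
behind the `shunt_strategy="coupled"` flag. It is not the default because
with `g = 1.44` it caps the voltage reachable through feedback at
`1/g = 0.69 < 1`: the feedback could then never raise the firing rate at the
stimulus trough, and over-cancellation — which the trained circuit does
exhibit — would be structurally impossible.

`G0 = 3` by default: the smallest baseline gain at which the equilibrated
negative image retains headroom to both the floor (`w = 0`) and the
homeostatic ceiling (`w = w_max`) across learning contrasts. The
`calibrate` pipeline recovers `G0` by bisection on the mean firing rate
under global stimulation at (8 Hz, 10 %) with uniform `w = w_max` weights
(the pre-learning convention, so calibration needs no trained state); the
synthetic reference's rate target corresponds to the default.

## Plasticity

Bursts are detected online: a *small* burst is exactly 2 spikes within
10 ms, a *large* burst exactly 4 spikes within 100 ms; a greedy
left-to-right scan prefers the largest valid burst at each unconsumed spike
and consumes its spikes, so burst spike sets are disjoint and a small burst
can never sit inside a large one (the detector is verified against an
exhaustive preference-ordered search). A burst's time is its first spike.

Each postsynaptic burst at `t_post` depresses every segment whose onset
`t_j` satisfies `0 <= t_post - t_j <= W_k`:

```
w_j <- [w_j - eta_k * K_k(t_post - t_j)]_+
```

with `eta_2 = 0.0018` (small) and `eta_4 = 0.0036` (large), and a causal
kernel `K_k` decaying linearly over its window `W_k` (exponential and
raised-cosine shapes are available). The presynaptic granule-cell burst is
assumed to match the postsynaptic burst type. Depression alone is balanced
by a non-associative homeostatic potentiation relaxing all weights toward
`w_max = 1.5` with `tau_w = 980 s`, applied in closed form between events.

**Kernel windows.** `W_small = 3 ms`, `W_large = 9 ms`. The windows are the
one place where the published constants over-determine the dynamics: with
the fixed `eta`/`tau_w` pair and the model's emergent burst rate (~4–6
bursts/s), kernels spanning tens of milliseconds deposit so much depression
per segment that every weight collapses to zero (and windows longer than the
8/16 Hz periods are phase-blind, erasing the negative image). The shipped
windows are the scale at which depression balances `tau_w = 980 s` at a
living equilibrium; they should be refit if the underlying in-vitro timing
data are consulted.

**Training.** `train_to_equilibrium` alternates simulation epochs (16
stimulus cycles with frozen weights) with event-driven updates, runs at
least ~3 `tau_w` of simulated time, and reports the mean profile over the
last 25 epochs (at stationarity the weights fluctuate around the fixed point
with the granularity of single depression events; the epoch average is the
deterministic equilibrium estimate). Non-convergence within `max_epochs` is
flagged on the result, never silent. For desk-scale runs the experiments
rescale `(tau_w / kappa, eta * kappa)` with `kappa = 10` by default: the
equilibrium balance is exactly preserved while the transient shortens by
`kappa`; `kappa = 1` runs the full-scale rule.

## Measurement

Responses are summarised by 32-bin cycle histograms over whole stimulus
cycles (spike count conserved exactly). Global responses are fitted with
`b0 + A sin(phi + phi0)` (linear least squares); local responses are
rectified and fitted with a circular Gaussian bump plus baseline
(initialised at the argmax bin), whose height is `A_local`. Cancellation is
`C = 1 - A_global/A_local`, reported unclipped (values < 0 are
over-cancellation); degradation is `D(c) = 1 - <C(f, c)>_f`; model and
reference degradation curves are compared by the summed squared difference
over the contrast grid (capped at 20 %). `classify_residual` additionally
signs the residual modulation by its phase relative to a feedback-free
simulation: positive = in phase (under-cancellation), negative = anti-phase
(over-cancellation).

## Synthetic reference

The calibration targets and the reference degradation curve stand in for
summary statistics of in-vivo recordings and are configuration, not data:
local peak cycle rates {150, 240, 300, 340} Hz at {5, 10, 15, 20} %
(increasing, concave — encoder saturation), a 30 Hz baseline, a
pre-learning global mean rate of 188 Hz at (8 Hz, 10 %), and a degradation
band rising gently from 0.05 at 5 % to 0.095 at 20 %. Histogram surrogates
add per-bin Gaussian jitter (SD 5 spikes/s; zero jitter reproduces the means
exactly). The generator emulates the *structure* of the recordings —
rectified local responses, near-flat global responses, narrow rising
degradation — but none of their trial-to-trial correlations, cell-to-cell
heterogeneity or non-stationarity, so passing the closed-loop tests shows
the pipeline is self-consistent, not that it would fit any particular real
dataset.

## Scans

`scan_learning_contrast` equilibrates each frequency channel at each
learning contrast, tests the whole grid with those frozen weights, and
scores each degradation curve against the reference band; the arg-min is
the model's optimal learning contrast. `scan_tau_w` repeats the scan per
potentiation time constant and reports the minimum error per `tau_w`.
`scripts/acceptance.py` runs the learning-contrast scan at
{5, 10, 15, 20, 25} % over the 4 and 8 Hz channels (the centre of the
cancellation band) with the default contrast grid — 40 simulated
conditions, desk-scale `kappa = 10`.

## Known limitations

* The plasticity equilibrium is reached when burst-driven depression
  balances potentiation, which happens slightly *before* the global response
  is fully flattened; the standing residual (typically 4–6 % of the local
  response) is in phase with the stimulus and varies with learning contrast
  mainly through how precisely bursts phase-lock during learning. The
  5–10 % differential contributed by the saturation factors `s(c)` is of the
  same order, so the location of the optimal learning contrast is sensitive
  to the reference band and to seed-level noise in a way the underlying
  biological result may not be.
* Under strong feedback the globally driven cell operates at low mean rates
  (≈10–40 Hz versus ≈100–150 Hz locally), where the rate–drive slope is
  shallow; gain mismatches are therefore compressed in the measured
  cancellation, and over-cancellation tends to appear as suppression of the
  response rather than as a prominent anti-phase modulation.
* Frequency channels are independent by construction (frequency specificity
  is assumed, not derived); aperiodic or time-varying-contrast stimuli and
  heterogeneous SP populations are out of scope.
* Exact numerical agreement with the published figures is not expected: the
  DAP normalisation, LTD kernel windows, `b(c)` levels and reference band
  are package choices within the published structural constraints.
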