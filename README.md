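# ellcancel

Contrast-invariant cancellation of redundant electrosensory signals in a
cerebellar-like circuit.

Wave-type weakly electric fish sense their world through amplitude
modulations (AMs) of their own electric organ discharge. Spatially *local*
AMs (prey) and spatially *global* AMs (conspecifics, tail bending) are both
encoded by P-unit electroreceptors, yet superficial pyramidal (SP) cells of
the electrosensory lateral-line lobe (ELL) respond strongly only to local
stimuli: a massive, heterogeneously delayed parallel-fiber (PF) feedback
pathway learns a *negative image* of the redundant global signal and cancels
it by destructive interference. Remarkably, this cancellation is nearly
invariant to the stimulus contrast (AM depth), even though the PF weights
cannot re-learn each new contrast.

`ellcancel` implements the full model of this circuit, for computational
neuroscientists studying redundancy suppression and burst-dependent
plasticity:

* **SP neuron** — a stochastic leaky integrate-and-fire cell,
  `tau_m dV/dt = -V + [I + S(t)]_+ + sigma*xi(t) + B(t) + feedback`,
  with low-pass-filtered Gaussian noise `xi`, rectified feedforward drive and
  a depolarizing after-potential (DAP) current `B(t)` gated by a dynamic
  dendritic refractory period, which makes the cell fire 2–5-spike bursts.
* **P-unit encoder** — the population drive `S(t) = a(f) * b(c) * sin(2*pi*f*t)`
  with a saturating contrast transfer `b(c)` calibrated from peak
  cycle-histogram rates, and low-frequency adaptation `a(f)`.
* **PF feedback** — one stimulus cycle tiled by ~2 ms phase segments, one
  active PF per segment, contributing `G(c) * (w_j - g*V)` (excitation plus
  disynaptic shunting inhibition), with gain `G(c) = G0 * s(c) * b(c)`
  carrying the P-unit drive and an optional pathway-saturation factor `s(c)`.
* **Burst plasticity** — small (2 spikes / 10 ms) and large (4 spikes /
  100 ms) bursts trigger timing-dependent depression
  `w_j <- [w_j - eta_k * K_k(t_burst - t_j)]_+` of recently active segments,
  balanced by slow homeostatic potentiation toward `w_max` with time constant
  `tau_w = 980 s`.
* **Cancellation metrics** — cycle histograms, sine fits (global) and
  circular Gaussian fits (local), cancellation `C = 1 - A_global / A_local`,
  degradation `D(c) = 1 - <C(f, c)>_f`, and the summed-squared-error scan of
  `D` against a reference curve over learning contrasts and `tau_w`.
* **Synthetic reference** — a surrogate of the in-vivo observables (local and
  global cycle histograms, rate targets, a gently rising degradation band)
  so calibration and scans run fully self-contained.

## Worked example

Train the 8 Hz feedback channel at 15 % learning contrast, then test global
stimuli at other contrasts with the *same* frozen weights:

```python
import numpy as np
from ellcancel import (
    ExperimentConfig, StimulusSpec, DEFAULT_TRANSFER, DEFAULT_GAIN,
    train_channel, simulate, compute_psth, fit_global_sine,
    fit_local_amplitude, cancellation,
)
from ellcancel.feedback import feedback_gain, feedback_shunt

cfg = ExperimentConfig(frequencies=(8.0,), seed=0)          # 8 Hz channel
pf = train_channel(cfg, 8.0).pf                             # learn at 15 %
r = np.corrcoef(pf.weights, np.sin(pf.phases))[0, 1]
print(f"trained {pf.n_segments} PF segments; corr(weights, stimulus) = {r:.2f}")

for c in (5.0, 10.0, 15.0, 20.0):
    local = simulate(StimulusSpec(8.0, c, 60.0, "local"), DEFAULT_TRANSFER, seed=1)
    a_local = fit_local_amplitude(compute_psth(local, 8.0, duration=60.0))
    G = feedback_gain(c, DEFAULT_TRANSFER, DEFAULT_GAIN, "global", 8.0)
    sh = feedback_shunt(c, DEFAULT_TRANSFER, DEFAULT_GAIN, "global", 8.0)
    spikes = simulate(StimulusSpec(8.0, c, 60.0, "global"), DEFAULT_TRANSFER, pf,
                      feedback_gain=G, feedback_shunt=sh, seed=2)
    a_global, _, _ = fit_global_sine(compute_psth(spikes, 8.0, duration=60.0))
    print(f"contrast {c:4.0f} %: A_local = {a_local:6.1f} Hz, "
          f"A_global = {a_global:5.1f} Hz, C = {cancellation(a_local, a_global):.3f}")
```

Output:

```
trained 62 PF segments; corr(weights, stimulus) = -0.98
contrast    5 %: A_local =  134.4 Hz, A_global =   8.5 Hz, C = 0.937
contrast   10 %: A_local =  217.2 Hz, A_global =   8.6 Hz, C = 0.960
contrast   15 %: A_local =  271.8 Hz, A_global =  11.0 Hz, C = 0.959
contrast   20 %: A_local =  292.2 Hz, A_global =  14.7 Hz, C = 0.950
```

The equilibrated weight profile is a negative image of the stimulus
(correlation −0.98), and a channel trained at a single contrast cancels
94–96 % of the global response at *every* test contrast — contrast-invariant
cancellation. The local response, by contrast, grows from 134 to 292 Hz.

The same pipelines are scriptable from the shell:

```bash
ellcancel --seed 1 --outdir results run-cancel        # full grid
ellcancel --seed 1 --outdir results scan-lc           # learning-contrast scan
ellcancel --seed 1 --no-saturation run-cancel         # Fig-4-style variant
```

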