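"""Superficial pyramidal (SP) cell: stochastic LIF with a DAP burst mechanism.

Membrane dynamics (dimensionless voltage, threshold 1, reset 0):

    tau_m dV/dt = -V + [I + S(t)]_+ + sigma*xi(t) + B(t) + feedback(t, V)

``[.]_+`` rectifies the feedforward drive (electroreceptor input is strictly
excitatory), ``xi`` is zero-mean unit-variance Gaussian noise low-pass
filtered at ``f_cut``, and ``B(t)`` is the depolarizing after-potential (DAP):
a brief somatic current injection following each spike that produces the
characteristic burst firing of SP cells.

DAP mechanism.  After a spike at t0 the cell receives, a short time later, a
current shaped as a (rectified) difference of alpha functions,

    B(t) = alpha * [ a(t - t0; beta) - a(t - t0; gamma) ]_+ ,
    a(x; tau) = (x / tau) * exp(-x / tau)   (peak 1/e at x = tau),

with gamma < beta so the difference is a delayed, unimodal positive bump
(peak ~0.17 * alpha about 5 ms after the spike).
The DAP is suppressed ("inactive for the current spike") whenever the
preceding inter-spike interval is shorter than a dynamic dendritic refractory
period r(t), which relaxes to a baseline r_s with time constant tau_b and is
incremented at every spike by mu3 * (mu1 + mu2 * exp(-ISI / mu4)).  Short
intra-burst intervals pump r up until it exceeds the intra-burst ISI, which
silences the DAP and terminates the burst; r then decays back.

Integration is fixed-step Euler-Maruyama (threshold handled at grid points);
the DAP states, the noise filter and r use exact exponential updates over each
step.  The inner loop is JIT-compiled with numba.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.signal import lfilter, lfilter_zi

from .stimulus import PUnitTransfer, StimulusSpec

__all__ = [
    "NeuronParams",
    "DAPParams",
    "NeuronState",
    "filtered_noise",
    "dap_waveform",
    "dap_step",
    "register_spike",
    "simulate",
    "save_spike_train",
    "lif_period",
    "DEFAULT_DT",
]

#: Default integration step (s): 0.025 ms, well below tau_ref and 1/f_cut.
DEFAULT_DT = 2.5e-5


@dataclass(frozen=True)
class NeuronParams:
    """LIF parameters (times in seconds, voltages dimensionless)."""

    v_th: float = 1.0
    v_r: float = 0.0
    tau_m: float = 7e-3
    tau_ref: float = 0.7e-3
    bias: float = 0.59       # constant bias I fitting spontaneous activity
    sigma: float = 0.768     # noise scale
    f_cut: float = 500.0     # noise low-pass cutoff (Hz)

    def __post_init__(self) -> None:
        if self.v_th <= self.v_r:
            raise ValueError("v_th must exceed v_r")
        if self.tau_m <= 0 or self.tau_ref <= 0:
            raise ValueError("time constants must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class DAPParams:
    """DAP / dendritic refractory parameters (times in seconds)."""

    alpha: float = 20.0
    beta: float = 2.45e-3
    gamma: float = 1.4e-3
    mu1: float = 0.6
    mu2: float = 2.0
    mu3: float = 0.7e-3
    mu4: float = 24.5e-3
    r_s: float = 0.7e-3
    tau_b: float = 7e-3
    #: per-spike impulse fed into each alpha cascade; together with alpha it
    #: sets the DAP amplitude (peak current ~ 0.17 * alpha * impulse)
    impulse: float = 1.0

    def __post_init__(self) -> None:
        for name in ("beta", "gamma", "mu3", "mu4", "r_s", "tau_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class NeuronState:
    """Mutable integration state (exposed for step-level tests)."""

    v: float = 0.0
    t_last_spike: float = -np.inf
    t_prev_spike: float = -np.inf
    r: float = 0.7e-3            # dynamic dendritic refractory period
    y_beta: float = 0.0          # alpha-cascade first stages
    y_gamma: float = 0.0
    u_beta: float = 0.0          # alpha-cascade outputs; B = alpha*[u_b - u_g]_+
    u_gamma: float = 0.0
    xi: float = 0.0              # filtered-noise state
    refractory_until: float = -np.inf

    def dap_current(self, params: DAPParams) -> float:
        return params.alpha * max(self.u_beta - self.u_gamma, 0.0)


# ---------------------------------------------------------------------------
# Filtered noise
# ---------------------------------------------------------------------------

def filtered_noise(
    params: NeuronParams, dt: float, n_steps: int, seed: int
) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian noise low-pass filtered at f_cut.

    First-order (AR(1)) low-pass with pole exp(-2*pi*f_cut*dt), driven by white
    Gaussian innovations scaled so the stationary variance is exactly one.
    """
    nyquist = 0.5 / dt
    if params.f_cut >= nyquist:
        raise ValueError(
            f"f_cut={params.f_cut} Hz requires dt < {0.5 / params.f_cut:.2e} s"
        )
    a = math.exp(-2.0 * math.pi * params.f_cut * dt)
    b = math.sqrt(1.0 - a * a)
    rng = np.random.default_rng(seed)
    w = rng.standard_normal(n_steps)
    zi = lfilter_zi([b], [1.0, -a]) * rng.standard_normal()
    xi, _ = lfilter([b], [1.0, -a], w, zi=zi)
    return xi


# ---------------------------------------------------------------------------
# DAP reference implementation (python level, used by tests and docs)
# ---------------------------------------------------------------------------

def dap_waveform(params: DAPParams, x: "np.ndarray | float") -> "np.ndarray | float":
    """Closed-form DAP current a time ``x`` after an isolated (active) spike."""
    x = np.asarray(x, dtype=float)
    a_b = np.where(x > 0, (x / params.beta) * np.exp(-x / params.beta), 0.0)
    a_g = np.where(x > 0, (x / params.gamma) * np.exp(-x / params.gamma), 0.0)
    return params.alpha * params.impulse * np.maximum(a_b - a_g, 0.0)


def dap_step(state: NeuronState, params: DAPParams, dt: float) -> float:
    """Advance the DAP cascade and the dendritic refractory variable by dt.

    Exact exponential updates; returns the DAP current B after the step.
    """
    for tau, y_attr, u_attr in (
        (params.beta, "y_beta", "u_beta"),
        (params.gamma, "y_gamma", "u_gamma"),
    ):
        decay = math.exp(-dt / tau)
        y = getattr(state, y_attr)
        u = getattr(state, u_attr)
        setattr(state, u_attr, (u + y * dt / tau) * decay)
        setattr(state, y_attr, y * decay)
    state.r = params.r_s + (state.r - params.r_s) * math.exp(-dt / params.tau_b)
    return state.dap_current(params)


def register_spike(state: NeuronState, params: DAPParams, t: float) -> bool:
    """Record a spike at time t; returns True if the DAP was activated.

    The DAP is injected only when the preceding inter-spike interval is at
    least the current dendritic refractory period r(t); the refractory period
    itself is incremented for every spike.
    """
    isi = t - state.t_last_spike
    active = isi >= state.r
    if active:
        # impulse into each alpha cascade: response impulse*(x/tau)*exp(-x/tau)
        state.y_beta += params.impulse
        state.y_gamma += params.impulse
    state.r += params.mu3 * (params.mu1 + params.mu2 * math.exp(-isi / params.mu4))
    state.t_prev_spike = state.t_last_spike
    state.t_last_spike = t
    return active


# ---------------------------------------------------------------------------
# Simulation kernel
# ---------------------------------------------------------------------------

@njit(cache=False)
def _lif_kernel(
    n_steps, dt, amp, omega, phase0, bias, sigma, tau_m, v_th, v_r, tau_ref,
    noise_a, noise_b, dap_on, alpha, beta, gamma, mu1, mu2, mu3, mu4, r_s, tau_b,
    impulse, gain, weights, seg_dur, n_seg, g_shunt, shunt, coupled, seed, v_out,
    record_v,
):  # pragma: no cover - exercised through simulate()
    np.random.seed(seed)
    v = 0.0
    xi = np.random.normal()
    yb = 0.0
    ub = 0.0
    yg = 0.0
    ug = 0.0
    r = r_s
    t_last = -1e9
    refr_until = -1e9
    d_b = math.exp(-dt / beta)
    d_g = math.exp(-dt / gamma)
    d_r = math.exp(-dt / tau_b)
    max_spikes = int(n_steps * dt / tau_ref) + 2
    spikes = np.empty(max_spikes)
    k = 0
    for n in range(n_steps):
        t = n * dt
        xi = noise_a * xi + noise_b * np.random.normal()
        ub = (ub + yb * dt / beta) * d_b
        yb = yb * d_b
        ug = (ug + yg * dt / gamma) * d_g
        yg = yg * d_g
        r = r_s + (r - r_s) * d_r
        ff = bias + amp * math.sin(omega * t + phase0)
        if ff < 0.0:
            ff = 0.0
        drive = ff + sigma * xi
        if dap_on:
            b_cur = ub - ug
            if b_cur > 0.0:
                drive += alpha * b_cur
        if gain != 0.0:
            j = int(t / seg_dur) % n_seg
            if coupled:
                drive += gain * weights[j] * (1.0 - g_shunt * v)
            else:
                drive += gain * weights[j] - shunt * v
        if t < refr_until:
            v = v_r
        else:
            v += dt * (drive - v) / tau_m
            if v >= v_th:
                spikes[k] = t
                k += 1
                isi = t - t_last
                if dap_on and isi >= r:
                    yb += impulse
                    yg += impulse
                r += mu3 * (mu1 + mu2 * math.exp(-isi / mu4))
                t_last = t
                v = v_r
                refr_until = t + tau_ref
        if record_v:
            v_out[n] = v
    return spikes[:k]


def simulate(
    spec: StimulusSpec,
    transfer: PUnitTransfer | None = None,
    feedback=None,
    *,
    params: NeuronParams | None = None,
    dap_params: DAPParams | None = None,
    dt: float = DEFAULT_DT,
    seed: int = 0,
    feedback_gain: float = 0.0,
    feedback_shunt: float | None = None,
    amplitude: float | None = None,
    dap_enabled: bool = True,
    record_v: bool = False,
):
    """Simulate the SP cell for one stimulus; returns ordered spike times (s).

    Parameters
    ----------
    spec, transfer
        Stimulus and P-unit transfer; the feedforward amplitude is
        a(f)*b(c) unless overridden via ``amplitude`` (used during transfer
        calibration, where b(c) is the unknown).
    feedback
        A :class:`~ellcancel.feedback.PFArray`, or None.  Must be None for
        local stimuli (local stimulation does not recruit the feedback
        pathway).  The contribution of the active phase segment j is
        ``feedback_gain * w_j - feedback_shunt * V`` (conductance strategy;
        ``feedback_shunt`` defaults to the array's g), or ``feedback_gain *
        w_j * (1 - g*V)`` with the coupled-shunt strategy.
    record_v
        If True, return ``(spike_times, v_trace)``.
    """
    params = params or NeuronParams()
    dap_params = dap_params or DAPParams()
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if spec.duration <= 0:
        raise ValueError("duration must be > 0")
    nyquist = 0.5 / dt
    if params.f_cut >= nyquist:
        raise ValueError("dt too large for the noise cutoff f_cut")
    if spec.stimulus_type == "local" and feedback is not None:
        raise ValueError("local stimuli do not activate the feedback pathway")

    if amplitude is None:
        if transfer is None:
            raise ValueError("either a transfer or an explicit amplitude is required")
        amp = transfer.adaptation(spec.am_frequency) * transfer.amplitude(spec.contrast)
    else:
        amp = float(amplitude)

    if feedback is not None and feedback_gain != 0.0:
        weights = np.ascontiguousarray(feedback.weights, dtype=np.float64)
        seg_dur = feedback.segment_duration
        n_seg = feedback.n_segments
        g_shunt = feedback.shunt_coefficient
        coupled = feedback.shunt_strategy == "coupled"
        gain = float(feedback_gain)
        shunt = g_shunt if feedback_shunt is None else float(feedback_shunt)
    else:
        weights = np.zeros(1)
        seg_dur = 1.0
        n_seg = 1
        g_shunt = 0.0
        shunt = 0.0
        coupled = True
        gain = 0.0

    n_steps = int(round(spec.duration / dt))
    noise_a = math.exp(-2.0 * math.pi * params.f_cut * dt)
    noise_b = math.sqrt(1.0 - noise_a * noise_a) if params.sigma > 0 else 0.0
    sigma = params.sigma if params.sigma > 0 else 0.0
    v_out = np.empty(n_steps if record_v else 1)
    spikes = _lif_kernel(
        n_steps, dt, amp, 2.0 * math.pi * spec.am_frequency, spec.phase_origin,
        params.bias, sigma, params.tau_m, params.v_th, params.v_r, params.tau_ref,
        noise_a, noise_b, dap_enabled, dap_params.alpha, dap_params.beta,
        dap_params.gamma, dap_params.mu1, dap_params.mu2, dap_params.mu3,
        dap_params.mu4, dap_params.r_s, dap_params.tau_b, dap_params.impulse,
        gain, weights, seg_dur, n_seg, g_shunt, shunt, coupled,
        int(seed) % (2**31 - 1), v_out, record_v,
    )
    if record_v:
        return spikes, v_out
    return spikes


def save_spike_train(spikes: np.ndarray, path) -> None:
    """Write spike times as a one-column CSV (seconds)."""
    np.savetxt(path, np.asarray(spikes), fmt="%.9f", header="spike_time_s", comments="")


def lif_period(drive: float, params: NeuronParams | None = None) -> float:
    """Closed-form firing period of the noise-free, DAP-free LIF.

    For constant suprathreshold drive D > v_th the period is
    tau_m * ln(D / (D - v_th)) + tau_ref (with v_r = 0).
    """
    params = params or NeuronParams()
    if drive <= params.v_th:
        return math.inf
    return params.tau_m * math.log(drive / (drive - params.v_th)) + params.tau_ref
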