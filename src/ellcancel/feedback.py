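"""Parallel-fiber (PF) feedback pathway.

The feedback cycle locked to the AM stimulus is discretised into short phase
segments; exactly one PF (segment) is active at any time, delivering a
step-wise constant, periodic drive to the SP cell.  The active segment j
contributes

    G * (w_j - g * V)              (default, "conductance" shunt)

i.e. excitation proportional to the segment weight w_j minus PF-driven
disynaptic shunting inhibition proportional to the membrane potential (the
inhibitory reversal potential sits near rest, so inhibition acts as an extra
conductance rather than a hyperpolarising current).  The global strength G
multiplies the whole term: the stellate-cell inhibition is recruited by the
same PF activity as the excitation, so saturation and adaptation scale both
components alike and the excitation/inhibition balance is contrast-invariant.
An alternative "coupled" strategy, G * w_j * (1 - g * V), ties the shunt to
the active weight; it caps the voltage the feedback alone can reach at 1/g
and is kept as a sensitivity flag only.

The global feedback gain is driven by the same P-unit population as the
feedforward pathway:

    G(c) = G0 * s(c) * b(c) * a(f) * h(f)

where b(c) is the P-unit transfer, a(f) the low-frequency adaptation factor,
s(c) <= 1 an optional saturation factor of the feedback pathway at high
contrast (granule-cell / PF synapse saturation), and h(f) an optional gain
reduction at the top AM frequency (granule cells failing to burst every cycle
at high f).  G is identically zero for local stimuli.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .stimulus import PUnitTransfer

__all__ = [
    "PFArray",
    "FeedbackGain",
    "DEFAULT_GAIN",
    "build_segments",
    "feedback_gain",
    "feedback_shunt",
    "feedback_term",
    "pathway_factor",
    "saturation_factor",
]

logger = logging.getLogger(__name__)

#: Default synaptic ceiling and shunting coefficient.
W_MAX = 1.5
SHUNT_G = 1.44


@dataclass
class PFArray:
    """Per-phase-segment PF weights for one AM-frequency channel.

    ``segment_duration`` is the *effective* duration (s): the stimulus period
    divided by ``n_segments``, so the onsets t_j = j * segment_duration tile
    one period exactly.  Weights are clipped to [0, w_max].
    """

    n_segments: int
    segment_duration: float
    weights: np.ndarray
    w_max: float = W_MAX
    shunt_coefficient: float = SHUNT_G
    shunt_strategy: str = "conductance"

    def __post_init__(self) -> None:
        if self.n_segments < 2:
            raise ValueError("need at least 2 segments per cycle")
        if self.shunt_strategy not in ("conductance", "coupled"):
            raise ValueError(f"unknown shunt strategy {self.shunt_strategy!r}")
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.n_segments,):
            raise ValueError("weights must have one entry per segment")
        if np.any(self.weights < 0) or np.any(self.weights > self.w_max):
            raise ValueError(f"weights must lie in [0, {self.w_max}]")

    @property
    def period(self) -> float:
        return self.n_segments * self.segment_duration

    @property
    def onsets(self) -> np.ndarray:
        """Segment onset times within one cycle (s, phase-locked)."""
        return np.arange(self.n_segments) * self.segment_duration

    @property
    def phases(self) -> np.ndarray:
        """Segment onset phases (radians in [0, 2*pi))."""
        return 2.0 * math.pi * self.onsets / self.period

    def active_segment(self, t: float) -> int:
        return int(t / self.segment_duration) % self.n_segments

    def copy(self) -> "PFArray":
        return replace(self, weights=self.weights.copy())


def build_segments(
    f: float,
    segment_duration: float = 2e-3,
    *,
    w_max: float = W_MAX,
    shunt_coefficient: float = SHUNT_G,
    shunt_strategy: str = "conductance",
    initial_weights: float | np.ndarray | None = None,
) -> PFArray:
    """Discretise one stimulus cycle at ``f`` Hz into PF phase segments.

    ``n_segments = round(period / segment_duration)``; if the period is not an
    integer multiple of the requested duration, the duration is adjusted to
    tile the period exactly and the residual is logged.  Weights start at
    ``w_max`` (the fixed point of the homeostatic potentiation rule) unless
    given explicitly, so learning only depresses from the relaxed state.
    """
    period = 1.0 / f
    if segment_duration >= period:
        raise ValueError("segment_duration must be shorter than the period")
    n = int(round(period / segment_duration))
    eff = period / n
    residual = abs(eff - segment_duration)
    if residual > 1e-12:
        logger.info(
            "segment duration adjusted %.6g -> %.6g ms to tile the %.6g ms "
            "period (residual %.3g ms)",
            segment_duration * 1e3, eff * 1e3, period * 1e3, residual * 1e3,
        )
    if initial_weights is None:
        w = np.full(n, w_max)
    elif np.isscalar(initial_weights):
        w = np.full(n, float(initial_weights))
    else:
        w = np.asarray(initial_weights, dtype=float)
    return PFArray(
        n_segments=n,
        segment_duration=eff,
        weights=w,
        w_max=w_max,
        shunt_coefficient=shunt_coefficient,
        shunt_strategy=shunt_strategy,
    )


@dataclass(frozen=True)
class FeedbackGain:
    """Contrast- and frequency-dependent global feedback strength.

    ``saturation`` maps contrast (%) to the factor s(c) in (0, 1]; s = 1 at and
    below 10 % contrast, linearly interpolated between table entries and
    clamped outside them.  ``hf_attenuation`` scales the gain at AM frequencies
    at or above ``hf_cutoff`` (set to 1 to disable).
    """

    G0: float
    saturation: tuple[tuple[float, float], ...] = ((10.0, 1.0), (15.0, 0.95), (20.0, 0.9))
    saturation_enabled: bool = True
    hf_attenuation: float = 0.9
    hf_cutoff: float = 16.0

    def __post_init__(self) -> None:
        if self.G0 < 0:
            raise ValueError("G0 must be >= 0")
        pts = tuple(sorted((float(c), float(s)) for c, s in self.saturation))
        object.__setattr__(self, "saturation", pts)
        ss = [s for _, s in pts]
        if any(not 0 < s <= 1 for s in ss):
            raise ValueError("saturation factors must lie in (0, 1]")
        if any(s2 > s1 for s1, s2 in zip(ss, ss[1:])):
            raise ValueError("s(c) must be non-increasing in c")

    def factor(self, contrast: float) -> float:
        return saturation_factor(self, contrast)

    def without_saturation(self) -> "FeedbackGain":
        return replace(self, saturation_enabled=False)


def saturation_factor(gain: FeedbackGain, contrast: float) -> float:
    """Feedback saturation factor s(c): 1 at low contrast, < 1 above ~10 %."""
    if not gain.saturation_enabled:
        return 1.0
    cs = np.array([c for c, _ in gain.saturation])
    ss = np.array([s for _, s in gain.saturation])
    return float(np.interp(contrast, cs, ss))


def feedback_gain(
    contrast: float,
    transfer: PUnitTransfer,
    gain: FeedbackGain,
    stimulus_type: str,
    am_frequency: float,
) -> float:
    """Global feedback strength G(c); exactly zero for local stimuli."""
    if stimulus_type not in ("local", "global"):
        raise ValueError(f"unknown stimulus_type {stimulus_type!r}")
    if stimulus_type == "local":
        return 0.0
    g = gain.G0 * saturation_factor(gain, contrast) * transfer.amplitude(contrast)
    g *= transfer.adaptation(am_frequency)  # P-units drive the feedback too
    if am_frequency >= gain.hf_cutoff:
        g *= gain.hf_attenuation
    return g


def pathway_factor(
    gain: FeedbackGain, contrast: float, am_frequency: float, transfer: PUnitTransfer
) -> float:
    """Multiplicative factor m = s(c) * a(f) * h(f) on the whole feedback term."""
    m = saturation_factor(gain, contrast) * transfer.adaptation(am_frequency)
    if am_frequency >= gain.hf_cutoff:
        m *= gain.hf_attenuation
    return m


def feedback_shunt(
    contrast: float,
    transfer: PUnitTransfer,
    gain: FeedbackGain,
    stimulus_type: str,
    am_frequency: float,
    shunt_coefficient: float = SHUNT_G,
) -> float:
    """Effective shunting conductance G(c) * g; zero for local stimuli.

    The disynaptic inhibition is driven by the same PF activity as the
    excitation, so the whole feedback term - shunt included - carries the
    global strength G(c): the active segment contributes G(c)*(w_j - g*V).
    This keeps the excitation/inhibition balance, and with it the mean firing
    rate under global stimulation, approximately contrast-invariant.
    """
    if stimulus_type == "local":
        return 0.0
    return feedback_gain(contrast, transfer, gain, stimulus_type, am_frequency) * shunt_coefficient


def feedback_term(
    t: float, v: float, pf: PFArray, gain: float, shunt: float | None = None
) -> float:
    """Membrane-equation contribution of the active PF segment at time t.

    Step-wise constant (at fixed V) within a segment and periodic across
    cycles.  This is the reference (python-level) form of the term used inside
    the simulation kernel; ``shunt`` defaults to the array's g for the
    conductance strategy.
    """
    j = pf.active_segment(t)
    if pf.shunt_strategy == "coupled":
        return gain * pf.weights[j] * (1.0 - pf.shunt_coefficient * v)
    if shunt is None:
        shunt = pf.shunt_coefficient
    return gain * pf.weights[j] - shunt * v


# Default baseline gain.  G0 = 3 is the smallest gain for which the
# equilibrated negative image keeps headroom to both the floor (w = 0) and the
# homeostatic ceiling (w = w_max) across learning contrasts; the synthetic
# reference's global mean-rate target corresponds to this value under the
# uniform-weight calibration convention, so `calibrate` recovers it.
DEFAULT_GAIN = FeedbackGain(G0=3.0)
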