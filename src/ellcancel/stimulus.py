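"""Amplitude-modulation stimuli and the P-unit population encoder.

The electric organ discharge (EOD) of a wave-type electric fish carries
amplitude modulations (AMs) characterised by a frequency ``f`` (Hz) and a
*contrast* ``c`` (modulation depth, % of EOD amplitude).  The P-unit
electroreceptor population encodes an AM as a sinusoidal modulation of its
firing rate; the population output driving the pyramidal cell is

    S(t) = a(f) * b(c) * sin(2*pi*f*t)

where ``b(c)`` is the (saturating) contrast -> input-amplitude transfer of the
P-units, expressed in the dimensionless voltage units of the neuron model, and
``a(f)`` is a small constant adaptation factor applied at low AM frequencies
only.  ``b(c)`` is not observable directly; it is obtained by calibrating the
model neuron's cycle-histogram peak rate against target rates measured (here:
synthesised) per contrast, and linearly interpolated in between.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "StimulusSpec",
    "PUnitTransfer",
    "DEFAULT_TRANSFER",
    "am_drive",
    "interpolate_transfer",
    "calibrate_transfer",
    "CalibrationError",
]

#: Model-validated contrast range (%).  P-units encode AMs quasi-linearly up
#: to roughly this depth and saturate beyond it, so the model is not exercised
#: above it.
MAX_CONTRAST = 25.0


class CalibrationError(RuntimeError):
    """Raised when a calibration target cannot be met by the neuron model."""


@dataclass(frozen=True)
class StimulusSpec:
    """A sinusoidal AM stimulus.

    Parameters
    ----------
    am_frequency : float
        AM frequency in Hz (> 0).
    contrast : float
        Modulation depth in percent of EOD amplitude, within [0, 25]
        (the encoder saturates above ~20 %; see PUnitTransfer).
    duration : float
        Stimulus duration in seconds (> 0).
    stimulus_type : {"local", "global"}
        Spatially local stimuli drive only the feedforward pathway; global
        stimuli additionally recruit the parallel-fiber feedback.
    phase_origin : float
        Phase (radians) at t = 0; the convention is s(t) = sin(2*pi*f*t),
        i.e. phase 0 at the ascending zero crossing.
    """

    am_frequency: float
    contrast: float
    duration: float
    stimulus_type: str = "local"
    phase_origin: float = 0.0

    def __post_init__(self) -> None:
        if self.am_frequency <= 0:
            raise ValueError(f"am_frequency must be > 0, got {self.am_frequency}")
        if not 0.0 <= self.contrast <= MAX_CONTRAST:
            raise ValueError(
                f"contrast must be in [0, {MAX_CONTRAST}] %, got {self.contrast}"
            )
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if self.stimulus_type not in ("local", "global"):
            raise ValueError(f"unknown stimulus_type {self.stimulus_type!r}")

    @property
    def period(self) -> float:
        """Stimulus period 1/f in seconds."""
        return 1.0 / self.am_frequency


@dataclass(frozen=True)
class PUnitTransfer:
    """Contrast -> SP-input amplitude map of the P-unit population.

    ``calibration_points`` are (contrast %, amplitude b(c)) pairs; queries are
    linearly interpolated between them and clamped to the last point above the
    calibrated range (the saturated regime).  ``adaptation_factor`` multiplies
    the signal for AM frequencies at or below ``adaptation_cutoff`` to account
    for P-unit adaptation at low frequencies.
    """

    calibration_points: tuple[tuple[float, float], ...]
    adaptation_factor: float = 0.9
    adaptation_cutoff: float = 2.0

    def __post_init__(self) -> None:
        pts = tuple(sorted((float(c), float(b)) for c, b in self.calibration_points))
        object.__setattr__(self, "calibration_points", pts)
        if len(pts) < 2:
            raise ValueError("need at least two calibration points")
        cs = [c for c, _ in pts]
        bs = [b for _, b in pts]
        if cs[0] != 0.0 or bs[0] != 0.0:
            raise ValueError("calibration must include the anchor point (0, 0)")
        if any(b < 0 for b in bs):
            raise ValueError("b(c) must be non-negative")
        if any(b2 < b1 for b1, b2 in zip(bs, bs[1:])):
            raise ValueError("b(c) must be non-decreasing in c")
        if not 0.0 < self.adaptation_factor <= 1.0:
            raise ValueError("adaptation_factor must be in (0, 1]")

    def amplitude(self, contrast: float) -> float:
        """Interpolated input amplitude b(c)."""
        return interpolate_transfer(self, contrast)

    def adaptation(self, am_frequency: float) -> float:
        """Low-frequency adaptation factor a(f) (1 above the cutoff)."""
        return self.adaptation_factor if am_frequency <= self.adaptation_cutoff else 1.0

    def with_points(self, points: Sequence[tuple[float, float]]) -> "PUnitTransfer":
        return replace(self, calibration_points=tuple(points))


def interpolate_transfer(transfer: PUnitTransfer, contrast: float) -> float:
    """Linear interpolation of b(c), clamped beyond the last calibration point.

    Clamping (rather than linear extension) above the calibrated range models
    the saturated P-unit regime.
    """
    if contrast < 0:
        raise ValueError(f"contrast must be >= 0, got {contrast}")
    cs = np.array([c for c, _ in transfer.calibration_points])
    bs = np.array([b for _, b in transfer.calibration_points])
    # np.interp clamps on both ends; the left end is the (0, 0) anchor.
    return float(np.interp(contrast, cs, bs))


def am_drive(
    spec: StimulusSpec, transfer: PUnitTransfer, t: "np.ndarray | float"
) -> "np.ndarray | float":
    """P-unit population output S(t) = a(f) * b(c) * sin(2*pi*f*t + phi0).

    Deterministic and periodic with period 1/f; zero for zero contrast.
    """
    amp = transfer.adaptation(spec.am_frequency) * transfer.amplitude(spec.contrast)
    return amp * np.sin(2.0 * math.pi * spec.am_frequency * np.asarray(t) + spec.phase_origin)


def calibrate_transfer(
    target_max_rates: Sequence[tuple[float, float]],
    max_rate_fn: Callable[[float], float],
    *,
    f_ref: float = 8.0,
    amplitude_hi: float = 2.0,
    tol: float = 1e-3,
    max_iter: int = 40,
    adaptation_factor: float = 0.9,
    adaptation_cutoff: float = 2.0,
) -> PUnitTransfer:
    """Recover b(c) from target peak cycle-histogram rates.

    For each (contrast, target peak rate) pair, finds by bracketing + bisection
    the input amplitude at which the feedback-free model neuron's maximum
    cycle-histogram firing rate equals the target.  ``max_rate_fn`` maps an
    input amplitude to the neuron's peak cycle rate at ``f_ref`` (it should
    average over enough cycles, with a fixed seed, that its Monte-Carlo error
    is below the rate resolution of the targets).

    Raises
    ------
    CalibrationError
        If a target lies outside the achievable [rate(0), rate(amplitude_hi)]
        range of the (monotone) amplitude -> peak-rate curve.
    """
    if len(target_max_rates) < 1:
        raise CalibrationError("empty calibration table")
    r_lo = max_rate_fn(0.0)
    r_hi = max_rate_fn(amplitude_hi)
    points: list[tuple[float, float]] = [(0.0, 0.0)]
    for contrast, target in sorted(target_max_rates):
        if contrast == 0.0:
            continue
        if target <= r_lo + 1e-9:
            # target at (or below) the spontaneous peak rate: zero amplitude
            points.append((contrast, 0.0))
            continue
        if target > r_hi:
            raise CalibrationError(
                f"target rate {target:.1f} Hz at contrast {contrast}% exceeds the "
                f"achievable range [{r_lo:.1f}, {r_hi:.1f}] Hz"
            )
        lo, hi = 0.0, amplitude_hi
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            if max_rate_fn(mid) < target:
                lo = mid
            else:
                hi = mid
            if hi - lo < tol:
                break
        points.append((contrast, 0.5 * (lo + hi)))
    return PUnitTransfer(
        calibration_points=tuple(points),
        adaptation_factor=adaptation_factor,
        adaptation_cutoff=adaptation_cutoff,
    )


# Default transfer, calibrated against the synthetic reference targets at
# contrasts {5, 10, 15, 20} % (see ellcancel.reference); values regenerable via
# ``ellcancel calibrate``.  The marginal gain db/dc decreases with c: the
# P-unit population saturates at high contrast.
DEFAULT_TRANSFER = PUnitTransfer(
    calibration_points=(
        (0.0, 0.0),
        (5.0, 0.195),
        (10.0, 0.312),
        (15.0, 0.415),
        (20.0, 0.472),
    )
)
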