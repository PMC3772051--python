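"""Response quantification: PSTHs, amplitude fits, cancellation and error.

The SP response to a periodic AM is summarised by its cycle (phase) histogram.
Global responses are near-sinusoidal and are fitted with a sine plus baseline;
local responses are rectified (the cell is silent over part of the cycle), so
they are fitted with a circular Gaussian bump plus baseline instead.  The
cancellation of the global signal and its degradation across contrast are

    C(f, c) = 1 - A_global(f, c) / A_local(f, c)
    D(c)    = 1 - (1 / N_f) * sum_f C(f, c)

C = 1 is perfect cancellation; values below zero (over-cancellation: the
global response is modulated in anti-phase with the stimulus) are reported
unclipped.  Model/reference degradation curves are compared with a summed
squared-difference error over the contrast grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "PSTH",
    "compute_psth",
    "fit_global_amplitude",
    "fit_global_sine",
    "fit_local_amplitude",
    "cancellation",
    "degradation",
    "error_function",
]


@dataclass(frozen=True)
class PSTH:
    """Cycle histogram: firing rate vs stimulus phase.

    ``phase_bins`` are uniform bin centers on [0, 2*pi); ``rates`` in
    spikes/s.  The total spike count is conserved:
    sum(rates) * bin_duration * n_cycles == n_spikes.
    """

    phase_bins: np.ndarray
    rates: np.ndarray
    n_cycles: int
    period: float

    def __post_init__(self) -> None:
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.phase_bins)

    @property
    def bin_duration(self) -> float:
        return self.period / self.n_bins

    @property
    def baseline(self) -> float:
        """Mean rate over the cycle (spikes/s)."""
        return float(np.mean(self.rates))

    @property
    def n_spikes(self) -> int:
        return int(round(np.sum(self.rates) * self.bin_duration * self.n_cycles))


def compute_psth(
    spikes: np.ndarray, f: float, n_bins: int = 32, *, duration: float | None = None
) -> PSTH:
    """Fold a spike train modulo the stimulus period into a phase histogram.

    Only whole cycles are used: spikes beyond the last complete cycle are
    dropped so the rate normalisation (count / (n_cycles * bin_duration)) is
    exact.
    """
    if n_bins < 4:
        raise ValueError("need at least 4 phase bins")
    spikes = np.asarray(spikes, dtype=float)
    period = 1.0 / f
    if duration is None:
        duration = float(spikes[-1]) if len(spikes) else 0.0
    n_cycles = int(duration / period)
    if n_cycles < 1:
        raise ValueError("recording must span at least one full stimulus cycle")
    spikes = spikes[spikes < n_cycles * period]
    phases = (spikes % period) / period  # in [0, 1)
    counts, _ = np.histogram(phases, bins=n_bins, range=(0.0, 1.0))
    bin_duration = period / n_bins
    rates = counts / (n_cycles * bin_duration)
    centers = (np.arange(n_bins) + 0.5) * (2.0 * math.pi / n_bins)
    return PSTH(phase_bins=centers, rates=rates, n_cycles=n_cycles, period=period)


def fit_global_sine(psth: PSTH) -> tuple[float, float, float]:
    """Least-squares sine fit r(phi) = b0 + A*sin(phi + phi0).

    Linear in (b0, a, b) with A*sin(phi + phi0) = a*sin(phi) + b*cos(phi);
    returns (A, phi0, b0) with A >= 0.  A flat histogram gives A = 0.
    """
    phi = psth.phase_bins
    design = np.column_stack([np.ones_like(phi), np.sin(phi), np.cos(phi)])
    coef, *_ = np.linalg.lstsq(design, psth.rates, rcond=None)
    b0, a, b = coef
    amplitude = math.hypot(a, b)
    phase = math.atan2(b, a)
    return amplitude, phase, float(b0)


def fit_global_amplitude(psth: PSTH) -> float:
    """Sine-fit amplitude |A| of a (global-stimulation) PSTH."""
    return fit_global_sine(psth)[0]


def _circular_gaussian(phi, b0, height, center, width):
    d = np.angle(np.exp(1j * (phi - center)))  # wrapped to (-pi, pi]
    return b0 + height * np.exp(-(d**2) / (2.0 * width**2))


def fit_local_amplitude(psth: PSTH, *, full_output: bool = False):
    """Gaussian-bump fit of a rectified (local-stimulation) PSTH.

    Fits r(phi) = b0 + H*exp(-d(phi, phi_c)^2 / (2*w^2)) with circular phase
    distance d, initialised at the argmax bin; returns the height H.  A flat
    histogram returns H = 0.
    """
    phi = psth.phase_bins
    r = psth.rates
    spread = float(np.max(r) - np.min(r))
    if spread <= 1e-12:
        return (0.0, None) if full_output else 0.0
    i0 = int(np.argmax(r))
    p0 = [float(np.min(r)), spread, float(phi[i0]), 1.0]
    bounds = ([0.0, 0.0, -math.pi, 0.05], [np.inf, np.inf, 3 * math.pi, math.pi])
    try:
        popt, _ = curve_fit(_circular_gaussian, phi, r, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError:
        # retry from a wider initial bump before giving up
        p0[3] = 2.0
        popt, _ = curve_fit(_circular_gaussian, phi, r, p0=p0, bounds=bounds, maxfev=20000)
    height = float(popt[1])
    return (height, popt) if full_output else height


def cancellation(a_local: float, a_global: float) -> float:
    """C = 1 - A_global / A_local; 1 is perfect, negative is over-cancellation."""
    if a_local <= 0:
        raise ValueError("A_local must be positive")
    return 1.0 - a_global / a_local


def degradation(c_by_frequency: Mapping[float, float]) -> float:
    """D = 1 - mean over AM frequencies of C(f)."""
    if not c_by_frequency:
        raise ValueError("need at least one frequency")
    return 1.0 - float(np.mean(list(c_by_frequency.values())))


def error_function(
    model_d: Mapping[float, float], reference_d: Mapping[float, float]
) -> float:
    """Summed squared difference between model and reference degradation curves.

    Both maps must be defined on the same contrast grid.
    """
    if set(model_d) != set(reference_d):
        raise ValueError("model and reference contrast grids differ")
    return float(sum((model_d[c] - reference_d[c]) ** 2 for c in model_d))
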