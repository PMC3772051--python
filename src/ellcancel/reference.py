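"""Synthetic reference dataset: surrogate in-vivo observables.

The analysis is calibrated against summary statistics of extracellular SP-cell
recordings: per-(frequency, contrast) local and global cycle histograms, the
peak local firing rate per contrast (used to calibrate the P-unit transfer
b(c)), the mean firing rate under global stimulation (used to calibrate the
feedback gain G0), and the degradation-vs-contrast curve (the anchor of the
learning-contrast error scans).  Those numbers are not shipped with this
package; this module synthesises a dataset with the same statistical
structure so every calibration and scan can run self-contained:

* local responses are rectified - a Gaussian-bump-like cycle histogram whose
  peak rate grows with contrast but saturates (concave), reflecting the
  quasi-linear-then-saturating P-unit encoder;
* global responses are near-flat, with a small residual sinusoidal modulation
  set by the degradation curve;
* the degradation curve D(c) rises gently with contrast within a narrow band.

All levels are configuration; the defaults are chosen to respect those
structural constraints and are the values the package's shipped calibrations
(``DEFAULT_TRANSFER``, ``DEFAULT_GAIN``) were derived from.  The dataset is
not a fit to any real recording.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ReferenceConfig",
    "ReferenceDataset",
    "generate_reference",
    "end_to_end_selfcheck",
]

#: Reference condition for rate calibrations (AM frequency Hz, contrast %).
F_REF, C_REF = 8.0, 10.0


@dataclass(frozen=True)
class ReferenceConfig:
    """Levels of the surrogate observables (rates in spikes/s)."""

    frequencies: tuple[float, ...] = (2.0, 4.0, 8.0, 16.0)
    contrasts: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0)
    #: peak local cycle-histogram rate per contrast; concave in c (saturation)
    local_peak_rates: tuple[tuple[float, float], ...] = (
        (5.0, 150.0), (10.0, 240.0), (15.0, 300.0), (20.0, 340.0),
    )
    #: spontaneous (no-AM) rate, also the local-response baseline
    baseline_rate: float = 30.0
    #: mean rate under global stimulation at (F_REF, C_REF), pre-learning
    #: (uniform-weight) convention - the G0 calibration target
    global_mean_rate: float = 188.0
    #: degradation-vs-contrast curve: gently rising, confined to a narrow band
    degradation_curve: tuple[tuple[float, float], ...] = (
        (5.0, 0.05), (10.0, 0.065), (15.0, 0.08), (20.0, 0.095),
    )
    #: per-bin Gaussian rate jitter (spikes/s) on the synthetic histograms
    noise_sd: float = 5.0
    n_bins: int = 32

    def __post_init__(self) -> None:
        if not self.frequencies or not self.contrasts:
            raise ValueError("frequency and contrast grids must be non-empty")
        rates = [r for _, r in sorted(self.local_peak_rates)]
        if any(r2 <= r1 for r1, r2 in zip(rates, rates[1:])):
            raise ValueError("local peak rates must increase with contrast")
        d2 = np.diff(rates, 2)
        if np.any(d2 > 1e-9):
            raise ValueError("local peak rates must be concave in contrast")
        ds = [d for _, d in sorted(self.degradation_curve)]
        if any(d2_ < d1_ for d1_, d2_ in zip(ds, ds[1:])):
            raise ValueError("degradation curve must be non-decreasing")


@dataclass
class ReferenceDataset:
    """Surrogate experimental observables (deterministic under ``seed``)."""

    frequencies: tuple[float, ...]
    contrasts: tuple[float, ...]
    local_max_rates: dict        # (f, c) -> peak cycle rate, spikes/s
    global_amplitudes: dict      # (f, c) -> residual sine amplitude, spikes/s
    degradation_curve: dict      # c -> D
    local_psths: dict            # (f, c) -> rates per phase bin
    global_psths: dict           # (f, c) -> rates per phase bin
    global_mean_rate: float
    baseline_rate: float
    noise_sd: float
    seed: int

    def degradation_on(self, contrasts) -> dict:
        return {c: self.degradation_curve[c] for c in contrasts}

    def to_dir(self, path: str | Path) -> None:
        """Write the dataset as tidy CSVs plus a JSON manifest."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        rows = [
            (f, c, self.local_max_rates[(f, c)], self.global_amplitudes[(f, c)])
            for f in self.frequencies for c in self.contrasts
        ]
        pd.DataFrame(
            rows, columns=["frequency_hz", "contrast_pct", "local_max_rate", "global_amplitude"]
        ).to_csv(path / "rates.csv", index=False)
        pd.DataFrame(
            sorted(self.degradation_curve.items()), columns=["contrast_pct", "degradation"]
        ).to_csv(path / "degradation.csv", index=False)
        psth_rows = []
        for kind, table in (("local", self.local_psths), ("global", self.global_psths)):
            for (f, c), rates in table.items():
                for i, r in enumerate(rates):
                    psth_rows.append((kind, f, c, i, r))
        pd.DataFrame(
            psth_rows, columns=["kind", "frequency_hz", "contrast_pct", "bin", "rate"]
        ).to_csv(path / "psths.csv", index=False)
        manifest = {
            "frequencies": list(self.frequencies),
            "contrasts": list(self.contrasts),
            "global_mean_rate": self.global_mean_rate,
            "baseline_rate": self.baseline_rate,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _local_profile(phases: np.ndarray, baseline: float, peak: float) -> np.ndarray:
    """Rectified-sinusoid-like local cycle histogram (peak at phase pi/2)."""
    shape = np.maximum(np.sin(phases), 0.0) ** 1.5  # sharpened by rectification
    return baseline + (peak - baseline) * shape


def generate_reference(
    config: ReferenceConfig | None = None, seed: int = 0
) -> ReferenceDataset:
    """Synthesise the surrogate dataset; jitter SD = 0 reproduces the means."""
    config = config or ReferenceConfig()
    rng = np.random.default_rng(seed)
    peak_by_c = dict(config.local_peak_rates)
    missing = [c for c in config.contrasts if c not in peak_by_c]
    if missing:
        raise ValueError(f"no local peak rate configured for contrasts {missing}")
    d_curve = dict(config.degradation_curve)
    if any(c not in d_curve for c in config.contrasts):
        raise ValueError("degradation curve must cover the contrast grid")
    phases = (np.arange(config.n_bins) + 0.5) * 2.0 * math.pi / config.n_bins
    local_max, global_amp, local_psths, global_psths = {}, {}, {}, {}
    for f in config.frequencies:
        for c in config.contrasts:
            peak = peak_by_c[c]
            lp = _local_profile(phases, config.baseline_rate, peak)
            lp = np.maximum(lp + rng.normal(0.0, config.noise_sd, lp.shape), 0.0)
            local_psths[(f, c)] = lp
            local_max[(f, c)] = float(peak)
            amp = d_curve[c] * (peak - config.baseline_rate)
            gp = config.baseline_rate + amp * np.sin(phases)
            gp = np.maximum(gp + rng.normal(0.0, config.noise_sd, gp.shape), 0.0)
            global_psths[(f, c)] = gp
            global_amp[(f, c)] = float(amp)
    return ReferenceDataset(
        frequencies=config.frequencies,
        contrasts=config.contrasts,
        local_max_rates=local_max,
        global_amplitudes=global_amp,
        degradation_curve={c: float(d_curve[c]) for c in config.contrasts},
        local_psths=local_psths,
        global_psths=global_psths,
        global_mean_rate=config.global_mean_rate,
        baseline_rate=config.baseline_rate,
        noise_sd=config.noise_sd,
        seed=seed,
    )


def end_to_end_selfcheck(
    reference: ReferenceDataset | None = None,
    *,
    seed: int = 0,
    learning_contrast: float = 15.0,
    frequencies: tuple[float, ...] = (4.0, 8.0),
    time_scale: float = 10.0,
    dt: float = 2.5e-5,
    calibration_duration: float = 60.0,
    config_overrides: Mapping | None = None,
) -> dict:
    """Calibrate, train and evaluate the full pipeline against the reference.

    Runs the whole analysis end to end: b(c) calibration against the
    reference's local peak rates, G0 calibration against its global mean
    rate, PF-weight equilibration at ``learning_contrast``, the cancellation
    table over (frequency, contrast), the degradation curve and its summed
    squared error against the reference curve.  Returns a machine-readable
    report.
    """
    from . import experiments  # deferred: experiments imports this module

    if reference is None:
        reference = generate_reference(seed=seed)
    transfer = experiments.calibrate_transfer_to_reference(
        reference, seed=seed, dt=dt, duration=calibration_duration
    )
    gain = experiments.calibrate_gain_to_reference(
        reference, transfer, seed=seed, dt=dt, duration=calibration_duration
    )
    cfg = experiments.ExperimentConfig(
        frequencies=frequencies,
        contrasts=tuple(reference.contrasts),
        learning_contrast=learning_contrast,
        time_scale=time_scale,
        dt=dt,
        seed=seed,
        **dict(config_overrides or {}),
    )
    table, deg = experiments.run_cancellation_experiment(
        cfg, transfer=transfer, gain=gain
    )
    err = sum(
        (deg[c] - reference.degradation_curve[c]) ** 2 for c in reference.contrasts
    )
    report = {
        "transfer": list(map(list, transfer.calibration_points)),
        "g0": gain.G0,
        "learning_contrast": learning_contrast,
        "cancellation": {
            f"{f:g}_{c:g}": float(
                table.loc[(table.frequency_hz == f) & (table.contrast_pct == c), "C"].iloc[0]
            )
            for f in frequencies for c in reference.contrasts
        },
        "degradation": {f"{c:g}": float(deg[c]) for c in reference.contrasts},
        "reference_degradation": {
            f"{c:g}": float(reference.degradation_curve[c]) for c in reference.contrasts
        },
        "error": float(err),
        "seed": seed,
    }
    return report
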