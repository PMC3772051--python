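"""Reproducible in-silico experiments over the full model.

Pipelines mirroring the study design: P-unit and feedback-gain calibration
against the (synthetic) reference observables, local-response fitting,
PF-weight equilibration at a learning contrast followed by testing across the
whole (frequency x contrast) grid with the *same* trained weights (plasticity
is slow: the fish cannot relearn per stimulus), and the two parameter scans -
error versus learning contrast, and its minimum versus the potentiation time
constant tau_w.

Desk-scale convention.  Full-scale equilibration takes ~3 * tau_w = ~50
simulated minutes per channel; experiments default to a joint rescaling
(tau_w / kappa, eta * kappa) with kappa = ``time_scale`` = 10, which leaves
the depression/potentiation balance - and hence the equilibrium profile -
unchanged while shortening the transient.  Set ``time_scale = 1`` for
full-scale runs.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .feedback import (
    DEFAULT_GAIN,
    FeedbackGain,
    PFArray,
    build_segments,
    feedback_gain,
    feedback_shunt,
)
from .metrics import (
    cancellation,
    compute_psth,
    degradation,
    error_function,
    fit_global_sine,
    fit_local_amplitude,
)
from .neuron import simulate
from .plasticity import PlasticityParams, TrainingResult, train_to_equilibrium
from .reference import C_REF, F_REF, ReferenceDataset, generate_reference
from .stimulus import (
    DEFAULT_TRANSFER,
    CalibrationError,
    PUnitTransfer,
    StimulusSpec,
    calibrate_transfer,
)

__all__ = [
    "ExperimentConfig",
    "calibrate_transfer_to_reference",
    "calibrate_gain_to_reference",
    "run_local_experiment",
    "train_channel",
    "run_cancellation_experiment",
    "scan_learning_contrast",
    "scan_tau_w",
]

logger = logging.getLogger(__name__)


def _child_seed(seed: int, *keys) -> int:
    """Deterministic sub-seed from a base seed and a tag tuple (< 2^31)."""
    tag = "/".join(str(k) for k in keys).encode()
    return (int(seed) * 2654435761 + zlib.crc32(tag)) % (2**31 - 1)


@dataclass(frozen=True)
class ExperimentConfig:
    """One reproducible experiment specification."""

    frequencies: tuple[float, ...] = (2.0, 4.0, 8.0, 16.0)
    contrasts: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0)
    learning_contrast: float = 15.0
    saturation_enabled: bool = True
    tau_w: float | None = None          # override of the 980 s default
    time_scale: float = 10.0            # joint (tau_w, eta) rescaling kappa
    segment_duration: float = 2e-3
    dt: float = 2.5e-5
    seed: int = 0
    epoch_cycles: int = 16
    max_epochs: int = 300
    test_duration: float = 80.0         # s per test simulation
    n_test_seeds: int = 2
    outdir: str | None = None

    def plasticity(self) -> PlasticityParams:
        base = PlasticityParams()
        if self.tau_w is not None:
            base = replace(base, tau_w=self.tau_w)
        return base.scaled(self.time_scale)

    def gain(self) -> FeedbackGain:
        g = DEFAULT_GAIN
        return g if self.saturation_enabled else g.without_saturation()


# ---------------------------------------------------------------------------
# Calibrations against the reference dataset
# ---------------------------------------------------------------------------

def calibrate_transfer_to_reference(
    reference: ReferenceDataset,
    *,
    seed: int = 0,
    dt: float = 2.5e-5,
    duration: float = 60.0,
) -> PUnitTransfer:
    """Recover b(c) from the reference's local peak cycle rates at F_REF."""
    sim_seed = _child_seed(seed, "calibrate-b")

    def max_rate_fn(amp: float) -> float:
        sp = simulate(
            StimulusSpec(F_REF, C_REF, duration, "local"), None,
            amplitude=amp, dt=dt, seed=sim_seed,
        )
        if len(sp) < 5:
            return 0.0
        return float(compute_psth(sp, F_REF, 32, duration=duration).rates.max())

    targets = [
        (c, reference.local_max_rates[(F_REF, c)])
        for c in reference.contrasts
        if (F_REF, c) in reference.local_max_rates
    ]
    if not targets:
        raise CalibrationError("reference has no local peak rates at the reference frequency")
    return calibrate_transfer(targets, max_rate_fn, f_ref=F_REF)


def calibrate_gain_to_reference(
    reference: ReferenceDataset,
    transfer: PUnitTransfer,
    *,
    seed: int = 0,
    dt: float = 2.5e-5,
    duration: float = 60.0,
    g0_hi: float = 10.0,
    tol: float = 5e-3,
) -> FeedbackGain:
    """Bisect G0 to match the reference mean rate under global stimulation.

    Uses the pre-learning convention: uniform w = w_max weights at
    (F_REF, C_REF).  The uniform-weight mean rate is monotone increasing in
    G0 (net feedback excitation grows with the gain).
    """
    pf = build_segments(F_REF, 2e-3)
    sim_seed = _child_seed(seed, "calibrate-g0")
    target = reference.global_mean_rate

    def mean_rate(g0: float) -> float:
        gain = replace(DEFAULT_GAIN, G0=g0)
        G = feedback_gain(C_REF, transfer, gain, "global", F_REF)
        sh = feedback_shunt(C_REF, transfer, gain, "global", F_REF)
        sp = simulate(
            StimulusSpec(F_REF, C_REF, duration, "global"), transfer, pf,
            feedback_gain=G, feedback_shunt=sh, dt=dt, seed=sim_seed,
        )
        return len(sp) / duration

    lo, hi = 0.0, g0_hi
    r_lo, r_hi = mean_rate(lo), mean_rate(hi)
    if not r_lo <= target <= r_hi:
        raise CalibrationError(
            f"global mean-rate target {target:.1f} Hz outside achievable "
            f"range [{r_lo:.1f}, {r_hi:.1f}] Hz"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if mean_rate(mid) < target:
            lo = mid
        else:
            hi = mid
    return replace(DEFAULT_GAIN, G0=round(0.5 * (lo + hi), 4))


# ---------------------------------------------------------------------------
# Local responses
# ---------------------------------------------------------------------------

def run_local_experiment(
    config: ExperimentConfig,
    transfer: PUnitTransfer | None = None,
) -> pd.DataFrame:
    """Simulate and fit local responses over the grid.

    Returns a tidy frame (frequency_hz, contrast_pct, a_local, peak_rate,
    mean_rate); writes ``local_responses.csv`` when an output directory is
    configured.
    """
    transfer = transfer or DEFAULT_TRANSFER
    rows = []
    for f in config.frequencies:
        for c in config.contrasts:
            sp = simulate(
                StimulusSpec(f, c, config.test_duration, "local"), transfer,
                dt=config.dt, seed=_child_seed(config.seed, "local", f, c),
            )
            psth = compute_psth(sp, f, 32, duration=config.test_duration)
            a_local = fit_local_amplitude(psth) if c > 0 else 0.0
            rows.append((f, c, a_local, float(psth.rates.max()), float(psth.baseline)))
    frame = pd.DataFrame(
        rows, columns=["frequency_hz", "contrast_pct", "a_local", "peak_rate", "mean_rate"]
    )
    _maybe_write(config, frame, "local_responses.csv")
    return frame


# ---------------------------------------------------------------------------
# Training + cancellation across the grid
# ---------------------------------------------------------------------------

def train_channel(
    config: ExperimentConfig,
    f: float,
    learning_contrast: float | None = None,
    *,
    transfer: PUnitTransfer | None = None,
    gain: FeedbackGain | None = None,
    plasticity: PlasticityParams | None = None,
    seed_tag: str = "train",
) -> TrainingResult:
    """Equilibrate the PF weights of one frequency channel."""
    transfer = transfer or DEFAULT_TRANSFER
    gain = gain or config.gain()
    lc = config.learning_contrast if learning_contrast is None else learning_contrast
    plasticity = plasticity or config.plasticity()
    G = feedback_gain(lc, transfer, gain, "global", f)
    sh = feedback_shunt(lc, transfer, gain, "global", f)
    return train_to_equilibrium(
        StimulusSpec(f, lc, 1.0, "global"), transfer, G,
        feedback_shunt=sh,
        plasticity=plasticity,
        segment_duration=config.segment_duration,
        dt=config.dt,
        seed=_child_seed(config.seed, seed_tag, f, lc),
        epoch_cycles=config.epoch_cycles,
        max_epochs=config.max_epochs,
    )


def _test_global_amplitude(
    config: ExperimentConfig,
    pf: PFArray,
    f: float,
    c: float,
    transfer: PUnitTransfer,
    gain: FeedbackGain,
    seed_tag: str = "test",
) -> tuple[float, float, float]:
    """Seed-averaged sine fit of the global response: (A, phase, mean rate)."""
    G = feedback_gain(c, transfer, gain, "global", f)
    sh = feedback_shunt(c, transfer, gain, "global", f)
    amps, phases, rates = [], [], []
    for k in range(config.n_test_seeds):
        sp = simulate(
            StimulusSpec(f, c, config.test_duration, "global"), transfer, pf,
            feedback_gain=G, feedback_shunt=sh, dt=config.dt,
            seed=_child_seed(config.seed, seed_tag, f, c, k),
        )
        a, ph, b0 = fit_global_sine(
            compute_psth(sp, f, 32, duration=config.test_duration)
        )
        amps.append(a)
        phases.append(ph)
        rates.append(len(sp) / config.test_duration)
    # average the fitted sine as a vector so noisy phases do not inflate A
    z = np.mean([a * np.exp(1j * p) for a, p in zip(amps, phases)])
    return float(np.abs(z)), float(np.angle(z)), float(np.mean(rates))


def run_cancellation_experiment(
    config: ExperimentConfig,
    *,
    transfer: PUnitTransfer | None = None,
    gain: FeedbackGain | None = None,
    trained: dict | None = None,
    local: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Cancellation table over the grid with one set of trained weights.

    Trains each frequency channel at ``config.learning_contrast`` (unless
    pre-trained channels are supplied) and tests every contrast with those
    same equilibrated weights.  Returns the tidy cancellation table
    (frequency_hz, contrast_pct, a_local, a_global, C, global_mean_rate) and
    the per-contrast degradation curve D(c) = 1 - mean_f C(f, c).
    """
    transfer = transfer or DEFAULT_TRANSFER
    gain = gain or config.gain()
    if local is None:
        local = run_local_experiment(config, transfer)
    a_local = {
        (r.frequency_hz, r.contrast_pct): r.a_local for r in local.itertuples()
    }
    rows = []
    c_table: dict[float, dict[float, float]] = {f: {} for f in config.frequencies}
    for f in config.frequencies:
        if trained is not None and f in trained:
            pf = trained[f].pf
        else:
            pf = train_channel(config, f, transfer=transfer, gain=gain).pf
        for c in config.contrasts:
            a_g, _, rate = _test_global_amplitude(config, pf, f, c, transfer, gain)
            C = cancellation(a_local[(f, c)], a_g)
            c_table[f][c] = C
            rows.append((f, c, a_local[(f, c)], a_g, C, rate))
    table = pd.DataFrame(
        rows,
        columns=["frequency_hz", "contrast_pct", "a_local", "a_global", "C", "global_mean_rate"],
    )
    deg = {c: degradation({f: c_table[f][c] for f in config.frequencies}) for c in config.contrasts}
    _maybe_write(config, table, "cancellation.csv")
    _maybe_write(
        config,
        pd.DataFrame(sorted(deg.items()), columns=["contrast_pct", "degradation"]),
        "degradation.csv",
    )
    return table, deg


# ---------------------------------------------------------------------------
# Scans
# ---------------------------------------------------------------------------

def classify_residual(
    config: ExperimentConfig,
    pf: PFArray,
    f: float,
    c: float,
    transfer: PUnitTransfer,
    gain: FeedbackGain,
) -> float:
    """Signed residual modulation of the global response at (f, c), spikes/s.

    Positive values are in phase with the feedback-free response
    (under-cancellation), negative values anti-phase (over-cancellation).
    The phase reference is the sine fit of a feedback-free simulation at the
    same (f, c).
    """
    sp = simulate(
        StimulusSpec(f, c, config.test_duration, "local"), transfer,
        dt=config.dt, seed=_child_seed(config.seed, "phase-ref", f, c),
    )
    _, ref_phase, _ = fit_global_sine(
        compute_psth(sp, f, 32, duration=config.test_duration)
    )
    a, phase, _ = _test_global_amplitude(config, pf, f, c, transfer, gain, seed_tag="resid")
    return float(a * np.cos(phase - ref_phase))


def scan_learning_contrast(
    config: ExperimentConfig,
    learning_contrasts=(5.0, 10.0, 15.0, 20.0, 25.0),
    reference_degradation: dict | None = None,
    *,
    transfer: PUnitTransfer | None = None,
    gain: FeedbackGain | None = None,
    residual_contrasts: tuple[float, float] = (5.0, 20.0),
) -> tuple[pd.DataFrame, float]:
    """Error versus learning contrast; returns (curve, optimal contrast).

    For each learning contrast the PF weights are equilibrated per frequency
    channel and the whole grid is tested with those weights; the summed
    squared distance between the model's degradation curve and the reference
    curve is the scan objective.  Signed residuals at the lowest/highest test
    contrasts (over-/under-cancellation diagnostics) are reported alongside.
    """
    transfer = transfer or DEFAULT_TRANSFER
    gain = gain or config.gain()
    if reference_degradation is None:
        reference_degradation = generate_reference(seed=config.seed).degradation_on(
            config.contrasts
        )
    local = run_local_experiment(config, transfer)
    rows = []
    for lc in learning_contrasts:
        cfg_lc = replace(config, learning_contrast=lc)
        trained = {
            f: train_channel(cfg_lc, f, transfer=transfer, gain=gain)
            for f in config.frequencies
        }
        _, deg = run_cancellation_experiment(
            cfg_lc, transfer=transfer, gain=gain, trained=trained, local=local
        )
        err = error_function(deg, reference_degradation)
        resid = {
            c: float(
                np.mean([
                    classify_residual(cfg_lc, trained[f].pf, f, c, transfer, gain)
                    for f in config.frequencies
                ])
            )
            for c in residual_contrasts
        }
        converged = all(t.converged for t in trained.values())
        rows.append(
            (lc, err, resid[residual_contrasts[0]], resid[residual_contrasts[1]], converged)
        )
        logger.info("learning contrast %.0f%%: error %.5f", lc, err)
    curve = pd.DataFrame(
        rows,
        columns=["learning_contrast", "error", "residual_low", "residual_high", "converged"],
    )
    _maybe_write(config, curve, "learning_contrast_scan.csv")
    best = float(curve.loc[curve.error.idxmin(), "learning_contrast"])
    return curve, best


def scan_tau_w(
    config: ExperimentConfig,
    tau_grid=(98.0, 245.0, 490.0, 980.0, 1960.0),
    learning_contrasts=(5.0, 10.0, 15.0, 20.0, 25.0),
    reference_degradation: dict | None = None,
    *,
    transfer: PUnitTransfer | None = None,
    gain: FeedbackGain | None = None,
) -> tuple[pd.DataFrame, float]:
    """Minimum scan error versus the potentiation time constant.

    Repeats the learning-contrast scan for each tau_w (the eta/tau_w joint
    rescaling keeps every other parameter fixed) and reports the minimum
    error per tau_w and its overall arg-min.
    """
    if reference_degradation is None:
        reference_degradation = generate_reference(seed=config.seed).degradation_on(
            config.contrasts
        )
    rows = []
    for tau in tau_grid:
        cfg_tau = replace(config, tau_w=tau)
        curve, best_lc = scan_learning_contrast(
            cfg_tau, learning_contrasts, reference_degradation,
            transfer=transfer, gain=gain,
        )
        rows.append((tau, float(curve.error.min()), best_lc))
    frame = pd.DataFrame(rows, columns=["tau_w", "min_error", "best_learning_contrast"])
    _maybe_write(config, frame, "tau_w_scan.csv")
    best_tau = float(frame.loc[frame.min_error.idxmin(), "tau_w"])
    return frame, best_tau


def _maybe_write(config: ExperimentConfig, frame: pd.DataFrame, name: str) -> None:
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out / name, index=False)
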