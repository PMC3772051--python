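import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.signal import welch

from ellcancel import (
    DAPParams,
    NeuronParams,
    NeuronState,
    StimulusSpec,
    dap_step,
    dap_waveform,
    filtered_noise,
    lif_period,
    register_spike,
    simulate,
)
from ellcancel.neuron import DEFAULT_DT

from conftest import FAST_DT


class TestFilteredNoise:
    def test_unit_variance_zero_mean(self):
        # Monte-Carlo oracle at 10^6 steps
        xi = filtered_noise(NeuronParams(), DEFAULT_DT, 1_000_000, seed=5)
        # effective sample size reduced by the AR(1) correlation time
        n_eff = len(xi) * (2 * math.pi * 500.0 * DEFAULT_DT)
        assert abs(xi.mean()) < 3.0 / math.sqrt(n_eff)
        assert abs(xi.var() - 1.0) < 3.0 * math.sqrt(2.0 / n_eff)

    def test_spectrum_attenuated_above_cutoff(self):
        params = NeuronParams()
        xi = filtered_noise(params, DEFAULT_DT, 400_000, seed=7)
        f, p = welch(xi, fs=1.0 / DEFAULT_DT, nperseg=8192)
        below = p[(f > 50) & (f < params.f_cut / 2)].mean()
        above = p[(f > 4 * params.f_cut) & (f < 10 * params.f_cut)].mean()
        assert above < below / 3

    def test_dt_too_large_for_cutoff_rejected(self):
        with pytest.raises(ValueError):
            filtered_noise(NeuronParams(), dt=2e-3, n_steps=10, seed=0)

    def test_reproducible_under_seed(self):
        a = filtered_noise(NeuronParams(), DEFAULT_DT, 1000, seed=3)
        b = filtered_noise(NeuronParams(), DEFAULT_DT, 1000, seed=3)
        np.testing.assert_array_equal(a, b)


class TestDAP:
    def test_no_spike_means_no_current(self):
        state = NeuronState()
        params = DAPParams()
        for _ in range(100):
            dap_step(state, params, 1e-4)
        assert state.dap_current(params) == 0.0

    def test_single_spike_waveform_nonnegative_unimodal_transient(self):
        params = DAPParams()
        x = np.linspace(0, 0.05, 2001)
        b = dap_waveform(params, x)
        assert np.all(b >= 0)
        peak = int(np.argmax(b))
        # unimodal: non-decreasing to the peak, non-increasing after
        assert np.all(np.diff(b[: peak + 1]) >= -1e-12)
        assert np.all(np.diff(b[peak:]) <= 1e-12)
        assert b[-1] < 1e-3 * b.max()

    @pytest.mark.parametrize("step", [1e-5, 1e-6])
    def test_stepped_state_matches_closed_form(self, step):
        # numeric integration oracle: finer steps converge on the waveform
        params = DAPParams()
        state = NeuronState()
        register_spike(state, params, 0.0)
        t, errs = 0.0, []
        for _ in range(int(0.02 / step)):
            t += step
            b = dap_step(state, params, step)
            errs.append(abs(b - float(dap_waveform(params, t))))
        assert max(errs) < 5e-3  # exact exponential update; error ~ O(step)

    def test_second_spike_inside_dendritic_refractory_gets_no_dap(self):
        params = DAPParams()
        state = NeuronState()
        assert register_spike(state, params, 0.0) is True
        # r jumped by mu3*(mu1 + mu2) ~ 1.8 ms; a spike 0.5 ms later is inside
        assert state.r > 0.5e-3
        assert register_spike(state, params, 0.5e-3) is False

    def test_refractory_variable_relaxes_to_baseline(self):
        params = DAPParams()
        state = NeuronState()
        register_spike(state, params, 0.0)
        for _ in range(int(0.2 / 1e-4)):
            dap_step(state, params, 1e-4)
        assert state.r == pytest.approx(params.r_s, rel=1e-3)


class TestSimulate:
    def test_subthreshold_fixed_point_no_spikes(self):
        # sigma=0, no AM, DAP off: V settles at I=0.59 < 1
        params = replace(NeuronParams(), sigma=0.0)
        spec = StimulusSpec(8.0, 0.0, 1.0)
        spikes, v = simulate(
            spec, None, amplitude=0.0, params=params, dap_enabled=False,
            record_v=True, seed=0,
        )
        assert len(spikes) == 0
        assert v[-1] == pytest.approx(0.59, abs=1e-3)

    def test_constant_drive_period_matches_closed_form(self):
        # D = 2: period = tau_m*ln2 + tau_ref = 7*ln2 + 0.7 ~ 5.552 ms
        params = replace(NeuronParams(), sigma=0.0, bias=2.0)
        spec = StimulusSpec(8.0, 0.0, 2.0)
        spikes = simulate(
            spec, None, amplitude=0.0, params=params, dap_enabled=False,
            dt=DEFAULT_DT, seed=0,
        )
        expected = lif_period(2.0)
        assert expected == pytest.approx(7e-3 * math.log(2) + 0.7e-3)
        measured = np.diff(spikes).mean()
        assert measured == pytest.approx(expected, rel=0.01)

    def test_euler_error_shrinks_with_dt(self):
        params = replace(NeuronParams(), sigma=0.0, bias=2.0)
        spec = StimulusSpec(8.0, 0.0, 2.0)
        errs = []
        for dt in (1e-4, 5e-5, 2.5e-5):
            sp = simulate(spec, None, amplitude=0.0, params=params,
                          dap_enabled=False, dt=dt, seed=0)
            errs.append(abs(np.diff(sp).mean() - lif_period(2.0)))
        assert errs[2] <= errs[0]

    def test_spike_times_strictly_increasing_min_isi_refractory(self, baseline_spikes):
        isi = np.diff(baseline_spikes)
        assert np.all(isi > 0)
        assert isi.min() >= NeuronParams().tau_ref - 1e-12

    def test_dap_increases_short_isi_fraction(self, transfer):
        spec = StimulusSpec(8.0, 0.0, 30.0)
        with_dap = simulate(spec, transfer, dt=FAST_DT, seed=21, dap_enabled=True)
        without = simulate(spec, transfer, dt=FAST_DT, seed=21, dap_enabled=False)
        frac = lambda sp: np.mean(np.diff(sp) < 10e-3) if len(sp) > 2 else 0.0
        assert frac(with_dap) > frac(without)

    def test_baseline_isi_distribution_bimodal(self, baseline_spikes):
        # burst peak at short ISIs plus a long quiescent tail
        isi = np.diff(baseline_spikes) * 1e3  # ms
        assert np.mean(isi < 10) > 0.3
        assert np.mean(isi > 30) > 0.05

    def test_rectification_clamps_negative_feedforward(self):
        # I + S < 0 contributes exactly zero: V stays at the reset level
        params = replace(NeuronParams(), sigma=0.0, bias=-5.0)
        spikes, v = simulate(
            StimulusSpec(8.0, 0.0, 0.5), None, amplitude=0.0, params=params,
            dap_enabled=False, record_v=True, seed=0,
        )
        assert len(spikes) == 0
        assert np.all(v >= -1e-12)

    def test_local_stimulus_rejects_feedback(self, transfer):
        from ellcancel import build_segments

        pf = build_segments(8.0, 2e-3)
        with pytest.raises(ValueError, match="local"):
            simulate(StimulusSpec(8.0, 5.0, 1.0, "local"), transfer, pf, feedback_gain=1.0)

    def test_reproducible_under_seed(self, transfer):
        spec = StimulusSpec(8.0, 10.0, 2.0)
        a = simulate(spec, transfer, dt=FAST_DT, seed=9)
        b = simulate(spec, transfer, dt=FAST_DT, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_invalid_dt_rejected(self, transfer):
        with pytest.raises(ValueError):
            simulate(StimulusSpec(8.0, 5.0, 1.0), transfer, dt=-1e-5)

    def test_spike_train_csv_round_trip(self, baseline_spikes, tmp_path):
        from ellcancel import save_spike_train

        path = tmp_path / "spikes.csv"
        save_spike_train(baseline_spikes, path)
        loaded = np.loadtxt(path, skiprows=1)
        np.testing.assert_allclose(loaded, baseline_spikes, atol=1e-9)
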