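import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ellcancel import (
    BurstEvent,
    PlasticityParams,
    StimulusSpec,
    apply_depression,
    apply_potentiation,
    build_segments,
    depression_kernel,
    detect_bursts,
    train_to_equilibrium,
)
from ellcancel.feedback import feedback_gain, feedback_shunt
from ellcancel import DEFAULT_GAIN, DEFAULT_TRANSFER

from conftest import FAST_DT


def greedy_oracle(times, params):
    """Independent burst assignment: lexicographically best event string.

    Enumerates, via memoized recursion over the first unconsumed spike, the
    (large > small > skip)-preferred assignment of disjoint bursts and returns
    it; the online detector must agree with this exhaustive-preference search.
    """
    times = list(times)
    n = len(times)
    size = {"large": 2, "small": 1, None: 0}

    def rank(assign):
        # events scanned left to right: earlier and larger ranks higher;
        # longer prefixes of equal events rank higher
        return tuple((-t, size[k]) for k, t in assign)

    def enumerate_all(i):
        if i >= n:
            return [()]
        options = [tail for tail in enumerate_all(i + 1)]
        if i + 1 < n and times[i + 1] - times[i] <= params.t_small:
            options += [(("small", times[i]),) + tail for tail in enumerate_all(i + 2)]
        if i + 3 < n and times[i + 3] - times[i] <= params.t_large:
            options += [(("large", times[i]),) + tail for tail in enumerate_all(i + 4)]
        return options

    return max(enumerate_all(0), key=rank)


class TestDetectBursts:
    def test_two_spikes_within_window_form_small_burst(self):
        events = detect_bursts([0.0, 0.005])
        assert len(events) == 1
        assert events[0].burst_type == "small"
        assert events[0].time == 0.0

    def test_four_spread_spikes_form_large_burst_without_inner_small(self):
        # no small burst inside a large one
        events = detect_bursts([0.0, 0.030, 0.060, 0.090])
        assert [e.burst_type for e in events] == ["large"]
        assert events[0].time == 0.0
        assert events[0].n_spikes == 4

    def test_sparse_train_has_no_bursts(self):
        assert detect_bursts([0.0, 0.2, 0.4]) == []

    def test_event_times_are_first_spikes_and_spikes_disjoint(self):
        events = detect_bursts([0.0, 0.002, 0.004, 0.006, 0.5, 0.503])
        assert [e.burst_type for e in events] == ["large", "small"]
        used = [s for e in events for s in e.constituent_spikes]
        assert len(used) == len(set(used))

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            detect_bursts([0.1, 0.05])

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.lists(st.floats(0.0, 0.5), min_size=0, max_size=12, unique=True))
    def test_greedy_equals_exhaustive_preference_oracle(self, raw):
        times = sorted(raw)
        params = PlasticityParams()
        got = [(e.burst_type, e.time) for e in detect_bursts(times, params)]
        assert got == list(greedy_oracle(times, params))


class TestApplyDepression:
    def setup_method(self):
        self.params = PlasticityParams()
        self.pf = build_segments(8.0, 2e-3)

    def test_burst_outside_all_windows_leaves_weights_unchanged(self):
        # event long after the last onset covered by any window
        pf = build_segments(8.0, 2e-3, initial_weights=1.0)
        before = pf.weights.copy()
        ev = BurstEvent("small", -0.5, (-0.5,))
        apply_depression(pf, ev, self.params)
        np.testing.assert_array_equal(pf.weights, before)

    def test_zero_weights_stay_floored(self):
        pf = build_segments(8.0, 2e-3, initial_weights=0.0)
        apply_depression(pf, BurstEvent("large", 0.05, (0.05,)), self.params)
        assert np.all(pf.weights == 0.0)

    def test_exact_depression_at_kernel_peak(self):
        # burst exactly at a segment onset: K(0) = 1, decrement exactly eta
        pf = build_segments(8.0, 2e-3, initial_weights=1.0)
        j = 10
        t_post = j * pf.segment_duration
        apply_depression(pf, BurstEvent("small", t_post, (t_post,)), self.params)
        assert pf.weights[j] == pytest.approx(1.0 - self.params.eta_small)

    def test_large_burst_depresses_at_least_as_much_as_small(self):
        for j in range(5):
            pf_s = build_segments(8.0, 2e-3, initial_weights=1.0)
            pf_l = build_segments(8.0, 2e-3, initial_weights=1.0)
            t_post = j * pf_s.segment_duration
            apply_depression(pf_s, BurstEvent("small", t_post, (t_post,)), self.params)
            apply_depression(pf_l, BurstEvent("large", t_post, (t_post,)), self.params)
            assert np.all(pf_l.weights <= pf_s.weights + 1e-15)

    def test_only_causal_onsets_depressed(self):
        # segments whose most recent onset follows the burst are untouched
        pf = build_segments(8.0, 2e-3, initial_weights=1.0)
        t_post = 10.5 * pf.segment_duration
        apply_depression(pf, BurstEvent("small", t_post, (t_post,)), self.params)
        w_small = self.params.w_small
        first_in_window = math.ceil((t_post - w_small) / pf.segment_duration)
        touched = set(range(first_in_window, 11))
        for j in range(pf.n_segments):
            if j in touched:
                assert pf.weights[j] < 1.0
            else:
                assert pf.weights[j] == 1.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        times=st.lists(st.floats(0.0, 2.0), min_size=1, max_size=20),
        kinds=st.lists(st.sampled_from(["small", "large"]), min_size=20, max_size=20),
    )
    def test_weights_always_within_bounds(self, times, kinds):
        pf = build_segments(8.0, 2e-3)
        params = replace(self.params, eta_small=0.4, eta_large=0.8)
        for t, k in zip(sorted(times), kinds):
            apply_depression(pf, BurstEvent(k, t, (t,)), params)
            apply_potentiation(pf, 0.3, params)
            assert np.all(pf.weights >= 0.0)
            assert np.all(pf.weights <= pf.w_max)


class TestApplyPotentiation:
    def test_ceiling_is_a_fixed_point(self):
        pf = build_segments(8.0, 2e-3)  # starts at w_max
        apply_potentiation(pf, 1e4)
        assert np.all(pf.weights == pf.w_max)

    def test_asymptotic_recovery_to_ceiling(self):
        pf = build_segments(8.0, 2e-3, initial_weights=0.0)
        apply_potentiation(pf, 1e6)
        np.testing.assert_allclose(pf.weights, 1.5, atol=1e-6)

    def test_closed_form_after_one_time_constant(self):
        # w = 0.5 after tau_w: 1.5 - 1.0/e ~ 1.1321
        pf = build_segments(8.0, 2e-3, initial_weights=0.5)
        apply_potentiation(pf, 980.0)
        np.testing.assert_allclose(pf.weights, 1.5 - math.exp(-1.0), atol=1e-12)
        assert pf.weights[0] == pytest.approx(1.1321, abs=5e-4)

    def test_matches_fine_step_euler_oracle(self):
        params = PlasticityParams()
        w, dt = 0.2, 0.01
        for _ in range(int(50.0 / dt)):
            w += dt * (params.w_max - w) / params.tau_w
        pf = build_segments(8.0, 2e-3, initial_weights=0.2)
        apply_potentiation(pf, 50.0, params)
        assert pf.weights[0] == pytest.approx(w, rel=1e-3)

    def test_negative_elapsed_rejected(self):
        pf = build_segments(8.0, 2e-3)
        with pytest.raises(ValueError):
            apply_potentiation(pf, -1.0)


class TestEquilibriumStatics:
    @staticmethod
    def _toy_equilibrium(tau_w):
        """Two-segment toy driven by regular bursts at segment-0 onsets.

        Brute-force iteration of the two update rules to their fixed point,
        independent of the training loop.
        """
        params = replace(PlasticityParams(), tau_w=tau_w, w_small=0.05)
        pf = build_segments(8.0, 0.125 / 2)  # 2 segments
        interval = 0.25  # a multiple of the period: always segment 0's onset
        for k in range(8000):
            apply_potentiation(pf, interval, params)
            t_post = k * interval
            apply_depression(pf, BurstEvent("small", t_post, (t_post,)), params)
        return pf.weights.copy()

    def test_smaller_tau_w_gives_higher_equilibrium_weights(self):
        w_fast = self._toy_equilibrium(tau_w=50.0)
        w_slow = self._toy_equilibrium(tau_w=980.0)
        assert np.all(w_fast >= w_slow - 1e-9)
        assert w_fast.mean() > w_slow.mean()

    def test_negligible_depression_equilibrates_at_ceiling(self, transfer):
        params = PlasticityParams(eta_small=1e-12, eta_large=2e-12, tau_w=5.0)
        spec = StimulusSpec(8.0, 10.0, 1.0, "global")
        G = feedback_gain(10.0, transfer, DEFAULT_GAIN, "global", 8.0)
        sh = feedback_shunt(10.0, transfer, DEFAULT_GAIN, "global", 8.0)
        res = train_to_equilibrium(
            spec, transfer, G, feedback_shunt=sh, plasticity=params,
            dt=FAST_DT, seed=4, max_epochs=30, min_epochs=10,
        )
        np.testing.assert_allclose(res.pf.weights, 1.5, atol=1e-6)

    def test_training_reproducible_under_seed(self, transfer, scaled_plasticity):
        spec = StimulusSpec(8.0, 10.0, 1.0, "global")
        G = feedback_gain(10.0, transfer, DEFAULT_GAIN, "global", 8.0)
        sh = feedback_shunt(10.0, transfer, DEFAULT_GAIN, "global", 8.0)
        kw = dict(
            feedback_shunt=sh, plasticity=scaled_plasticity, dt=FAST_DT,
            seed=42, max_epochs=40, min_epochs=10,
        )
        r1 = train_to_equilibrium(spec, transfer, G, **kw)
        r2 = train_to_equilibrium(spec, transfer, G, **kw)
        np.testing.assert_array_equal(r1.pf.weights, r2.pf.weights)

    def test_training_requires_global_stimulus(self, transfer):
        with pytest.raises(ValueError, match="global"):
            train_to_equilibrium(StimulusSpec(8.0, 10.0, 1.0, "local"), transfer, 1.0)


def test_burst_log_frame():
    from ellcancel import bursts_to_frame

    events = detect_bursts([0.0, 0.002, 0.004, 0.006, 0.5, 0.503])
    frame = bursts_to_frame(events)
    assert list(frame.columns) == ["time_s", "burst_type", "n_spikes"]
    assert frame.n_spikes.tolist() == [4, 2]


class TestDepressionKernel:
    @pytest.mark.parametrize("shape", ["linear", "exponential", "raised-cosine"])
    def test_kernel_supported_causal_and_bounded(self, shape):
        dt = np.linspace(-0.05, 0.2, 400)
        k = depression_kernel(dt, window=0.1, shape=shape)
        assert np.all(k[dt < 0] == 0)
        assert np.all(k[dt > 0.1] == 0)
        assert np.all((k >= 0) & (k <= 1))
        assert depression_kernel(np.array([0.0]), 0.1, shape)[0] == pytest.approx(1.0)
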