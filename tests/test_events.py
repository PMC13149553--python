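import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from speedcode.events import (
    FiringWindow,
    Peth,
    build_heatmap,
    compute_peth,
    detect_firing_window,
    detect_running_events,
    label_trials,
    spike_density,
    time_difference_stats,
)
from speedcode.session import SpeedTrace, SpikeTrain, StimulusEvent, StimulusSchedule


def _step_trace(onset=10.0, dur=5.0, level=20.0, fs=100.0, total=60.0):
    v = np.zeros(int(total * fs))
    i0, i1 = int(onset * fs), int((onset + dur) * fs)
    v[i0:i1] = level
    return SpeedTrace(fs, v)


class TestRunningEvents:
    def test_zero_trace_zero_events(self, flat_trace):
        assert len(detect_running_events(flat_trace)) == 0

    def test_step_bout_onset_within_one_sample(self):
        trace = _step_trace()
        ev = detect_running_events(trace, threshold=0.5)
        assert len(ev) == 1
        assert abs(ev.onsets[0] - 10.0) <= 1.0 / trace.sampling_rate + 1e-12
        assert abs(ev.peak_speeds[0] - 20.0) < 1e-9

    def test_close_bouts_merged_by_min_gap(self):
        fs = 100.0
        v = np.zeros(3000)
        v[1000:1200] = 10.0    # 10-12 s
        v[1205:1400] = 10.0    # gap 0.05 s < min_gap 0.2 s
        ev = detect_running_events(SpeedTrace(fs, v), min_gap=0.2, min_duration=0.5)
        assert len(ev) == 1

    def test_short_bouts_dropped(self):
        fs = 100.0
        v = np.zeros(2000)
        v[1000:1020] = 10.0  # 0.2 s < min_duration
        ev = detect_running_events(SpeedTrace(fs, v), min_duration=0.5)
        assert len(ev) == 0

    def test_negative_speed_detected_by_magnitude(self):
        trace = _step_trace(level=-15.0)
        ev = detect_running_events(trace)
        assert len(ev) == 1 and ev.peak_speeds[0] == 15.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_subthreshold_noise_invariance(self, seed):
        # noise strictly below threshold/2 on a flat trace adds no events
        rng = np.random.default_rng(seed)
        noise = rng.uniform(-0.24, 0.24, 2000)
        ev = detect_running_events(SpeedTrace(100.0, noise), threshold=0.5)
        assert len(ev) == 0

    def test_idempotent_on_detected_events(self):
        trace = _step_trace()
        a = detect_running_events(trace)
        b = detect_running_events(trace)
        np.testing.assert_array_equal(a.onsets, b.onsets)


class TestLabelTrials:
    def test_no_stimuli_all_spontaneous(self, flat_trace):
        trace = _step_trace()
        ev = detect_running_events(trace)
        labelled, trials = label_trials(ev, StimulusSchedule(), trace, 3.0)
        assert labelled.provenance == ["spontaneous"]
        assert trials == []

    def test_recent_stimulus_marks_run_evoked(self):
        trace = _step_trace(onset=10.0)
        ev = detect_running_events(trace)
        stim = StimulusSchedule([StimulusEvent("sound", 9.0, 1.0)])
        labelled, _ = label_trials(ev, stim, trace, 3.0)
        assert labelled.provenance == ["stimulus_evoked"]

    def test_flat_speed_marks_stimulus_no_run(self, flat_trace):
        stim = StimulusSchedule([StimulusEvent("light", 5.0, 1.0)])
        ev = detect_running_events(flat_trace)
        _, trials = label_trials(ev, stim, flat_trace, 3.0)
        assert trials[0]["no_run"] is True


class TestPeth:
    def test_hand_counted_bins(self):
        spikes = SpikeTrain("a", np.array([0.005, 0.012, 0.095]), 1.0)
        peth = compute_peth(spikes, np.array([0.0]), window=(0.0, 0.1), bin_width=0.01)
        expected = np.zeros(10, dtype=int)
        expected[[0, 1, 9]] = 1
        np.testing.assert_array_equal(peth.counts[0], expected)
        assert peth.mean_rate[0] == pytest.approx(100.0)

    def test_empty_train_all_zero(self):
        spikes = SpikeTrain("a", np.array([]), 10.0)
        peth = compute_peth(spikes, np.array([5.0]), window=(-1, 1), bin_width=0.1)
        assert peth.counts.sum() == 0

    def test_rate_invariant_to_duplicated_trials(self):
        spikes = SpikeTrain("a", np.array([1.1, 2.1]), 10.0)
        one = compute_peth(spikes, np.array([1.0]), (0, 0.5), 0.1)
        two = compute_peth(spikes, np.array([1.0, 1.0]), (0, 0.5), 0.1)
        np.testing.assert_allclose(one.mean_rate, two.mean_rate)

    def test_no_events_raises(self):
        spikes = SpikeTrain("a", np.array([1.0]), 10.0)
        with pytest.raises(ValueError, match="no alignment events"):
            compute_peth(spikes, np.array([]), (0, 1), 0.1)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_counting(self, seed):
        rng = np.random.default_rng(seed)
        times = np.unique(np.round(rng.uniform(0, 30, 40), 6))
        spikes = SpikeTrain("a", times, 30.0)
        events = rng.uniform(5, 25, 3)
        peth = compute_peth(spikes, events, window=(-2, 2), bin_width=0.25)
        for i, t0 in enumerate(events):
            for j in range(peth.counts.shape[1]):
                lo = t0 + peth.bin_edges[j]
                hi = t0 + peth.bin_edges[j + 1]
                brute = np.sum((times >= lo) & (times < hi))
                assert peth.counts[i, j] == brute


class TestSpikeDensity:
    def test_empty_train_zero_density(self):
        sd = spike_density(SpikeTrain("a", np.array([]), 1.0), sigma=0.01)
        assert np.all(sd.density == 0)

    def test_single_spike_peak_height(self):
        spikes = SpikeTrain("a", np.array([0.5]), 1.0)
        sd = spike_density(spikes, sigma=0.01, grid_step=0.0005)
        peak = sd.density.max()
        assert peak == pytest.approx(1.0 / (0.01 * np.sqrt(2 * np.pi)), rel=1e-3)

    def test_integral_conserves_spike_count(self):
        spikes = SpikeTrain("a", np.array([2.0, 5.0, 7.5]), 10.0)
        sd = spike_density(spikes, sigma=0.01, grid_step=0.0005)
        integral = np.trapezoid(sd.density, sd.grid)
        assert integral == pytest.approx(3.0, abs=1e-3)


class TestFiringWindow:
    @staticmethod
    def _peth_from_rates(rates, bin_width=0.1, n_trials=10):
        """Counts matrix whose mean rate reproduces `rates` exactly."""
        rates = np.asarray(rates, dtype=float)
        counts = np.tile(rates * bin_width, (n_trials, 1)).astype(int)
        edges = -rates.size * bin_width + np.arange(rates.size + 1) * bin_width
        return Peth(bin_edges=edges, counts=counts)

    def test_hand_scan_window(self):
        # baseline 2 sp/s over [-10, -5]; ramp above 3.1 from -1.8 to 0
        bw = 0.1
        rates = np.full(100, 20.0)          # 10 s pre-onset, counts = 2/bin
        rates[-18:] = 40.0                  # last 1.8 s elevated
        peth = self._peth_from_rates(rates, bw)
        win = detect_firing_window(peth, (-10.0, -5.0), sustained=True, smooth_sigma=0)
        assert win.start == pytest.approx(-1.8)
        assert win.end == 0.0

    def test_flat_peth_no_window(self):
        peth = self._peth_from_rates(np.full(100, 20.0))
        win = detect_firing_window(peth, (-10.0, -5.0), smooth_sigma=0)
        assert not win.found
        assert win.time_difference is None

    def test_threshold_is_strictly_baseline_plus_two_sd(self):
        # rates exactly at mean + 2 SD must NOT start a window
        bw = 0.1
        base = np.tile([10.0, 30.0], 25)     # mean 20, SD 10
        peth_rates = np.concatenate([base, np.full(50, 40.0)])   # == mean+2SD
        peth = self._peth_from_rates(peth_rates, bw)
        win = detect_firing_window(peth, (-10.0, -5.0), smooth_sigma=0)
        assert not win.found
        above = np.concatenate([base, np.full(50, 50.0)])        # > mean+2SD
        win2 = detect_firing_window(self._peth_from_rates(above, bw),
                                    (-10.0, -5.0), smooth_sigma=0)
        assert win2.found

    def test_degenerate_baseline_flagged(self):
        rates = np.full(100, 10.0)
        rates[-10:] = 20.0
        win = detect_firing_window(self._peth_from_rates(rates), (-10.0, -5.0),
                                   smooth_sigma=0)
        assert win.degenerate_baseline
        assert win.found


class TestTimeDifferenceStats:
    def test_constant_input(self):
        wins = [FiringWindow(-2.0, 0.0, 1.0, 0.1) for _ in range(5)]
        out = time_difference_stats(wins)
        assert out["mean"] == pytest.approx(2.0)
        assert out["sd"] == 0.0
        assert "gauss_fit" not in out  # degenerate histogram, no fit

    def test_gaussian_sample_recovers_mean(self):
        rng = np.random.default_rng(0)
        diffs = rng.normal(2.225, 0.582, 500)
        wins = [FiringWindow(-d, 0.0, 0.0, 0.0) for d in diffs]
        out = time_difference_stats(wins)
        assert out["gauss_fit"] is not None
        assert out["gauss_fit"]["mu"] == pytest.approx(2.225, abs=0.1)

    def test_gaussian_fits_normal_better_than_uniform(self):
        rng = np.random.default_rng(1)
        normal = rng.normal(2.0, 0.5, 400)
        uniform = rng.uniform(0.5, 3.5, 400)
        r2 = {}
        for name, d in (("n", normal), ("u", uniform)):
            wins = [FiringWindow(-x, 0.0, 0.0, 0.0) for x in d]
            r2[name] = time_difference_stats(wins)["gauss_fit"]["r_squared"]
        assert r2["n"] > r2["u"]


class TestHeatmap:
    @staticmethod
    def _events(onsets, peak=10.0):
        onsets = np.asarray(onsets, dtype=float)
        from speedcode.events import RunningEvents
        return RunningEvents(onsets, onsets + 2.0, np.full(onsets.size, peak))

    def test_rows_minmax_scaled(self, rng):
        spikes = SpikeTrain("a", np.unique(np.round(rng.uniform(0, 100, 300), 5)), 100.0)
        mat, kept, _ = build_heatmap([spikes], [self._events([30.0, 60.0])])
        assert mat.shape[0] == 1
        assert mat.min() == 0.0 and mat.max() == 1.0

    def test_event_too_close_to_previous_excluded(self):
        spikes = SpikeTrain("a", np.array([29.55, 30.5]), 100.0)
        events = self._events([26.0, 30.0])  # 4 s apart: second excluded
        mat, kept, centers = build_heatmap([spikes], [events])
        # only the event at 26 s qualifies
        assert mat.shape[0] == 1
        # spike at 29.55 lands 3.55 s after the qualifying onset
        j = np.argmin(np.abs(centers - 3.55))
        assert mat[0][j] == 1.0

    def test_rate_equals_brute_force_count_over_n_dt(self):
        spikes = SpikeTrain("a", np.array([10.05, 10.15, 20.05, 30.25]), 60.0)
        onsets = np.array([10.0, 20.0, 30.0])
        from speedcode.events import RunningEvents
        ev = RunningEvents(onsets, onsets + 1.0, np.full(3, 5.0))
        peth = compute_peth(spikes, onsets, (-10, 10), 0.1)
        # bin [0.0, 0.1): spikes 10.05 and 20.05 -> 2 / (3 * 0.1)
        j = np.flatnonzero(np.isclose(peth.bin_edges[:-1], 0.0))[0]
        assert peth.mean_rate[j] == pytest.approx(2 / (3 * 0.1))

    def test_constant_row_maps_to_zero(self):
        spikes = SpikeTrain("a", np.array([]), 100.0)
        mat, kept, _ = build_heatmap([spikes], [self._events([40.0])])
        assert kept == ["a"]
        assert np.all(mat == 0.0)

    def test_neuron_without_qualifying_events_omitted(self):
        spikes = SpikeTrain("a", np.array([1.0]), 50.0)
        ev = self._events([30.0], peak=0.2)  # below min_peak
        mat, kept, _ = build_heatmap([spikes], [ev])
        assert mat.size == 0 and kept == []
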