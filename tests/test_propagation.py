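"""PSTH construction, peak delays, first-spike latencies, trial classification."""

import numpy as np
import pytest

from tunnelmea.bursts import Burstlet, merge_network_bursts
from tunnelmea.data import SpikeData, StimulusLog
from tunnelmea.layout import default_layout
from tunnelmea.propagation import (
    PropagationTrial,
    analyze_trials,
    classify_trial,
    compute_psth,
    first_spike_latency,
    peak_to_peak_delay,
    summarize_propagation,
)

LAYOUT = default_layout()


def _stim(times, electrode="41"):
    return StimulusLog(times=np.asarray(times, float), electrode=electrode)


def _session(trains, duration):
    return SpikeData(trains=trains, duration=duration, layout=LAYOUT)


class TestComputePsth:
    def test_single_spike_bin_placement(self):
        spikes = _session({"22": np.array([1.012])}, 3.0)
        psth = compute_psth(spikes, _stim([1.0]), "A")[0]
        counts = psth.counts["22"]
        assert counts.sum() == 1
        assert counts[2] == 1  # 12 ms falls in the [10, 15) ms bin

    def test_no_spikes_all_zero(self):
        spikes = _session({}, 3.0)
        psth = compute_psth(spikes, _stim([1.0]), "A")[0]
        assert psth.mean_profile.sum() == 0

    def test_blanked_and_stimulated_spikes_excluded(self):
        trains = {"22": np.array([1.002, 1.050]),    # first falls in blanking
                  "41": np.array([1.100])}           # stimulated electrode
        spikes = _session(trains, 3.0)
        psth = compute_psth(spikes, _stim([1.0]), "A")[0]
        assert "41" not in psth.counts
        assert psth.counts["22"].sum() == 1

    def test_trial_near_recording_end_dropped(self):
        spikes = _session({"22": np.array([0.5])}, 3.0)
        out = compute_psth(spikes, _stim([1.0, 2.8]), "A")
        assert len(out) == 1

    def test_poisson_rate_expectation(self, rng):
        """100 Hz Poisson spiking averages ~0.5 counts per 5 ms bin."""
        duration, n_trials = 125.0, 60
        t = np.sort(rng.uniform(0, duration, rng.poisson(100 * duration)))
        spikes = _session({"22": np.unique(t)}, duration)
        stim = StimulusLog(times=np.arange(n_trials) * 2.0 + 0.25, electrode="41")
        psths = compute_psth(spikes, stim, "A", blank=0.0)
        counts = np.concatenate([p.counts["22"] for p in psths])
        se = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - 0.5) < 3 * se

    def test_spike_count_conservation(self, session_5t):
        """PSTH totals equal the region spikes in-window minus exclusions."""
        spikes, stim, _ = session_5t
        psths = compute_psth(spikes, stim, "A")
        ids = [e for e in spikes.layout.region_ids("A") if e != stim.electrode]
        for p in psths:
            t0 = p.stimulus_time
            manual = sum(
                int(np.sum((spikes.train(e) >= t0 + 0.005)
                           & (spikes.train(e) < t0 + 0.5)))
                for e in ids)
            assert sum(c.sum() for c in p.counts.values()) == manual
            assert p.spikes_ms.size == manual


class TestPeakToPeakDelay:
    def _psth_with_peak(self, peak_bin, region="A"):
        edges = np.arange(101) * 5.0
        counts = np.zeros(100)
        counts[peak_bin] = 10.0
        from tunnelmea.propagation import PSTHMatrix
        return PSTHMatrix(stimulus_time=0.0, region=region, edges_ms=edges,
                          counts={"22": counts}, spikes_ms=np.empty(0))

    def test_simple_subtraction(self):
        # peaks centred at 25 ms (bin 5) and 150 ms (bin 30)
        assert peak_to_peak_delay(self._psth_with_peak(5),
                                  self._psth_with_peak(30)) == pytest.approx(125.0)

    def test_identical_profiles_zero_delay(self):
        p = self._psth_with_peak(12)
        assert peak_to_peak_delay(p, p) == 0.0

    def test_flat_profile_undefined(self):
        flat = self._psth_with_peak(0)
        flat.counts["22"][:] = 0.0
        assert peak_to_peak_delay(self._psth_with_peak(5), flat) is None

    def test_tie_breaks_toward_earlier_bin(self):
        from tunnelmea.propagation import PSTHMatrix
        edges = np.arange(101) * 5.0
        counts = np.zeros(100)
        counts[[40, 60]] = 7.0  # symmetric twin peaks
        p = PSTHMatrix(0.0, "A", edges, {"22": counts}, np.empty(0))
        q = self._psth_with_peak(0)
        assert peak_to_peak_delay(q, p) == pytest.approx(40 * 5.0 + 2.5 - 2.5)


class TestFirstSpikeLatency:
    def _ramp_psth(self):
        """Profile ramping linearly 0 -> peak over [0, 100] ms, then back down.

        The symmetric descent keeps the apex in place under smoothing.
        """
        from tunnelmea.propagation import PSTHMatrix
        edges = np.arange(101) * 5.0
        counts = np.zeros(100)
        counts[:20] = np.arange(1, 21)   # linear ramp peaking in bin 19
        counts[20:39] = np.arange(19, 0, -1)
        spikes = np.arange(0, 500, 1.0)  # dense spikes every 1 ms
        return PSTHMatrix(0.0, "A", edges, {"22": counts}, spikes)

    def test_linear_ramp_geometry(self):
        psth = self._ramp_psth()
        assert first_spike_latency(psth, 0.5) == pytest.approx(50.0, abs=5.0)
        assert first_spike_latency(psth, 0.1) == pytest.approx(10.0, abs=5.0)

    def test_threshold_one_returns_peak_time(self):
        psth = self._ramp_psth()
        lat = first_spike_latency(psth, 1.0)
        assert lat == pytest.approx(95.0, abs=5.0)

    def test_threshold_ordering_on_simulated_trials(self, session_5t):
        """latency(10%) <= latency(20%) <= latency(50%) on every trial."""
        spikes, stim, _ = session_5t
        trials = analyze_trials(spikes, stim)
        checked = 0
        for t in trials:
            for lat in (t.latency_a_ms, t.latency_b_ms):
                if len(lat) == 3:
                    assert lat[0.1] <= lat[0.2] <= lat[0.5]
                    checked += 1
        assert checked > 50

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            first_spike_latency(self._ramp_psth(), 0.0)


class TestClassifyTrial:
    def _event(self, region, start, end, n_electrodes=8):
        bl = [Burstlet(f"{region}{i}", start, end, 4) for i in range(n_electrodes)]
        return merge_network_bursts(bl, region=region)[0]

    def test_propagated_trial_is_success(self):
        a = [self._event("A", 10.015, 10.2)]
        b = [self._event("B", 10.140, 10.3)]
        af, bf, a0, b0 = classify_trial(a, b, 10.0)
        assert (af, bf) == (True, True)
        assert b0 > a0

    def test_no_b_burst_is_failure(self):
        a = [self._event("A", 10.015, 10.2)]
        af, bf, _, _ = classify_trial(a, [], 10.0)
        assert (af, bf) == (True, False)

    def test_sporadic_b_firing_not_counted(self):
        """A one-electrode Well-B event is sporadic firing, not propagation."""
        a = [self._event("A", 10.015, 10.2)]
        b = [self._event("B", 10.140, 10.3, n_electrodes=1)]
        af, bf, _, _ = classify_trial(a, b, 10.0)
        assert (af, bf) == (True, False)

    def test_b_burst_before_a_onset_not_counted(self):
        a = [self._event("A", 10.100, 10.2)]
        b = [self._event("B", 10.050, 10.09)]
        af, bf, _, _ = classify_trial(a, b, 10.0)
        assert (af, bf) == (True, False)

    def test_no_a_burst_invalidates_trial(self):
        b = [self._event("B", 10.140, 10.3)]
        af, bf, _, _ = classify_trial([], b, 10.0)
        assert (af, bf) == (False, False)


class TestSummarizePropagation:
    def _trial(self, a, b, delay=None):
        return PropagationTrial(stimulus_time=0.0, a_burst=a, b_burst=b,
                                delay_ms=delay)

    def test_success_fraction_arithmetic(self):
        trials = [self._trial(True, True, 100.0)] * 12 + \
                 [self._trial(True, False)] * 48
        s = summarize_propagation(trials)
        assert s.success_fraction == pytest.approx(0.20)
        assert s.n_valid == 60

    def test_all_successes(self):
        s = summarize_propagation([self._trial(True, True, 50.0)] * 5)
        assert s.success_fraction == 1.0
        assert s.mean_delay_ms == pytest.approx(50.0)

    def test_invalid_trials_excluded_from_denominator(self):
        trials = [self._trial(False, False)] * 10 + [self._trial(True, True, 80.0)]
        s = summarize_propagation(trials)
        assert s.n_valid == 1 and s.success_fraction == 1.0

    def test_zero_valid_trials_flagged_empty(self):
        s = summarize_propagation([self._trial(False, False)] * 3)
        assert s.empty and s.success_fraction is None
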