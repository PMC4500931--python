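"""Evoked-burst propagation metrics: PSTHs, delays, latencies, success rates.

For every probe stimulus a post-stimulus time histogram (5 ms bins over a
500 ms window) is built per electrode and averaged within each well.  The
peak-to-peak delay is the time between the Well-A and Well-B profile peaks;
threshold first-spike latency is the first spike after the profile crosses
10/20/50% of its peak.  A trial counts as a successful propagation only when
a detected Well-B network burst (not merely sporadic spikes) starts inside
the window after the Well-A burst onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from .bursts import BurstEvent, detect_network_bursts
from .data import SpikeData, StimulusLog
from .layout import REGION_A, REGION_B

__all__ = [
    "PSTHMatrix",
    "PropagationTrial",
    "PropagationSummary",
    "compute_psth",
    "peak_to_peak_delay",
    "first_spike_latency",
    "classify_trial",
    "analyze_trials",
    "summarize_propagation",
]

WINDOW_S_DEFAULT = 0.500
BIN_S_DEFAULT = 0.005
BLANK_S_DEFAULT = 0.005
PEAK_SMOOTH_SD_BINS = 1.0      # analysis smoothing for peak finding
DISPLAY_SMOOTH_SD_BINS = 3.0   # broader smoothing for display profiles
LATENCY_THRESHOLDS = (0.1, 0.2, 0.5)
MIN_BURST_ELECTRODES_DEFAULT = 4
CORE_ELECTRODES_DEFAULT = 8


@dataclass
class PSTHMatrix:
    """Binned spike counts for one region in one post-stimulus window."""

    stimulus_time: float
    region: str
    edges_ms: np.ndarray                 # len n_bins + 1, half-open [t, t+bin)
    counts: dict[str, np.ndarray]        # electrode id -> per-bin counts
    spikes_ms: np.ndarray                # pooled region spike offsets (ms, blanked removed)

    @property
    def bin_ms(self) -> float:
        return float(self.edges_ms[1] - self.edges_ms[0])

    @property
    def centers_ms(self) -> np.ndarray:
        return 0.5 * (self.edges_ms[:-1] + self.edges_ms[1:])

    @property
    def mean_profile(self) -> np.ndarray:
        """Across-electrode mean count per bin."""
        if not self.counts:
            return np.zeros(len(self.edges_ms) - 1)
        return np.mean(list(self.counts.values()), axis=0)

    def smoothed_profile(self, sd_bins: float = PEAK_SMOOTH_SD_BINS) -> np.ndarray:
        return gaussian_filter1d(self.mean_profile, sd_bins, mode="nearest")


def compute_psth(spikes: SpikeData,
                 stim: StimulusLog,
                 region: str,
                 window: float = WINDOW_S_DEFAULT,
                 bin_s: float = BIN_S_DEFAULT,
                 blank: float = BLANK_S_DEFAULT) -> list[PSTHMatrix]:
    """One PSTH per stimulus; trials too close to the recording end are dropped.

    Spikes inside the blanking period and the stimulated electrode are
    excluded.  Bins partition ``[0, window)`` exactly.
    """
    n_bins = int(round(window / bin_s))
    if abs(n_bins * bin_s - window) > 1e-9:
        raise ValueError("bin width must divide the window exactly")
    edges = np.arange(n_bins + 1) * bin_s
    ids = tuple(e for e in spikes.active_ids(region) if e != stim.electrode)
    out = []
    for t0 in stim.times:
        if t0 + window > spikes.duration:
            continue  # dropped: window would run past the recording end
        counts = {}
        pooled = []
        for eid in ids:
            tr = spikes.train(eid)
            rel = tr[(tr >= t0 + blank) & (tr < t0 + window)] - t0
            counts[eid], _ = np.histogram(rel, bins=edges)
            pooled.append(rel)
        pooled = np.sort(np.concatenate(pooled)) if pooled else np.empty(0)
        out.append(PSTHMatrix(stimulus_time=float(t0), region=region,
                              edges_ms=edges * 1e3, counts=counts,
                              spikes_ms=pooled * 1e3))
    return out


def _peak_index(profile: np.ndarray) -> int | None:
    """Index of the global maximum; earlier bin wins ties; None if flat zero."""
    if profile.max() <= 0:
        return None
    return int(np.argmax(profile))


def peak_to_peak_delay(psth_a: PSTHMatrix, psth_b: PSTHMatrix,
                       smooth_sd_bins: float = PEAK_SMOOTH_SD_BINS) -> float | None:
    """Delay (ms) between the smoothed profile peaks of the two wells."""
    if not np.array_equal(psth_a.edges_ms, psth_b.edges_ms):
        raise ValueError("PSTHs must share identical bins")
    ia = _peak_index(psth_a.smoothed_profile(smooth_sd_bins))
    ib = _peak_index(psth_b.smoothed_profile(smooth_sd_bins))
    if ia is None or ib is None:
        return None
    centers = psth_a.centers_ms
    return float(centers[ib] - centers[ia])


def first_spike_latency(psth: PSTHMatrix, threshold: float,
                        smooth_sd_bins: float = PEAK_SMOOTH_SD_BINS) -> float | None:
    """First-spike latency (ms) at a fractional threshold of the profile peak.

    The crossing is the earliest bin, at or before the peak, where the
    smoothed profile reaches ``threshold x peak``; the latency is the first
    pooled region spike at or after the crossing time.  If the level is never
    reached before the peak the peak-bin start is used; with no qualifying
    spike the crossing time itself is returned.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    prof = psth.smoothed_profile(smooth_sd_bins)
    ip = _peak_index(prof)
    if ip is None:
        return None
    level = threshold * prof[ip]
    idx = np.flatnonzero(prof[: ip + 1] >= level)
    cross_idx = int(idx[0]) if idx.size else ip
    t_cross = psth.edges_ms[cross_idx]
    after = psth.spikes_ms[psth.spikes_ms >= t_cross]
    return float(after[0]) if after.size else float(t_cross)


@dataclass
class PropagationTrial:
    """Per-stimulus propagation record (times in ms post-stimulus)."""

    stimulus_time: float
    a_burst: bool
    b_burst: bool
    a_onset_ms: float | None = None
    b_onset_ms: float | None = None
    a_peak_ms: float | None = None
    b_peak_ms: float | None = None
    delay_ms: float | None = None
    latency_a_ms: dict[float, float] = field(default_factory=dict)
    latency_b_ms: dict[float, float] = field(default_factory=dict)

    @property
    def success(self) -> bool:
        return self.a_burst and self.b_burst

    def latency_diff_ms(self, threshold: float) -> float | None:
        a = self.latency_a_ms.get(threshold)
        b = self.latency_b_ms.get(threshold)
        return None if a is None or b is None else b - a


def classify_trial(bursts_a: list[BurstEvent],
                   bursts_b: list[BurstEvent],
                   stim_time: float,
                   window: float = WINDOW_S_DEFAULT,
                   min_electrodes: int = MIN_BURST_ELECTRODES_DEFAULT,
                   core_electrodes: int = CORE_ELECTRODES_DEFAULT,
                   lead: float = 0.300,
                   ) -> tuple[bool, bool, float | None, float | None]:
    """Evoked / propagated burst flags for one stimulus.

    A trial has an evoked burst when a source-well network burst spanning
    at least ``min_electrodes`` electrodes has its core onset (the earliest
    moment ``core_electrodes`` electrodes burst simultaneously) inside the
    window; propagation requires a comparable target-well burst with core
    onset after the evoked one.  The electrode minimum separates network
    bursts from sporadic firing; the stiffer core requirement keeps the
    onset on the main body of the burst, because chance pre-burst spikes
    chained into a handful of burstlets can otherwise drag it early.  The
    evoked-burst test additionally accepts onsets up to ``lead`` seconds
    before the stimulus (safe because stimuli are separated by orders of
    magnitude more than that).  Returns (a_flag, b_flag, a_onset, b_onset)
    with onsets in seconds.
    """
    core_n = max(min_electrodes, core_electrodes)

    def onsets(events, lo):
        cores = (e.core_start(core_n) for e in events
                 if e.n_electrodes >= min_electrodes)
        return sorted(t for t in cores
                      if t is not None and lo <= t < stim_time + window)

    a_on = onsets(bursts_a, stim_time - lead)
    if not a_on:
        return False, False, None, None
    b_on = [t for t in onsets(bursts_b, stim_time) if t > a_on[0]]
    return True, bool(b_on), a_on[0], (b_on[0] if b_on else None)


def analyze_trials(spikes: SpikeData,
                   stim: StimulusLog,
                   source: str = REGION_A,
                   target: str = REGION_B,
                   window: float = WINDOW_S_DEFAULT,
                   bin_s: float = BIN_S_DEFAULT,
                   blank: float = BLANK_S_DEFAULT,
                   thresholds: tuple[float, ...] = LATENCY_THRESHOLDS,
                   min_electrodes: int = MIN_BURST_ELECTRODES_DEFAULT,
                   core_electrodes: int = CORE_ELECTRODES_DEFAULT,
                   bursts_a: list[BurstEvent] | None = None,
                   bursts_b: list[BurstEvent] | None = None,
                   ) -> list[PropagationTrial]:
    """Full per-trial propagation analysis for one session."""
    if bursts_a is None:
        bursts_a = detect_network_bursts(spikes, source)
    if bursts_b is None:
        bursts_b = detect_network_bursts(spikes, target)
    psth_a = compute_psth(spikes, stim, source, window, bin_s, blank)
    psth_b = compute_psth(spikes, stim, target, window, bin_s, blank)
    trials = []
    for pa, pb in zip(psth_a, psth_b):
        t0 = pa.stimulus_time
        a_flag, b_flag, a_on, b_on = classify_trial(
            bursts_a, bursts_b, t0, window, min_electrodes, core_electrodes)
        trial = PropagationTrial(
            stimulus_time=t0, a_burst=a_flag, b_burst=b_flag,
            a_onset_ms=None if a_on is None else (a_on - t0) * 1e3,
            b_onset_ms=None if b_on is None else (b_on - t0) * 1e3,
        )
        prof_a, prof_b = pa.smoothed_profile(), pb.smoothed_profile()
        ia, ib = _peak_index(prof_a), _peak_index(prof_b)
        if ia is not None:
            trial.a_peak_ms = float(pa.centers_ms[ia])
            for th in thresholds:
                trial.latency_a_ms[th] = first_spike_latency(pa, th)
        if ib is not None:
            trial.b_peak_ms = float(pb.centers_ms[ib])
            for th in thresholds:
                trial.latency_b_ms[th] = first_spike_latency(pb, th)
        if trial.success and ia is not None and ib is not None:
            trial.delay_ms = peak_to_peak_delay(pa, pb)
        trials.append(trial)
    return trials


@dataclass
class PropagationSummary:
    n_trials: int
    n_valid: int              # trials with an evoked source burst
    n_success: int
    success_fraction: float | None
    mean_delay_ms: float | None
    delay_ci_ms: tuple[float, float] | None
    mean_latency_diff_ms: dict[float, float]
    latency_diff_ci_ms: dict[float, tuple[float, float]]
    empty: bool = False


def _t_ci(x: np.ndarray, confidence: float) -> tuple[float, float]:
    if x.size < 2 or np.std(x, ddof=1) == 0:
        return float(x.mean()), float(x.mean())
    lo, hi = stats.t.interval(confidence, x.size - 1, loc=x.mean(), scale=stats.sem(x))
    return float(lo), float(hi)


def summarize_propagation(trials: list[PropagationTrial],
                          confidence: float = 0.95) -> PropagationSummary:
    """Success fraction over valid trials plus delay/latency t-intervals."""
    valid = [t for t in trials if t.a_burst]
    if not valid:
        return PropagationSummary(len(trials), 0, 0, None, None, None, {}, {}, empty=True)
    successes = [t for t in valid if t.success]
    delays = np.array([t.delay_ms for t in successes if t.delay_ms is not None])
    mean_delay = float(delays.mean()) if delays.size else None
    delay_ci = _t_ci(delays, confidence) if delays.size else None
    lat_mean, lat_ci = {}, {}
    thresholds = sorted({th for t in successes for th in t.latency_a_ms})
    for th in thresholds:
        diffs = np.array([d for t in successes
                          if (d := t.latency_diff_ms(th)) is not None])
        if diffs.size:
            lat_mean[th] = float(diffs.mean())
            lat_ci[th] = _t_ci(diffs, confidence)
    return PropagationSummary(
        n_trials=len(trials), n_valid=len(valid), n_success=len(successes),
        success_fraction=len(successes) / len(valid),
        mean_delay_ms=mean_delay, delay_ci_ms=delay_ci,
        mean_latency_diff_ms=lat_mean, latency_diff_ci_ms=lat_ci)
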