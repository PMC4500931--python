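"""Two-well feed-forward spiking simulator with tunnel-count dose response.

The generator emulates a pair of cultured cortical populations coupled by a
configurable number of axon-filled microtunnels.  Each well fires a ~1 Hz
Poisson baseline per electrode; network bursts (spontaneous, or evoked by a
probe stimulus in the source well) raise firing under an alpha-function
envelope.  A source-well burst crosses to the other well with a probability
and mean onset delay that depend on the total axon count, following the
printed dose-response anchors:

* success probability: piecewise-linear through (0 axons, 0), (20, 0.20),
  (50, 0.50), (100, 0.80), constant 0.80 beyond 100 axons (the propagation
  probability plateaus around ten tunnels);
* mean delay: 300 ms at 20 axons decaying exponentially to a 90 ms floor,
  ``90 + 210 * exp(-(n - 20) / 60)`` ms for n >= 20.

Electrodes beneath the tunnels additionally record axonal relay copies of
source-burst spikes, delayed by each axon's conduction time over the 400 um
tunnel (uniform 0.4-2.2 ms, i.e. 180-1140 mm/s).
"""

from __future__ import annotations

import math

from dataclasses import dataclass

import numpy as np

from .data import SpikeData, StimulusLog, RawRecording, DEFAULT_SAMPLING_HZ
from .layout import (
    ElectrodeLayout,
    default_layout,
    electrode_id,
    DEFAULT_STIM_ELECTRODE,
    DEFAULT_STIM_ELECTRODE_REVERSE,
    REGION_A,
    REGION_B,
)

__all__ = [
    "CalibrationCurve",
    "DelayCalibration",
    "SimConfig",
    "GroundTruth",
    "BurstRecord",
    "StimulusRecord",
    "transmission_probability",
    "mean_transmission_delay",
    "simulate_session",
    "render_raw_trace",
    "DEFAULT_SUCCESS_CURVE",
    "DEFAULT_DELAY_CALIBRATION",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone piecewise-linear dose-response through printed anchors.

    ``anchors`` are (axon_count, value) pairs with strictly increasing axon
    counts; ``extrapolation`` is ``"constant"`` (hold the last anchor value)
    or ``"linear-to-origin"`` (only meaningful below the first anchor).
    """

    anchors: tuple[tuple[float, float], ...]
    extrapolation: str = "constant"

    def __post_init__(self):
        xs = [a[0] for a in self.anchors]
        if len(xs) < 1 or any(b <= a for a, b in zip(xs, xs[1:])):
            raise ValueError("anchor axon counts must be strictly increasing")
        if self.extrapolation not in ("constant", "linear-to-origin"):
            raise ValueError(f"unknown extrapolation rule {self.extrapolation!r}")

    def __call__(self, n_axons: float) -> float:
        if n_axons < 0:
            raise ValueError("axon count must be non-negative")
        xs = np.array([a[0] for a in self.anchors])
        ys = np.array([a[1] for a in self.anchors])
        if n_axons <= xs[0]:
            if self.extrapolation == "linear-to-origin" and xs[0] > 0:
                return float(ys[0] * n_axons / xs[0])
            return float(ys[0])
        if n_axons >= xs[-1]:
            return float(ys[-1])
        return float(np.interp(n_axons, xs, ys))


#: success anchors from the printed 2-tunnel 20% / 5-tunnel 50% / 10-tunnel 80%
#: figures at ~10 axons per tunnel, with zero transmission at zero axons
DEFAULT_SUCCESS_CURVE = CalibrationCurve(
    anchors=((0.0, 0.0), (20.0, 0.20), (50.0, 0.50), (100.0, 0.80)),
    extrapolation="constant",
)


@dataclass(frozen=True)
class DelayCalibration:
    """Exponential decay of mean cross-well onset delay with axon count.

    ``mu(n) = floor_ms + span_ms * exp(-(n - knee_axons) / tau_axons)`` for
    ``n >= knee_axons``, clamped to ``floor_ms + span_ms`` below the knee.
    The default pins 300 ms at 20 axons and ~90 ms at 510 axons; the shape
    between the two printed bounds is a modelling choice.
    """

    floor_ms: float = 90.0
    span_ms: float = 210.0
    knee_axons: float = 20.0
    tau_axons: float = 60.0

    def __call__(self, n_axons: float) -> float:
        if n_axons < 1:
            raise ValueError("delay is undefined below one axon")
        n = max(float(n_axons), self.knee_axons)
        return self.floor_ms + self.span_ms * math.exp(-(n - self.knee_axons) / self.tau_axons)


DEFAULT_DELAY_CALIBRATION = DelayCalibration()


def transmission_probability(n_axons: float,
                             curve: CalibrationCurve = DEFAULT_SUCCESS_CURVE) -> float:
    """Probability that a source-well burst initiates a burst across the tunnels."""
    if n_axons < 0:
        raise ValueError("axon count must be non-negative")
    return curve(n_axons)


def mean_transmission_delay(n_axons: float,
                            calibration: DelayCalibration = DEFAULT_DELAY_CALIBRATION,
                            ) -> float:
    """Mean burst-onset delay (ms) between wells for a given axon count."""
    return calibration(n_axons)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated session.

    Defaults reproduce the recorded protocol: 60 probe stimuli repeated every
    10 s, ~1.3 Hz baseline firing, ~1.2 spontaneous network bursts per minute
    per well, 10 axons per tunnel, and feed-forward plating from Well A.
    """

    n_tunnels: int = 5
    axons_per_tunnel: int = 10
    baseline_rate: float = 1.3            # spikes/s per electrode
    spontaneous_burst_rate: float = 1.2   # bursts/min per well
    burst_peak_rate: float = 50.0         # spikes/s per electrode at envelope peak
    burst_rise_tau: float = 30.0          # ms, alpha-function time constant
    burst_max_duration: float = 300.0     # ms, envelope truncation
    n_stimuli: int = 60
    stimulus_interval: float = 10.0       # s
    evoked_latency_mean: float = 10.0     # ms, stimulus -> source-burst onset
    evoked_latency_sd: float = 3.0        # ms
    axonal_delay_range: tuple[float, float] = (0.4, 2.2)  # ms over the 400 um tunnel
    delay_jitter_sd: float = 30.0         # ms, SD of cross-well onset delay
    relay_per_axon: float = 0.02          # relayed fraction of burst spikes per local axon
    reverse_coupling_factor: float = 0.1  # residual coupling against the plating direction
    session_padding: float = 10.0         # s
    source_well: str = REGION_A           # plating direction: bursts evoked here
    seed: int = 0
    success_curve: CalibrationCurve = DEFAULT_SUCCESS_CURVE
    delay_calibration: DelayCalibration = DEFAULT_DELAY_CALIBRATION

    def __post_init__(self):
        if self.n_tunnels < 0:
            raise ValueError("n_tunnels must be >= 0")
        if self.axons_per_tunnel < 0:
            raise ValueError("axons_per_tunnel must be >= 0")
        for name in ("baseline_rate", "burst_peak_rate", "burst_rise_tau",
                     "burst_max_duration", "stimulus_interval", "evoked_latency_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.spontaneous_burst_rate < 0:
            raise ValueError("spontaneous_burst_rate must be >= 0")
        if not 0.0 <= self.reverse_coupling_factor <= 1.0:
            raise ValueError("reverse_coupling_factor must lie in [0, 1]")
        if self.n_stimuli < 0:
            raise ValueError("n_stimuli must be >= 0")
        if self.session_padding < 0:
            raise ValueError("session_padding must be >= 0")
        lo, hi = self.axonal_delay_range
        if not (0 < lo <= hi):
            raise ValueError("axonal_delay_range must be positive and ordered")
        if self.source_well not in (REGION_A, REGION_B):
            raise ValueError("source_well must be 'A' or 'B'")
        if self.n_stimuli > 0 and self.duration < self.n_stimuli * self.stimulus_interval:
            raise ValueError("session too short for the stimulation protocol")

    @property
    def n_axons(self) -> int:
        return self.n_tunnels * self.axons_per_tunnel

    @property
    def target_well(self) -> str:
        return REGION_B if self.source_well == REGION_A else REGION_A

    @property
    def duration(self) -> float:
        return self.n_stimuli * self.stimulus_interval + self.session_padding


@dataclass(frozen=True)
class BurstRecord:
    """Ground-truth burst envelope: which well, onset (s), and provenance."""

    well: str
    onset: float
    kind: str            # "evoked" | "spontaneous" | "transmitted"
    stimulus_index: int = -1


@dataclass(frozen=True)
class StimulusRecord:
    """Ground truth for one probe stimulus."""

    index: int
    time: float
    source_onset: float
    transmitted: bool
    target_onset: float | None


@dataclass(frozen=True)
class GroundTruth:
    """Everything the simulator knows that the pipeline must recover."""

    stimuli: tuple[StimulusRecord, ...]
    bursts: tuple[BurstRecord, ...]
    n_axons: int
    source_well: str
    target_well: str

    @property
    def n_transmitted(self) -> int:
        return sum(s.transmitted for s in self.stimuli)


# tunnel columns are filled from the device centre outward
_COLUMN_FILL_ORDER = (4, 5, 3, 6, 2, 7, 1, 8)


def _tunnel_axons_per_column(n_tunnels: int, axons_per_tunnel: int) -> dict[int, int]:
    counts: dict[int, int] = {}
    for t in range(n_tunnels):
        col = _COLUMN_FILL_ORDER[t % len(_COLUMN_FILL_ORDER)]
        counts[col] = counts.get(col, 0) + axons_per_tunnel
    return counts


def _alpha_burst_spikes(rng: np.random.Generator, n_electrodes: int,
                        peak_rate: float, tau_s: float, max_dur_s: float,
                        ) -> list[np.ndarray]:
    """Per-electrode spike offsets (s from onset) under the alpha envelope.

    The envelope ``r(t) = R (t/tau) exp(1 - t/tau)`` integrates to
    ``R e tau`` over an unbounded window; offsets follow a Gamma(2, tau)
    density truncated at the maximum burst duration.
    """
    total_mass = peak_rate * math.e * tau_s * (
        1.0 - (1.0 + max_dur_s / tau_s) * math.exp(-max_dur_s / tau_s))
    counts = rng.poisson(total_mass, size=n_electrodes)
    out = []
    for c in counts:
        t = rng.gamma(2.0, tau_s, size=c)
        # redraw the rare offsets beyond the truncation point
        bad = t > max_dur_s
        while np.any(bad):
            t[bad] = rng.gamma(2.0, tau_s, size=int(bad.sum()))
            bad = t > max_dur_s
        out.append(np.sort(t))
    return out


def simulate_session(config: SimConfig,
                     layout: ElectrodeLayout | None = None,
                     ) -> tuple[SpikeData, StimulusLog, GroundTruth]:
    """Simulate one stimulation session; deterministic given (config, seed)."""
    layout = layout or default_layout()
    ss = np.random.SeedSequence(config.seed)
    rng_events, rng_spikes, rng_relay, rng_base = (
        np.random.default_rng(c) for c in ss.spawn(4))

    duration = config.duration
    src, tgt = config.source_well, config.target_well
    well_ids = {w: layout.region_ids(w, include_excluded=True) for w in (src, tgt)}
    p_fwd = transmission_probability(config.n_axons, config.success_curve)
    mu_delay_s = (mean_transmission_delay(config.n_axons, config.delay_calibration) / 1e3
                  if config.n_axons >= 1 else None)
    jitter_s = config.delay_jitter_sd / 1e3

    stim_times = config.session_padding / 2.0 + np.arange(config.n_stimuli) * config.stimulus_interval
    stim_electrode = (DEFAULT_STIM_ELECTRODE if src == REGION_A
                      else DEFAULT_STIM_ELECTRODE_REVERSE)

    def draw_delay() -> float:
        d = rng_events.normal(mu_delay_s, jitter_s)
        while d <= 0:
            d = rng_events.normal(mu_delay_s, jitter_s)
        return d

    bursts: list[BurstRecord] = []
    stim_records: list[StimulusRecord] = []

    # --- burst timetable -------------------------------------------------
    for i, t in enumerate(stim_times):
        lat = rng_events.normal(config.evoked_latency_mean, config.evoked_latency_sd) / 1e3
        onset = t + max(lat, 1e-3)
        bursts.append(BurstRecord(src, onset, "evoked", i))
        transmitted = config.n_axons >= 1 and rng_events.random() < p_fwd
        t_onset = None
        if transmitted:
            t_onset = onset + draw_delay()
            if t_onset < duration:
                bursts.append(BurstRecord(tgt, t_onset, "transmitted", i))
            else:
                transmitted, t_onset = False, None
        stim_records.append(StimulusRecord(i, float(t), onset, transmitted, t_onset))

    spont_rate_hz = config.spontaneous_burst_rate / 60.0
    for well in (src, tgt):
        n_spont = rng_events.poisson(spont_rate_hz * duration)
        for onset in np.sort(rng_events.uniform(0, duration, size=n_spont)):
            bursts.append(BurstRecord(well, float(onset), "spontaneous"))
            # single-hop cross-well transmission of spontaneous bursts
            p = p_fwd if well == src else p_fwd * config.reverse_coupling_factor
            if config.n_axons >= 1 and rng_events.random() < p:
                other = tgt if well == src else src
                t_onset = onset + draw_delay()
                if t_onset < duration:
                    bursts.append(BurstRecord(other, float(t_onset), "transmitted"))
    bursts.sort(key=lambda b: b.onset)

    # --- envelope spikes -------------------------------------------------
    tau_s = config.burst_rise_tau / 1e3
    max_dur_s = config.burst_max_duration / 1e3
    per_elec: dict[str, list[np.ndarray]] = {eid: [] for eid in layout.ids}
    burst_spike_pool: dict[int, np.ndarray] = {}   # burst idx -> pooled well spike times
    for bi, b in enumerate(bursts):
        ids = well_ids[b.well]
        offs = _alpha_burst_spikes(rng_spikes, len(ids), config.burst_peak_rate,
                                   tau_s, max_dur_s)
        pooled = []
        for eid, o in zip(ids, offs):
            times = b.onset + o
            per_elec[eid].append(times)
            pooled.append(times)
        burst_spike_pool[bi] = np.sort(np.concatenate(pooled)) if pooled else np.empty(0)

    # --- tunnel relay copies --------------------------------------------
    axons_per_col = _tunnel_axons_per_column(config.n_tunnels, config.axons_per_tunnel)
    lo_ms, hi_ms = config.axonal_delay_range
    # per column: conduction delay of each forward and each reverse axon (s)
    fwd_axon_delay = {c: rng_relay.uniform(lo_ms, hi_ms, size=m) / 1e3
                      for c, m in axons_per_col.items()}
    rev_axon_delay = {c: rng_relay.uniform(lo_ms, hi_ms, size=max(1, m)) / 1e3
                      for c, m in axons_per_col.items()}
    # tunnel rows ordered from Well A side to Well B side
    near_row, far_row = (4, 5) if src == REGION_A else (5, 4)
    for bi, b in enumerate(bursts):
        if b.kind == "transmitted" and b.well == tgt:
            continue  # already relayed when its source burst was processed
        forward = b.well == src
        pool = burst_spike_pool[bi]
        if pool.size == 0:
            continue
        for col, m in axons_per_col.items():
            m_eff = m if forward else m * config.reverse_coupling_factor
            p_relay = min(1.0, config.relay_per_axon * m_eff)
            if p_relay <= 0:
                continue
            sel = pool[rng_relay.random(pool.size) < p_relay]
            if sel.size == 0:
                continue
            delays = fwd_axon_delay[col] if forward else rev_axon_delay[col]
            d_total = delays[rng_relay.integers(0, delays.size, size=sel.size)]
            n_row, f_row = (near_row, far_row) if forward else (far_row, near_row)
            for row, frac in ((n_row, 1.0 / 3.0), (f_row, 2.0 / 3.0)):
                eid = electrode_id(col, row)
                if eid in layout:
                    per_elec[eid].append(sel + frac * d_total)

    # --- Poisson baseline ------------------------------------------------
    for eid in layout.ids:
        n = rng_base.poisson(config.baseline_rate * duration)
        per_elec[eid].append(rng_base.uniform(0, duration, size=n))

    trains = {}
    for eid, parts in per_elec.items():
        t = np.concatenate(parts) if parts else np.empty(0)
        t = np.unique(t[(t >= 0) & (t < duration)])
        trains[eid] = t

    spikes = SpikeData(trains=trains, duration=duration, layout=layout)
    stim = StimulusLog(times=stim_times, electrode=stim_electrode,
                       max_stimuli=max(config.n_stimuli, 1))
    truth = GroundTruth(stimuli=tuple(stim_records), bursts=tuple(bursts),
                        n_axons=config.n_axons, source_well=src, target_well=tgt)
    return spikes, stim, truth


# ---------------------------------------------------------------------------
# raw-trace rendering
# ---------------------------------------------------------------------------

def _biphasic_template(sampling_hz: float, amplitude: float) -> np.ndarray:
    """Negative-leading biphasic extracellular spike, ~1 ms long.

    Difference of two Gaussian lobes; the trough reaches ``-amplitude``.
    """
    t = np.arange(int(round(1.0e-3 * sampling_hz))) / sampling_hz
    neg = np.exp(-0.5 * ((t - 0.25e-3) / 0.08e-3) ** 2)
    pos = 0.45 * np.exp(-0.5 * ((t - 0.55e-3) / 0.14e-3) ** 2)
    w = -neg + pos
    return amplitude * w / np.abs(w.min())


def render_raw_trace(spikes: SpikeData,
                     stim: StimulusLog | None = None,
                     noise_sd: float = 4.0,
                     waveform: str = "biphasic",
                     artifact_amplitude: float = 0.0,
                     spike_amplitude: float | None = None,
                     sampling_hz: float = DEFAULT_SAMPLING_HZ,
                     artifact_tau_ms: float = 5.0,
                     seed: int = 0) -> RawRecording:
    """Render 25 kHz voltage traces from spike times (noise + templates + artifacts).

    Only electrodes present in ``spikes.trains`` are rendered.  Overlapping
    spikes superpose linearly.  The stimulus artifact is a large decaying
    exponential added to every rendered electrode.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if waveform != "biphasic":
        raise ValueError(f"unknown waveform template {waveform!r}")
    amp = 8.0 * noise_sd if spike_amplitude is None else spike_amplitude
    if amp < 6.0 * noise_sd:
        raise ValueError("spike amplitude below 6x noise SD: detection ill-posed")

    n = int(round(spikes.duration * sampling_hz))
    template = _biphasic_template(sampling_hz, amp)
    trough_offset = int(np.argmin(template))  # spike timestamps mark the trough
    artifact = None
    if artifact_amplitude and stim is not None and len(stim):
        ta = np.arange(int(round(10 * artifact_tau_ms * 1e-3 * sampling_hz))) / sampling_hz
        artifact = artifact_amplitude * np.exp(-ta / (artifact_tau_ms * 1e-3))

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    traces = {}
    for eid, train in spikes.trains.items():
        x = rng.normal(0.0, noise_sd, size=n)
        for t in train:
            i0 = int(round(t * sampling_hz)) - trough_offset
            tpl = template[max(0, -i0):]
            i0 = max(i0, 0)
            seg = tpl[: max(0, min(len(tpl), n - i0))]
            x[i0:i0 + len(seg)] += seg
        if artifact is not None:
            for t in stim.times:
                i0 = int(round(t * sampling_hz))
                seg = artifact[: max(0, min(len(artifact), n - i0))]
                x[i0:i0 + len(seg)] += seg
        traces[eid] = x
    return RawRecording(traces=traces, sampling_hz=sampling_hz, layout=spikes.layout)
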