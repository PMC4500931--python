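"""Summex-style network-burst detection and basic activity statistics.

Each electrode is scanned for *burstlets*: runs of at least four spikes whose
interspike intervals stay below a per-electrode threshold set to 25% of the
inverse of that electrode's mean firing rate.  Burstlets from the electrodes
of one region that overlap in time (transitively) are merged into network
bursts; bursts shorter than 10 ms are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import SpikeData

__all__ = [
    "Burstlet",
    "BurstEvent",
    "isi_threshold",
    "detect_burstlets",
    "merge_network_bursts",
    "detect_network_bursts",
    "activity_summary",
]

MIN_SPIKES_DEFAULT = 4
ISI_FRACTION_DEFAULT = 0.25
MIN_BURST_DURATION_S = 0.010


@dataclass(frozen=True)
class Burstlet:
    electrode: str
    start: float
    end: float
    n_spikes: int


@dataclass(frozen=True)
class BurstEvent:
    region: str
    start: float
    end: float
    burstlets: tuple[Burstlet, ...]

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def n_electrodes(self) -> int:
        return len({b.electrode for b in self.burstlets})

    @property
    def n_spikes(self) -> int:
        return sum(b.n_spikes for b in self.burstlets)

    def core_start(self, min_electrodes: int = 1) -> float | None:
        """Earliest time at which ``min_electrodes`` electrodes burst at once.

        Single-electrode burstlets can reach back before the network event
        proper when chance baseline spikes fall within the ISI threshold of
        the first burst spikes; the core onset marks where the main body of
        the burst begins instead.  Returns None when the event never has
        that many electrodes simultaneously active.
        """
        if min_electrodes <= 1:
            return self.start
        marks = []  # (time, +1/-1, electrode)
        for b in self.burstlets:
            marks.append((b.start, 1, b.electrode))
            marks.append((b.end, -1, b.electrode))
        marks.sort(key=lambda m: (m[0], -m[1]))
        active: dict[str, int] = {}
        for t, delta, eid in marks:
            active[eid] = active.get(eid, 0) + delta
            if delta > 0 and sum(v > 0 for v in active.values()) >= min_electrodes:
                return t
        return None


def isi_threshold(train: np.ndarray, duration: float,
                  frac: float = ISI_FRACTION_DEFAULT) -> float | None:
    """Burstlet ISI threshold: ``frac`` x the electrode's inverse mean rate.

    Returns None for a silent electrode (excluded from the burstlet search).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(np.asarray(train).size)
    if n == 0:
        return None
    return frac * duration / n


def detect_burstlets(train: np.ndarray, threshold: float,
                     min_spikes: int = MIN_SPIKES_DEFAULT,
                     electrode: str = "") -> list[Burstlet]:
    """Maximal runs of >= ``min_spikes`` spikes with all ISIs below threshold."""
    if threshold <= 0:
        raise ValueError("ISI threshold must be positive")
    t = np.asarray(train, dtype=np.float64)
    if t.size < min_spikes:
        return []
    ok = np.diff(t) < threshold
    out = []
    i = 0
    m = ok.size
    while i < m:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j < m and ok[j]:
            j += 1
        n = j - i + 1  # spikes spanned by the run of short ISIs
        if n >= min_spikes:
            out.append(Burstlet(electrode, float(t[i]), float(t[j]), n))
        i = j
    return out


def merge_network_bursts(burstlets: list[Burstlet],
                         region: str = "",
                         min_duration: float = MIN_BURST_DURATION_S,
                         ) -> list[BurstEvent]:
    """Connected components of the closed-interval overlap graph over burstlets.

    Interval graphs make transitive closure a single start-ordered sweep.
    Components spanning less than ``min_duration`` are discarded.
    """
    if not burstlets:
        return []
    bl = sorted(burstlets, key=lambda b: (b.start, b.end))
    events: list[BurstEvent] = []
    members = [bl[0]]
    end = bl[0].end
    for b in bl[1:]:
        if b.start <= end:
            members.append(b)
            end = max(end, b.end)
        else:
            events.append(_make_event(region, members))
            members = [b]
            end = b.end
    events.append(_make_event(region, members))
    return [e for e in events if e.duration >= min_duration]


def _make_event(region: str, members: list[Burstlet]) -> BurstEvent:
    return BurstEvent(region=region,
                      start=min(b.start for b in members),
                      end=max(b.end for b in members),
                      burstlets=tuple(members))


def detect_network_bursts(spikes: SpikeData, region: str,
                          frac: float = ISI_FRACTION_DEFAULT,
                          min_spikes: int = MIN_SPIKES_DEFAULT,
                          min_duration: float = MIN_BURST_DURATION_S,
                          ) -> list[BurstEvent]:
    """Per-electrode burstlet search followed by network-burst merging."""
    burstlets: list[Burstlet] = []
    for eid in spikes.active_ids(region):
        train = spikes.train(eid)
        thr = isi_threshold(train, spikes.duration, frac)
        if thr is None:
            continue
        burstlets.extend(detect_burstlets(train, thr, min_spikes, electrode=eid))
    return merge_network_bursts(burstlets, region=region, min_duration=min_duration)


def activity_summary(spikes: SpikeData,
                     bursts_by_region: dict[str, list[BurstEvent]] | None = None,
                     confidence: float = 0.95) -> dict:
    """Mean firing rate across electrodes and per-region burst rates.

    The mean rate averages ``spike_count / duration`` over the recorded,
    non-excluded electrodes (electrodes with a spike-train entry, silent or
    not); the confidence interval is a t-interval over electrodes.  Burst
    rates are per minute.
    """
    ids = [eid for eid in spikes.trains if eid not in spikes.excluded]
    rates = np.array([spikes.rate(eid) for eid in ids])
    summary: dict = {"n_electrodes": len(ids), "duration_s": spikes.duration}
    if rates.size == 0 or spikes.n_spikes() == 0:
        summary.update(mean_rate_hz=0.0, rate_ci_hz=(0.0, 0.0), empty=True)
    else:
        mean = float(rates.mean())
        if rates.size > 1 and rates.std(ddof=1) > 0:
            lo, hi = stats.t.interval(confidence, rates.size - 1, loc=mean,
                                      scale=stats.sem(rates))
        else:
            lo = hi = mean
        summary.update(mean_rate_hz=mean, rate_ci_hz=(float(lo), float(hi)), empty=False)
    burst_rates = {}
    for region, events in (bursts_by_region or {}).items():
        burst_rates[region] = 60.0 * len(events) / spikes.duration
    summary["burst_rate_per_min"] = burst_rates
    return summary
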