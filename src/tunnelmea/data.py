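"""Core in-memory containers: spike trains, stimulus logs, raw voltage traces.

Times are seconds (float64) throughout; report-facing code converts to
milliseconds at the edge.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .layout import ElectrodeLayout, default_layout

DEFAULT_SAMPLING_HZ = 25_000.0
MAX_STIMULI_DEFAULT = 60


@dataclass
class SpikeData:
    """Per-electrode sorted spike timestamps over one recording.

    ``trains`` maps electrode id to a strictly increasing float64 array of
    spike times in seconds within ``[0, duration)``.  ``excluded`` ids are
    retained in the container but skipped by analysis stages (stimulated or
    otherwise rejected channels).
    """

    trains: dict[str, np.ndarray]
    duration: float
    layout: ElectrodeLayout = field(default_factory=default_layout)
    excluded: frozenset = frozenset()

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        self.excluded = frozenset(self.excluded)
        clean = {}
        for eid, t in self.trains.items():
            if eid not in self.layout:
                raise KeyError(f"electrode {eid!r} not in layout")
            t = np.asarray(t, dtype=np.float64)
            if t.ndim != 1:
                raise ValueError(f"electrode {eid!r}: spike times must be 1-D")
            if t.size and (t[0] < 0 or t[-1] >= self.duration):
                raise ValueError(
                    f"electrode {eid!r}: spike times outside [0, {self.duration})")
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise ValueError(f"electrode {eid!r}: spike times not strictly increasing")
            clean[eid] = t
        self.trains = clean

    def train(self, eid: str) -> np.ndarray:
        return self.trains.get(eid, np.empty(0))

    def n_spikes(self, eid: str | None = None) -> int:
        if eid is not None:
            return int(self.train(eid).size)
        return int(sum(t.size for t in self.trains.values()))

    def rate(self, eid: str) -> float:
        """Mean firing rate of one electrode over the whole recording (Hz)."""
        return self.train(eid).size / self.duration

    def active_ids(self, region: str | None = None) -> tuple[str, ...]:
        """Non-excluded electrode ids, optionally restricted to one region."""
        ids = self.layout.ids if region is None else self.layout.region_ids(region)
        return tuple(i for i in ids if i not in self.excluded)

    def with_excluded(self, ids) -> "SpikeData":
        return dataclasses.replace(self, excluded=self.excluded | frozenset(ids))


@dataclass
class StimulusLog:
    """Times and site of the biphasic probe stimuli (+-800 mV, 200 us/phase)."""

    times: np.ndarray
    electrode: str
    amplitude_mv: float = 800.0
    phase_us: float = 200.0
    max_stimuli: int = MAX_STIMULI_DEFAULT

    def __post_init__(self):
        t = np.asarray(self.times, dtype=np.float64)
        if t.ndim != 1:
            raise ValueError("stimulus times must be 1-D")
        if t.size > 1:
            isi = np.diff(t)
            if not np.all(isi > 0):
                raise ValueError("stimulus times must be strictly increasing")
            if np.any(isi < 1.0):
                raise ValueError("inter-stimulus interval must be at least 1 s")
        if t.size > self.max_stimuli:
            raise ValueError(
                f"{t.size} stimuli exceed the configured maximum {self.max_stimuli}")
        self.times = t

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class RawRecording:
    """Uniformly sampled extracellular voltage traces (microvolts)."""

    traces: dict[str, np.ndarray]
    sampling_hz: float = DEFAULT_SAMPLING_HZ
    start: float = 0.0
    layout: ElectrodeLayout = field(default_factory=default_layout)
    excluded: frozenset = frozenset()

    def __post_init__(self):
        if self.sampling_hz <= 0:
            raise ValueError("sampling rate must be positive")
        self.excluded = frozenset(self.excluded)
        lengths = {len(v) for v in self.traces.values()}
        if len(lengths) > 1:
            raise ValueError("all electrode traces must have equal length")
        self.traces = {k: np.asarray(v, dtype=np.float64) for k, v in self.traces.items()}

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.traces.values()))) if self.traces else 0

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_hz

    def with_excluded(self, ids) -> "RawRecording":
        return dataclasses.replace(self, excluded=self.excluded | frozenset(ids))
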