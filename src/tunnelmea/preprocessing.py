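"""Raw-trace conditioning: noise estimation, spike detection, artifact removal.

Spikes are detected as negative threshold crossings at ``k`` times a robust
estimate of the background-noise standard deviation (default k = 5), with the
timestamp placed at the local voltage trough.  Stimulus windows are blanked
for 5 ms and the following transient suppressed by subtracting a locally
fitted low-order polynomial.
"""

from __future__ import annotations

import warnings


import numpy as np

from .data import RawRecording, SpikeData, StimulusLog

__all__ = [
    "estimate_noise_sd",
    "detect_spikes",
    "remove_stimulus_artifact",
]

_MAD_TO_SD = 0.6744897501960817  # Phi^-1(0.75): MAD of a Gaussian in SD units


def estimate_noise_sd(trace: np.ndarray,
                      sampling_hz: float = 25_000.0,
                      window_ms: float = 100.0,
                      quiescence_rule: str = "median-peak") -> float:
    """Robust background-noise SD from the quiet half of the recording.

    The trace is cut into windows; windows whose peak absolute amplitude is
    at or below the 50th percentile of window peaks are pooled and the SD
    estimated as MAD / 0.6745.  Returns 0.0 (with a warning) for a constant
    trace.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if trace.size < sampling_hz:
        raise ValueError("need at least 1 s of samples to estimate noise")
    if quiescence_rule != "median-peak":
        raise ValueError(f"unknown quiescence rule {quiescence_rule!r}")
    w = max(1, int(round(window_ms * 1e-3 * sampling_hz)))
    n_win = trace.size // w
    chunks = trace[: n_win * w].reshape(n_win, w)
    peaks = np.abs(chunks).max(axis=1)
    quiet = chunks[peaks <= np.percentile(peaks, 50)]
    if quiet.size == 0:
        quiet = chunks
    x = quiet.ravel()
    sd = float(np.median(np.abs(x - np.median(x))) / _MAD_TO_SD)
    if sd == 0.0:
        warnings.warn("degenerate trace: background noise SD is zero")
    return sd


def _detect_one(trace: np.ndarray, threshold: float, sampling_hz: float,
                dead_time_s: float, trough_window_s: float) -> np.ndarray:
    """Indices -> times of negative crossings of ``-threshold``; trough-aligned."""
    below = trace < -threshold
    crossings = np.flatnonzero(below[1:] & ~below[:-1]) + 1
    if crossings.size == 0:
        return np.empty(0)
    w = max(1, int(round(trough_window_s * sampling_hz)))
    dead = dead_time_s
    times = []
    last = -np.inf
    for i in crossings:
        t_cross = i / sampling_hz
        if t_cross - last < dead:
            continue
        seg = trace[i: i + w]
        t_spike = (i + int(np.argmin(seg))) / sampling_hz
        times.append(t_spike)
        last = t_cross
    return np.asarray(times)


def detect_spikes(rec: RawRecording,
                  k: float = 5.0,
                  dead_time_ms: float = 1.0,
                  trough_window_ms: float = 1.0,
                  noise_sd: dict[str, float] | None = None) -> SpikeData:
    """Threshold spike detection at ``-k * SD`` per electrode.

    ``noise_sd`` may supply per-electrode SDs (e.g. from a separate quiet
    recording); otherwise :func:`estimate_noise_sd` is applied per trace.
    Electrodes with zero SD are excluded with a warning.
    """
    if k <= 0:
        raise ValueError("threshold multiplier k must be positive")
    trains: dict[str, np.ndarray] = {}
    excluded = set(rec.excluded)
    for eid, trace in rec.traces.items():
        sd = (noise_sd or {}).get(eid)
        if sd is None:
            sd = estimate_noise_sd(trace, rec.sampling_hz)
        if sd <= 0:
            warnings.warn(f"electrode {eid}: zero noise SD, excluded from detection")
            excluded.add(eid)
            continue
        t = _detect_one(trace, k * sd, rec.sampling_hz,
                        dead_time_ms * 1e-3, trough_window_ms * 1e-3)
        # trough alignment can reorder or duplicate near-simultaneous events
        trains[eid] = np.unique(t[t < rec.duration])
    return SpikeData(trains=trains, duration=rec.duration, layout=rec.layout,
                     excluded=frozenset(excluded))


def remove_stimulus_artifact(rec: RawRecording,
                             stim: StimulusLog,
                             blank_ms: float = 5.0,
                             fit_window_ms: float = 20.0,
                             max_degree: int = 3) -> RawRecording:
    """Blank stimulus windows and subtract a local polynomial fit of the tail.

    Samples within ``blank_ms`` of each stimulus are replaced by the local
    pre-stimulus baseline (median of the preceding 10 ms); the next
    ``fit_window_ms`` are replaced by the residual after subtracting a
    least-squares polynomial of degree ``<= max_degree``.  The stimulated
    electrode is flagged excluded.  Samples outside the treated windows are
    never altered.
    """
    if np.any(stim.times < 0) or np.any(stim.times > rec.duration):
        raise ValueError("stimulus times fall outside the recording")
    fs = rec.sampling_hz
    nb = int(round(blank_ms * 1e-3 * fs))
    nf = int(round(fit_window_ms * 1e-3 * fs))
    n = rec.n_samples

    windows = []
    for t in stim.times:
        i0 = int(round(t * fs))
        win = (i0, min(i0 + nb, n), min(i0 + nb + nf, n))
        if windows and win[0] < windows[-1][2]:
            warnings.warn("overlapping stimulus windows merged")
            p0, _, _ = windows.pop()
            win = (p0, win[1], win[2])
        windows.append(win)

    traces = {}
    for eid, x in rec.traces.items():
        y = x.copy()
        for i0, i1, i2 in windows:
            base = np.median(y[max(0, i0 - int(0.010 * fs)): i0]) if i0 > 0 else 0.0
            y[i0:i1] = base
            if i2 > i1:
                seg = x[i1:i2]
                u = np.linspace(-1.0, 1.0, seg.size)
                deg = min(max_degree, seg.size - 1)
                coef = np.polynomial.polynomial.polyfit(u, seg, deg)
                y[i1:i2] = seg - np.polynomial.polynomial.polyval(u, coef)
        traces[eid] = y
    out = RawRecording(traces=traces, sampling_hz=fs, start=rec.start,
                       layout=rec.layout, excluded=rec.excluded)
    if stim.electrode in rec.traces or stim.electrode in rec.layout:
        out = out.with_excluded([stim.electrode])
    return out
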