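"""Conditional Granger causality on exponentially smoothed spike trains.

Spike trains from the post-stimulus windows are binned at 1 ms, smoothed
with a causal exponential kernel (tau = 4 ms), and fitted to a multivariate
autoregressive model of order 10, pooling lagged covariance across trials
without crossing trial boundaries.  The conditional Granger causality from
source i to target j is the log ratio of residual variances between the
model omitting i's lags and the full model; significance comes from the
F-test that the lag coefficients from i to j are jointly zero, corrected
across all ordered pairs by Benjamini-Hochberg FDR at q = 0.001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .data import SpikeData, StimulusLog
from .layout import ElectrodeLayout, REGION_A, REGION_B, REGION_TUNNEL

__all__ = [
    "SmoothedActivity",
    "MVARModel",
    "CGCResult",
    "smooth_trains",
    "fit_mvar",
    "conditional_gc",
    "cgc_matrix",
    "fdr_mask",
    "connection_summaries",
    "export_graph",
    "select_order",
]

BIN_S_DEFAULT = 0.001
TAU_S_DEFAULT = 0.004
WINDOW_S_DEFAULT = 0.500
MIN_RATE_HZ_DEFAULT = 0.5
ORDER_DEFAULT = 10
FDR_Q_DEFAULT = 0.001


@dataclass
class SmoothedActivity:
    """Continuous activity: (n_trials, n_bins, n_channels), 1 ms steps."""

    channels: tuple[str, ...]
    data: np.ndarray
    bin_s: float = BIN_S_DEFAULT
    tau_s: float = TAU_S_DEFAULT

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def index(self, eid: str) -> int:
        return self.channels.index(eid)


def smooth_trains(spikes: SpikeData,
                  stim: StimulusLog,
                  window: float = WINDOW_S_DEFAULT,
                  bin_s: float = BIN_S_DEFAULT,
                  tau: float = TAU_S_DEFAULT,
                  min_rate_hz: float = MIN_RATE_HZ_DEFAULT,
                  channels: tuple[str, ...] | None = None) -> SmoothedActivity:
    """Binary 1 ms bins per trial convolved with a causal exp(-t/tau) kernel.

    Only electrodes whose overall firing rate exceeds ``min_rate_hz`` (and
    that are not excluded or stimulated) enter; the kernel is truncated at
    10 tau and never smooths across trial boundaries.
    """
    if channels is None:
        channels = tuple(
            eid for eid in spikes.active_ids()
            if eid != stim.electrode and spikes.rate(eid) > min_rate_hz)
    else:
        channels = tuple(channels)
    if not channels:
        raise ValueError("no electrodes pass the rate filter")
    n_bins = int(round(window / bin_s))
    kernel = np.exp(-np.arange(int(round(10 * tau / bin_s))) * bin_s / tau)
    stim_times = [t for t in stim.times if t + window <= spikes.duration]
    data = np.zeros((len(stim_times), n_bins, len(channels)))
    edges = np.arange(n_bins + 1) * bin_s
    for ti, t0 in enumerate(stim_times):
        for ci, eid in enumerate(channels):
            tr = spikes.train(eid)
            rel = tr[(tr >= t0) & (tr < t0 + window)] - t0
            binary = np.minimum(np.histogram(rel, bins=edges)[0], 1).astype(float)
            data[ti, :, ci] = np.convolve(binary, kernel)[:n_bins]
    return SmoothedActivity(channels=channels, data=data, bin_s=bin_s, tau_s=tau)


def _design(data: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Pooled (Z, Y) regression matrices; per-trial, per-channel mean centring.

    Z columns are ordered lag-major: column ``(l-1)*k + c`` holds channel c
    at lag l.  Rows never span a trial boundary.
    """
    n_trials, n_bins, k = data.shape
    if n_bins <= p:
        raise ValueError(f"trial segments of {n_bins} samples cannot support order {p}")
    ys, zs = [], []
    for tr in range(n_trials):
        d = data[tr] - data[tr].mean(axis=0, keepdims=True)
        ys.append(d[p:])
        zs.append(np.concatenate([d[p - l: n_bins - l] for l in range(1, p + 1)], axis=1))
    return np.vstack(zs), np.vstack(ys)


@dataclass
class MVARModel:
    """Least-squares multivariate autoregressive fit."""

    channels: tuple[str, ...]
    order: int
    coefs: np.ndarray          # (order, n_channels target, n_channels source)
    resid_var: np.ndarray      # per-target residual variance (ML, RSS/N)
    n_obs: int
    n_trials: int


def fit_mvar(X: SmoothedActivity,
             channels: tuple[str, ...] | None = None,
             p: int = ORDER_DEFAULT) -> MVARModel:
    """Fit a VAR(p) by pooled least squares across trials."""
    idx = ([X.index(c) for c in channels] if channels is not None
           else list(range(len(X.channels))))
    names = tuple(X.channels[i] for i in idx)
    data = X.data[:, :, idx]
    Z, Y = _design(data, p)
    k = len(idx)
    if Z.shape[0] < 10 * Z.shape[1]:
        warnings.warn(
            f"only {Z.shape[0]} pooled samples for {Z.shape[1]} parameters per target")
    G = Z.T @ Z
    try:
        B = np.linalg.solve(G, Z.T @ Y)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "rank-deficient regressor matrix; collinear channels among "
            f"{_collinear_channels(Z, names, p)}")
    resid = Y - Z @ B
    coefs = B.reshape(p, k, k).transpose(0, 2, 1)  # (lag, target, source)
    return MVARModel(channels=names, order=p, coefs=coefs,
                     resid_var=(resid ** 2).mean(axis=0),
                     n_obs=Z.shape[0], n_trials=data.shape[0])


def _collinear_channels(Z: np.ndarray, names: tuple[str, ...], p: int) -> list[str]:
    # report channels whose lag blocks do not add rank
    bad = []
    for ci, name in enumerate(names):
        cols = [l * len(names) + ci for l in range(p)]
        block = Z[:, cols]
        if np.linalg.matrix_rank(block) < len(cols):
            bad.append(name)
    return bad or list(names)


def _fit_rss(Z: np.ndarray, y: np.ndarray) -> float:
    b, *_ = np.linalg.lstsq(Z, y, rcond=None)
    return float(((y - Z @ b) ** 2).sum())


def conditional_gc(X: SmoothedActivity, source: str, target: str,
                   p: int = ORDER_DEFAULT,
                   conditioning: tuple[str, ...] | None = None,
                   ) -> tuple[float, float]:
    """CGC from ``source`` to ``target`` conditioned on all other channels.

    Fits the restricted model (target from everyone's past except the
    source) and the full model (adds the source's past); returns
    ``(ln(rss_restricted / rss_full), F-test p-value)``.  Numerically
    negative values are clipped to zero.
    """
    if source == target:
        raise ValueError("source and target must differ")
    chans = conditioning if conditioning is not None else X.channels
    chans = tuple(dict.fromkeys(list(chans) + [source, target]))
    idx = [X.index(c) for c in chans]
    data = X.data[:, :, idx]
    Z, Y = _design(data, p)
    k = len(chans)
    j = chans.index(target)
    i = chans.index(source)
    y = Y[:, j]
    keep = [l * k + c for l in range(p) for c in range(k) if c != i]
    rss_full = _fit_rss(Z, y)
    rss_restr = _fit_rss(Z[:, keep], y)
    gc = float(np.log(rss_restr / rss_full)) if rss_full > 0 else 0.0
    n, kf = Z.shape
    df_den = n - kf
    fstat = ((rss_restr - rss_full) / p) / (rss_full / df_den)
    pval = float(stats.f.sf(max(fstat, 0.0), p, df_den))
    return max(gc, 0.0), pval


@dataclass
class CGCResult:
    """Pairwise CGC matrix (source -> target) with significance information."""

    channels: tuple[str, ...]
    gc: np.ndarray            # (source, target), nats; diagonal NaN
    pvals: np.ndarray         # diagonal NaN
    mask: np.ndarray | None = None
    fdr_q: float | None = None

    def significant(self, q: float = FDR_Q_DEFAULT) -> "CGCResult":
        self.mask = fdr_mask(self.pvals, q)
        self.fdr_q = q
        return self


def cgc_matrix(X: SmoothedActivity,
               channels: tuple[str, ...] | None = None,
               p: int = ORDER_DEFAULT) -> CGCResult:
    """All-pairs conditional Granger causality from a single full-model fit.

    Uses the exact nested-OLS identity: dropping the ``p`` lag columns of a
    source from the full regression raises the residual sum of squares by
    ``b_S' [ (Z'Z)^-1_SS ]^-1 b_S``, so one Gram inversion serves every
    ordered pair.
    """
    idx = ([X.index(c) for c in channels] if channels is not None
           else list(range(len(X.channels))))
    names = tuple(X.channels[i] for i in idx)
    data = X.data[:, :, idx]
    Z, Y = _design(data, p)
    k = len(names)
    n, kf = Z.shape
    G = Z.T @ Z
    try:
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "rank-deficient regressor matrix; collinear channels among "
            f"{_collinear_channels(Z, names, p)}")
    B = Ginv @ (Z.T @ Y)
    rss_full = ((Y - Z @ B) ** 2).sum(axis=0)
    df_den = n - kf
    gc = np.full((k, k), np.nan)
    pv = np.full((k, k), np.nan)
    for i in range(k):
        S = [l * k + i for l in range(p)]
        W = Ginv[np.ix_(S, S)]
        Winv_bS = np.linalg.solve(W, B[S, :])
        delta = np.einsum("ij,ij->j", B[S, :], Winv_bS)  # per-target RSS increase
        for j in range(k):
            if j == i:
                continue
            gc[i, j] = max(float(np.log1p(delta[j] / rss_full[j])), 0.0)
            fstat = (delta[j] / p) / (rss_full[j] / df_den)
            pv[i, j] = float(stats.f.sf(max(fstat, 0.0), p, df_den))
    return CGCResult(channels=names, gc=gc, pvals=pv)


def fdr_mask(pvals: np.ndarray, q: float = FDR_Q_DEFAULT) -> np.ndarray:
    """Benjamini-Hochberg rejection mask over all finite entries."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any(np.isfinite(pvals) & ((pvals < 0) | (pvals > 1))):
        raise ValueError("p-values must lie in [0, 1]")
    mask = np.zeros(pvals.shape, dtype=bool)
    finite = np.isfinite(pvals)
    if finite.any():
        adj = stats.false_discovery_control(pvals[finite], method="bh")
        mask[finite] = adj <= q
    return mask


def select_order(X: SmoothedActivity, max_p: int = 20,
                 criterion: str = "bic") -> int:
    """Information-criterion VAR order selection (utility; order 10 is the default)."""
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    best, best_score = 1, np.inf
    for p in range(1, max_p + 1):
        m = fit_mvar(X, p=p)
        k = len(m.channels)
        # Gaussian log-likelihood with diagonal residual covariance
        ll = -0.5 * m.n_obs * np.sum(np.log(m.resid_var))
        n_par = p * k * k
        score = (-2 * ll + (2 if criterion == "aic" else np.log(m.n_obs)) * n_par)
        if score < best_score:
            best, best_score = p, score
    return best


def _tunnel_rows(layout: ElectrodeLayout) -> tuple[int, int]:
    rows = sorted({layout[e].row for e in layout.region_ids(REGION_TUNNEL, True)})
    return rows[0], rows[-1]


def connection_summaries(result: CGCResult, layout: ElectrodeLayout,
                         denominator: str = "well_a") -> dict:
    """Cross-well connection percentage and tunnel directional bias.

    ``denominator`` selects the normalisation of the cross-well percentage:
    ``"well_a"`` divides significant A->B edges by all significant edges
    originating in Well A; ``"both_wells"`` divides by all significant edges
    between well electrodes (either well).  The directional bias compares
    summed significant CGC between the two tunnel rows in the A->B versus
    B->A direction, as percentages of their total.
    """
    if result.mask is None:
        raise ValueError("run CGCResult.significant() before summarising")
    if denominator not in ("well_a", "both_wells"):
        raise ValueError("denominator must be 'well_a' or 'both_wells'")
    region = {eid: layout.region_of(eid) for eid in result.channels}
    k = len(result.channels)
    edges = [(i, j) for i in range(k) for j in range(k)
             if i != j and result.mask[i, j]]

    def reg(i):
        return region[result.channels[i]]

    n_ab = sum(1 for i, j in edges if reg(i) == REGION_A and reg(j) == REGION_B)
    if denominator == "well_a":
        denom = sum(1 for i, j in edges if reg(i) == REGION_A)
    else:
        wells = (REGION_A, REGION_B)
        denom = sum(1 for i, j in edges if reg(i) in wells and reg(j) in wells)
    cross_pct = 100.0 * n_ab / denom if denom else None

    row_a, row_b = _tunnel_rows(layout)
    fwd = rev = 0.0
    for i, j in edges:
        if reg(i) == REGION_TUNNEL and reg(j) == REGION_TUNNEL:
            ri, rj = layout[result.channels[i]].row, layout[result.channels[j]].row
            if ri == row_a and rj == row_b:
                fwd += result.gc[i, j]
            elif ri == row_b and rj == row_a:
                rev += result.gc[i, j]
    total = fwd + rev
    return {
        "n_significant": len(edges),
        "cross_well_ab_percent": cross_pct,
        "cross_well_denominator": denominator,
        "tunnel_forward_percent": 100.0 * fwd / total if total else None,
        "tunnel_reverse_percent": 100.0 * rev / total if total else None,
        "empty": len(edges) == 0,
    }


def export_graph(result: CGCResult, layout: ElectrodeLayout, path: str,
                 formats: tuple[str, ...] = ("gexf", "graphml")) -> list[str]:
    """Write the significant-connection digraph as GEXF and/or GraphML.

    Nodes carry region and grid position; directed edges are the significant
    pairs weighted by CGC value.  ``path`` is the base name without suffix.
    """
    if result.mask is None:
        raise ValueError("run CGCResult.significant() before exporting")
    g = nx.DiGraph()
    for eid in result.channels:
        e = layout[eid]
        g.add_node(eid, region=e.region, row=e.row, col=e.col)
    k = len(result.channels)
    for i in range(k):
        for j in range(k):
            if i != j and result.mask[i, j]:
                g.add_edge(result.channels[i], result.channels[j],
                           weight=float(result.gc[i, j]))
    written = []
    for fmt in formats:
        out = f"{path}.{fmt}"
        if fmt == "gexf":
            nx.write_gexf(g, out)
        elif fmt == "graphml":
            nx.write_graphml(g, out)
        else:
            raise ValueError(f"unknown graph format {fmt!r}")
        written.append(out)
    return written
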