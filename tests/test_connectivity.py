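"""Smoothing kernel, MVAR fitting, conditional Granger causality, FDR, export."""

import numpy as np
import pytest

from tunnelmea.connectivity import (
    CGCResult,
    SmoothedActivity,
    cgc_matrix,
    conditional_gc,
    connection_summaries,
    export_graph,
    fdr_mask,
    fit_mvar,
    smooth_trains,
)
from tunnelmea.data import SpikeData, StimulusLog
from tunnelmea.layout import default_layout

LAYOUT = default_layout()


def _activity(data, channels=None):
    data = np.asarray(data, float)
    channels = channels or tuple(f"2{i + 2}" for i in range(data.shape[2]))
    return SmoothedActivity(channels=tuple(channels), data=data)


def _var_realization(coefs, n, rng, sigma=None):
    """Simulate a stable VAR given coefs[lag][target][source]."""
    coefs = np.asarray(coefs, float)
    p, k, _ = coefs.shape
    sigma = np.ones(k) if sigma is None else np.asarray(sigma, float)
    x = np.zeros((n + 100, k))
    e = rng.normal(0, 1, (n + 100, k)) * np.sqrt(sigma)
    for t in range(p, n + 100):
        x[t] = e[t]
        for l in range(p):
            x[t] += coefs[l] @ x[t - 1 - l]
    return x[100:]


class TestSmoothTrains:
    def _spikes(self, trains, duration=100.0):
        return SpikeData(trains=trains, duration=duration, layout=LAYOUT)

    def _stim(self, n=3):
        return StimulusLog(times=5.0 + 2.0 * np.arange(n), electrode="41")

    def test_single_spike_kernel_shape(self):
        # spike 100 ms into the first window; enough spikes overall to pass 0.5 Hz
        extra = 10.0 + np.arange(60) * 1.0
        spikes = self._spikes({"22": np.sort(np.append(extra, 5.1005))})
        X = smooth_trains(spikes, self._stim())
        v = X.data[0, :, X.index("22")]
        assert v[99] == 0.0
        assert v[100] == pytest.approx(1.0)
        assert v[104] == pytest.approx(np.exp(-1.0))  # 4 ms later at tau = 4 ms

    def test_two_spike_superposition(self):
        extra = 10.0 + np.arange(60) * 1.0
        t = np.sort(np.concatenate([extra, [5.100, 5.101]]))
        spikes = self._spikes({"22": t})
        X = smooth_trains(spikes, self._stim())
        v = X.data[0, :, X.index("22")]
        assert v.max() == pytest.approx(1.0 + np.exp(-0.25))

    def test_low_rate_electrode_excluded(self):
        trains = {"22": np.arange(40) * 2.5,          # 0.4 Hz: below the cut
                  "23": np.arange(60) * 1.0}          # 0.6 Hz: included
        X = smooth_trains(self._spikes(trains), self._stim())
        assert "22" not in X.channels and "23" in X.channels

    def test_no_qualifying_electrodes_is_error(self):
        with pytest.raises(ValueError, match="rate filter"):
            smooth_trains(self._spikes({"22": np.array([1.0])}), self._stim())


class TestFitMvar:
    COEFS = [[[0.5, 0.1], [0.3, 0.4]], [[-0.2, 0.0], [0.1, 0.2]]]

    def test_var2_coefficients_recovered(self, rng):
        """Estimates agree with the generating VAR(2) at sampling precision."""
        x = _var_realization(self.COEFS, 10_000, rng)
        X = _activity(x[None])
        m = fit_mvar(X, p=2)
        # joint Wald statistic per target: (b - b0)' X'X (b - b0) / s^2 is
        # chi^2 with 4 df when the estimates recover the generating values
        from scipy.stats import chi2
        from tunnelmea.connectivity import _design
        Z, Y = _design(X.data, 2)
        G = Z.T @ Z
        dof = Z.shape[0] - Z.shape[1]
        true = np.asarray(self.COEFS)
        wald = 0.0
        for j in range(2):
            resid = Y[:, j] - Z @ np.linalg.lstsq(Z, Y[:, j], rcond=None)[0]
            s2 = (resid ** 2).sum() / dof
            diff = np.concatenate([m.coefs[l, j] - true[l, j] for l in range(2)])
            wald += diff @ G @ diff / s2
        assert wald < chi2.ppf(0.999, 8)

    def test_white_noise_cross_coefficients_null(self, rng):
        x = rng.normal(0, 1, (1, 8000, 2))
        m = fit_mvar(_activity(x), p=3)
        # cross terms hover near zero at the 1/sqrt(n) scale
        cross = [m.coefs[l, i, j] for l in range(3) for i in range(2)
                 for j in range(2) if i != j]
        assert np.max(np.abs(cross)) < 4.5 / np.sqrt(8000)

    def test_segment_shorter_than_order_rejected(self, rng):
        x = rng.normal(0, 1, (2, 8, 2))
        with pytest.raises(ValueError, match="order"):
            fit_mvar(_activity(x), p=10)

    def test_trial_pooling_never_crosses_boundaries(self, rng):
        """Fitting two trials equals fitting each trial's rows stacked."""
        x = rng.normal(0, 1, (2, 200, 2))
        m2 = fit_mvar(_activity(x), p=2)
        from tunnelmea.connectivity import _design
        Z, Y = _design(x, 2)
        assert Z.shape[0] == 2 * (200 - 2)
        b = np.linalg.lstsq(Z, Y, rcond=None)[0]
        np.testing.assert_allclose(
            m2.coefs, b.reshape(2, 2, 2).transpose(0, 2, 1), rtol=1e-8)


def brute_force_cgc(data, src, tgt, p):
    """Independent restricted-vs-full least squares on explicit lag matrices."""
    n_trials, T, k = data.shape
    rows_full, rows_restr, ys = [], [], []
    for tr in range(n_trials):
        d = data[tr] - data[tr].mean(axis=0)
        for t in range(p, T):
            past = [d[t - l, c] for l in range(1, p + 1) for c in range(k)]
            rows_full.append(past)
            rows_restr.append([v for idx, v in enumerate(past)
                               if idx % k != src])
            ys.append(d[t, tgt])
    zf, zr, y = np.array(rows_full), np.array(rows_restr), np.array(ys)
    bf = np.linalg.lstsq(zf, y, rcond=None)[0]
    br = np.linalg.lstsq(zr, y, rcond=None)[0]
    rss_f = ((y - zf @ bf) ** 2).sum()
    rss_r = ((y - zr @ br) ** 2).sum()
    return np.log(rss_r / rss_f), rss_f, rss_r


class TestConditionalGc:
    def test_matches_brute_force_oracle(self, rng):
        coefs = [[[0.4, 0.0], [0.5, 0.3]]]
        x = _var_realization(coefs, 3000, rng)
        X = _activity(x[None])
        for p in (1, 4):
            gc, _ = conditional_gc(X, "22", "23", p=p)
            want, _, _ = brute_force_cgc(X.data, 0, 1, p)
            assert gc == pytest.approx(want, rel=1e-8)

    def test_matrix_route_agrees_with_pairwise_route(self, rng):
        coefs = [[[0.4, 0.1, 0.0], [0.3, 0.3, 0.1], [0.0, 0.4, 0.2]]]
        x = _var_realization(coefs, 4000, rng)
        X = _activity(x[None])
        res = cgc_matrix(X, p=4)
        for i, src in enumerate(X.channels):
            for j, tgt in enumerate(X.channels):
                if i == j:
                    continue
                gc, pv = conditional_gc(X, src, tgt, p=4)
                assert res.gc[i, j] == pytest.approx(gc, rel=1e-7, abs=1e-12)
                assert res.pvals[i, j] == pytest.approx(pv, rel=1e-6, abs=1e-12)

    def test_analytic_geweke_value(self, rng):
        """Two-channel GC matches the spectral (Kolmogorov) closed form.

        For y_t = a y_{t-1} + c x_{t-1} + e and AR(1) x, the reduced-model
        innovation variance is exp of the mean log spectrum of y; the full
        model recovers the unit innovation variance.
        """
        a, b, c = 0.4, 0.5, 0.8
        coefs = [[[b, 0.0], [c, a]]]
        x = _var_realization(coefs, 100_000, rng)
        X = _activity(x[None])
        gc, _ = conditional_gc(X, "22", "23", p=10)
        w = np.linspace(0, np.pi, 20001)
        z = np.exp(-1j * w)
        s_y = (np.abs(c * z / (1 - b * z)) ** 2 + 1) / np.abs(1 - a * z) ** 2
        sigma2_red = np.exp(np.trapezoid(np.log(s_y), w) / np.pi)
        assert gc == pytest.approx(np.log(sigma2_red), rel=0.05)

    def test_conditioning_removes_mediated_link(self, rng):
        """x -> y -> z: CGC(x->z | y) vanishes, pairwise GC(x->z) does not."""
        coefs = [[[0.5, 0.0, 0.0], [0.7, 0.3, 0.0], [0.0, 0.7, 0.3]]]
        x = _var_realization(coefs, 20_000, rng)
        X = _activity(x[None], channels=("x", "y", "z"))
        gc_cond, _ = conditional_gc(X, "x", "z", p=5)
        gc_pair, _ = conditional_gc(X, "x", "z", p=5, conditioning=("x", "z"))
        assert gc_cond < 0.01
        assert gc_pair > 0.05

    def test_null_gc_near_zero_with_uniform_pvalue(self, rng):
        x = rng.normal(0, 1, (1, 6000, 2))
        gc, pv = conditional_gc(_activity(x), "22", "23", p=5)
        assert gc < 0.01
        assert 0.0 <= pv <= 1.0

    def test_affine_rescaling_invariance(self, rng):
        coefs = [[[0.4, 0.2], [0.3, 0.3]]]
        x = _var_realization(coefs, 3000, rng)
        gc1, p1 = conditional_gc(_activity(x[None]), "22", "23", p=3)
        y = x.copy()
        y[:, 0] = 7.0 - 3.5 * y[:, 0]  # affine map of the source channel
        gc2, p2 = conditional_gc(_activity(y[None]), "22", "23", p=3)
        assert gc2 == pytest.approx(gc1, rel=1e-8)
        assert p2 == pytest.approx(p1, rel=1e-6)

    def test_self_pair_rejected(self, rng):
        X = _activity(rng.normal(0, 1, (1, 100, 2)))
        with pytest.raises(ValueError):
            conditional_gc(X, "22", "22")


class TestFdrMask:
    def test_all_ones_no_rejections(self):
        p = np.ones((3, 3))
        np.fill_diagonal(p, np.nan)
        assert not fdr_mask(p).any()

    def test_hand_computed_bh_step_up(self):
        """p = [1e-4, .9, .9, .9] at q = .001: only 1e-4 <= .001 * 1/4."""
        p = np.array([1e-4, 0.9, 0.9, 0.9])
        assert fdr_mask(p, q=0.001).tolist() == [True, False, False, False]

    def test_nan_entries_ignored(self):
        p = np.array([[np.nan, 1e-9], [0.5, np.nan]])
        mask = fdr_mask(p, q=0.001)
        assert mask[0, 1] and not mask[1, 0] and not mask[0, 0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_mask(np.array([0.5, 1.5]))


class TestSummariesAndExport:
    def _toy_result(self):
        # channels: two in A, two in B, two tunnel electrodes (rows 4 and 5)
        channels = ("22", "23", "26", "27", "24", "25")
        k = len(channels)
        gc = np.full((k, k), np.nan)
        pv = np.full((k, k), np.nan)
        mask = np.zeros((k, k), bool)
        return CGCResult(channels=channels, gc=gc, pvals=pv, mask=mask)

    def test_cross_well_fraction_arithmetic(self):
        res = self._toy_result()
        # 8 A-internal edges requires more A channels; emulate with weights:
        # use 3 A->A edges and 2 A->B edges: fraction = 2 / 5 = 40%
        res.mask[0, 1] = res.mask[1, 0] = True
        res.gc[0, 1] = res.gc[1, 0] = 0.5
        res.mask[0, 2], res.mask[0, 3] = True, True
        res.gc[0, 2] = res.gc[0, 3] = 0.2
        res.mask[1, 2] = True
        res.gc[1, 2] = 0.2
        s = connection_summaries(res, LAYOUT, denominator="well_a")
        assert s["cross_well_ab_percent"] == pytest.approx(100 * 3 / 5)

    def test_both_wells_denominator(self):
        res = self._toy_result()
        res.mask[0, 2] = True   # A -> B
        res.gc[0, 2] = 0.2
        res.mask[2, 3] = True   # B -> B
        res.gc[2, 3] = 0.2
        s = connection_summaries(res, LAYOUT, denominator="both_wells")
        assert s["cross_well_ab_percent"] == pytest.approx(50.0)

    def test_symmetric_tunnel_weights_give_even_split(self):
        res = self._toy_result()
        res.mask[4, 5] = res.mask[5, 4] = True
        res.gc[4, 5] = res.gc[5, 4] = 0.3
        s = connection_summaries(res, LAYOUT)
        assert s["tunnel_forward_percent"] == pytest.approx(50.0)
        assert s["tunnel_reverse_percent"] == pytest.approx(50.0)

    def test_empty_mask_flagged(self):
        s = connection_summaries(self._toy_result(), LAYOUT)
        assert s["empty"] and s["cross_well_ab_percent"] is None

    def test_graph_round_trip(self, tmp_path):
        import networkx as nx
        res = self._toy_result()
        res.mask[0, 2], res.mask[4, 5], res.mask[2, 1] = True, True, True
        res.gc[0, 2], res.gc[4, 5], res.gc[2, 1] = 0.11, 0.22, 0.33
        paths = export_graph(res, LAYOUT, str(tmp_path / "net"))
        g = nx.read_gexf(paths[0])
        assert set(g.nodes) == set(res.channels)
        assert set(g.edges) == {("22", "26"), ("24", "25"), ("26", "23")}
        assert g.edges["22", "26"]["weight"] == pytest.approx(0.11)
        g2 = nx.read_graphml(paths[1])
        assert set(g2.edges) == set(g.edges)

    def test_empty_mask_exports_nodes_only(self, tmp_path):
        import networkx as nx
        paths = export_graph(self._toy_result(), LAYOUT, str(tmp_path / "net"))
        g = nx.read_gexf(paths[0])
        assert len(g.nodes) == 6 and len(g.edges) == 0
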