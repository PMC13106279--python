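import itertools

import numpy as np
import pytest

from craniosemg.config import BANDS, PipelineConfig, TimeDomainConfig
from craniosemg.network import (
    FEATURE_NAMES,
    assemble_feature_vector,
    band_coherence,
    coherence_significance,
    edge_weights,
    effective_segments,
    local_sd_series,
    network_metrics,
    visibility_graph,
)

FS = 2000.0


class TestLocalSdSeries:
    def test_constant_signal_gives_zeros(self):
        np.testing.assert_array_equal(local_sd_series(np.ones(500)), 0.0)

    def test_series_length_drops_partial_block(self):
        assert len(local_sd_series(np.zeros(570), 100)) == 5

    def test_alternating_block_scale_recovered(self):
        rng = np.random.default_rng(0)
        blocks = []
        for i in range(40):
            sd = 1.0 if i % 2 == 0 else 2.0
            blocks.append(rng.normal(0, sd, 100))
        v = local_sd_series(np.concatenate(blocks), 100)
        assert np.all(np.abs(v[::2] - 1.0) < 0.5)
        assert np.all(np.abs(v[1::2] - 2.0) < 0.7)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            local_sd_series(np.ones(150), 100)


def brute_force_visibility(v):
    """O(M^3) check of the strict natural-visibility criterion."""
    m = len(v)
    edges = set()
    for x in range(m):
        for y in range(x + 1, m):
            ok = True
            for z in range(x + 1, y):
                if not (v[y] - v[z]) / (y - z) > (v[y] - v[x]) / (y - x):
                    ok = False
                    break
            if ok:
                edges.add((x, y))
    return edges


class TestVisibilityGraph:
    def test_two_nodes_fully_connected(self):
        assert visibility_graph(np.array([1.0, 5.0])).density == 1.0

    def test_strictly_linear_series_has_only_adjacent_edges(self):
        g = visibility_graph(np.arange(10, dtype=float))
        assert g.density == pytest.approx(0.2)

    def test_strictly_convex_series_is_complete(self):
        v = (np.arange(10.0) - 4.5) ** 2
        assert visibility_graph(v).density == 1.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            m = rng.integers(2, 51)
            v = rng.standard_normal(m)
            assert visibility_graph(v).edges == brute_force_visibility(v)


class TestCoherence:
    def test_self_coherence_is_one(self):
        x = np.random.default_rng(0).standard_normal(20000)
        f, coh, _ = band_coherence(x, x, FS)
        assert np.all(np.abs(coh - 1.0) < 1e-6)

    def test_delayed_copy_keeps_high_coherence(self):
        x = np.random.default_rng(1).standard_normal(20000)
        f, coh, _ = band_coherence(x, np.roll(x, 5), FS)
        for lo, hi in BANDS.values():
            assert coh[(f >= lo) & (f <= hi)].mean() > 0.9

    def test_independent_noise_band_mean_below_threshold(self):
        below = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            f, coh, l_hat = band_coherence(
                rng.standard_normal(20000), rng.standard_normal(20000), FS
            )
            s = coherence_significance(l_hat)
            means = [coh[(f >= lo) & (f <= hi)].mean() for lo, hi in BANDS.values()]
            below += np.mean(means) < s
        assert below >= 18  # >= 90% of seeds

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="epoch"):
            band_coherence(np.ones(4000), np.ones(5000), FS)

    def test_single_window_rejected(self):
        x = np.random.default_rng(2).standard_normal(1100)
        with pytest.raises(ValueError, match="window"):
            band_coherence(x, x.copy(), FS)


class TestSignificance:
    def test_closed_form_at_two_segments(self):
        assert coherence_significance(2) == pytest.approx(0.95)

    def test_closed_form_at_21_segments(self):
        assert coherence_significance(21) == pytest.approx(1 - 0.05 ** (1 / 20))
        assert coherence_significance(21) == pytest.approx(0.139, abs=0.001)

    def test_strictly_decreasing_to_zero(self):
        vals = [coherence_significance(l) for l in (2, 5, 10, 100, 10000)]
        assert np.all(np.diff(vals) < 0)
        assert vals[-1] < 0.001

    def test_degenerate_l_hat_rejected(self):
        with pytest.raises(ValueError):
            coherence_significance(1.0)

    def test_effective_segments_below_raw_count(self):
        n = 20000
        l_hat = effective_segments(n)
        k_raw = 1 + (n - 1024) // 256
        assert 2 < l_hat < k_raw


class TestEdgeWeights:
    f = np.linspace(0, 1000, 4097)[:2049]

    def test_all_subthreshold_gives_zero_weight(self):
        coh = np.full_like(self.f, 0.05)
        w = edge_weights(self.f, coh, s_threshold=0.2)
        assert all(v == 0.0 for v in w.values())

    def test_fisher_z_of_pruned_mean(self):
        coh = np.full_like(self.f, 0.5)
        w = edge_weights(self.f, coh, s_threshold=0.2)
        assert w["beta"] == pytest.approx(np.arctanh(0.5), rel=1e-6)

    def test_near_unit_coherence_is_clamped_finite(self):
        coh = np.ones_like(self.f)
        w = edge_weights(self.f, coh, s_threshold=0.2)
        assert all(np.isfinite(v) for v in w.values())

    def test_notched_bin_excluded_from_low_gamma(self):
        coh = np.full_like(self.f, 0.3)
        coh[np.abs(self.f - 60.0) <= 1.0] = 0.0  # notch trough
        w = edge_weights(self.f, coh, s_threshold=0.1)
        assert w["low_gamma"] == pytest.approx(np.arctanh(0.3), rel=1e-6)


def brute_force_ge(w):
    """Dijkstra-free shortest paths by Floyd-Warshall on 1/w lengths."""
    n = w.shape[0]
    d = np.where(w > 0, 1.0 / np.where(w > 0, w, 1), np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                d[i, j] = min(d[i, j], d[i, k] + d[k, j])
    vals = [1.0 / d[i, j] if np.isfinite(d[i, j]) and d[i, j] > 0 else 0.0
            for i, j in itertools.combinations(range(n), 2)]
    return float(np.mean(vals))


class TestNetworkMetrics:
    def test_complete_unit_graph(self):
        w = np.ones((6, 6)) - np.eye(6)
        nodstr, ge = network_metrics(w)
        assert nodstr == pytest.approx(5.0)
        assert ge == pytest.approx(1.0)

    def test_empty_graph(self):
        assert network_metrics(np.zeros((6, 6))) == (0.0, 0.0)

    def test_three_node_path(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        _, ge = network_metrics(w)
        assert ge == pytest.approx(5 / 6 / 1, rel=1e-9)

    def test_asymmetric_input_rejected(self):
        w = np.zeros((3, 3))
        w[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            network_metrics(w)

    def test_matches_brute_force_and_monotone_in_edge_weight(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            w = rng.random((6, 6)) * (rng.random((6, 6)) < 0.6)
            w = np.triu(w, 1)
            w = w + w.T
            _, ge = network_metrics(w)
            assert ge == pytest.approx(brute_force_ge(w), rel=1e-9)
            # increase one present edge: GE must not decrease
            i, j = np.unravel_index(np.argmax(np.triu(w, 1)), w.shape)
            w2 = w.copy()
            w2[i, j] = w2[j, i] = w[i, j] * 2 + 0.1
            _, ge2 = network_metrics(w2)
            assert ge2 >= ge - 1e-12


class TestAssembleFeatureVector:
    def test_sixty_finite_named_features(self, clean_recording, burst_set):
        rec, _ = clean_recording
        fv = assemble_feature_vector(rec, burst_set)
        assert list(fv) == FEATURE_NAMES
        assert all(np.isfinite(v) for v in fv.values())

    def test_scale_invariant_features_unchanged_under_doubling(
        self, clean_recording, burst_set
    ):
        rec, _ = clean_recording
        cfg = PipelineConfig()
        fv = assemble_feature_vector(rec, burst_set, cfg)
        from dataclasses import replace as drep

        rec2 = drep(rec, signal=rec.signal * 2.0)
        cfg2 = PipelineConfig(time_domain=TimeDomainConfig(amplitude_threshold_mv=8.0))
        fv2 = assemble_feature_vector(rec2, detect_bursts_like(rec2, burst_set), cfg2)
        for name in FEATURE_NAMES:
            stem = name.split("_")[0]
            if stem in ("ZR", "SlpSignChange", "RR", "DET", "density"):
                assert fv2[name] == pytest.approx(fv[name], rel=1e-9), name

    def test_missing_channel_bursts_propagate_nan(self, clean_recording):
        from craniosemg.segmentation import BurstSet

        rec, _ = clean_recording
        empty = BurstSet(centers={ch: np.array([], dtype=int) for ch in rec.channels})
        fv = assemble_feature_vector(rec, empty)
        assert np.isnan(fv["MAV_RTEMP"])  # burst-dependent
        assert np.isfinite(fv["MNF_RTEMP"])  # whole-signal feature


def detect_bursts_like(rec, bursts):
    """Burst set with identical centers (amplitude scaling must not move
    detections; reuse them to isolate the feature computation)."""
    from craniosemg.segmentation import BurstSet

    return BurstSet(centers=dict(bursts.centers), params=bursts.params)
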