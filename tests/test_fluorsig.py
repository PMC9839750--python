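"""Signal treatment: trend fitting, homogenization, smoothing, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualflit import fluorsig as fl
from dualflit import simulate as sim
from dualflit import tracking as trk

from conftest import make_trace


class TestTrendFit:
    def test_linear_series_recovered_exactly(self):
        t = np.arange(1, 21)
        fit = fl.fit_temporal_trend(3.0 * t + 7.0, "linear")
        assert fit.form == "linear"
        assert abs(fit.params[0] - 3.0) < 1e-9
        assert abs(fit.params[1] - 7.0) < 1e-9

    def test_power_law_recovered_on_noiseless_series(self):
        t = np.arange(1, 101, dtype=float)
        means = 5.0 * t ** -0.5 + 10.0
        fit = fl.fit_temporal_trend(means, "power_law")
        assert fit.form == "power_law"
        a, b, c = fit.params
        for got, true in zip((a, b, c), (5.0, -0.5, 10.0)):
            assert abs(got - true) / abs(true) < 1e-6

    def test_constant_series_gives_flat_trend(self):
        means = np.full(30, 42.0)
        for form in ("linear", "power_law"):
            fit = fl.fit_temporal_trend(means, form)
            assert np.allclose(fit.trend(np.arange(30)), 42.0, atol=1e-6)

    def test_linear_residual_mean_is_zero(self):
        rng = np.random.default_rng(0)
        means = 2.0 * np.arange(1, 51) + rng.normal(0, 5, 50)
        fit = fl.fit_temporal_trend(means, "linear")
        assert abs(fit.residuals.mean()) < 1e-9


class TestHomogenize:
    def test_on_trend_input_unchanged(self):
        t = np.arange(1, 11)
        means = 2.0 * t + 5.0
        stack = np.repeat(means, 25).reshape(10, 5, 5).astype(float)
        fit = fl.fit_temporal_trend(means, "linear")
        out = fl.homogenize(stack, fit)
        assert np.allclose(out, stack, atol=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_corrected_means_equal_trend_for_random_stacks(self, seed):
        rng = np.random.default_rng(seed)
        stack = rng.uniform(0, 500, size=(12, 8, 9))
        fit = fl.fit_temporal_trend(stack.mean(axis=(1, 2)), "linear")
        out = fl.homogenize(stack, fit)
        g = fit.trend(np.arange(12))
        assert np.abs(out.mean(axis=(1, 2)) - g).max() < 1e-6

    def test_flicker_removed_on_rendered_fixture(self, pge2):
        clone = sim.simulate_lineage(pge2, 20.0, seed=1)
        sim.simulate_traces(clone, seed=2)
        cfg = sim.RenderConfig(duration_h=20.0, flicker_sd=50.0,
                               pixel_noise_sd=0.0, seed=3)
        sim.render_sequence(clone, cfg)
        stack = clone.images[sim.COMMIT_CHANNEL]
        fit = fl.fit_temporal_trend(stack.mean(axis=(1, 2)), "linear")
        out = fl.homogenize(stack, fit)
        g = fit.trend(np.arange(stack.shape[0]))
        assert np.abs(out.mean(axis=(1, 2)) - g).max() < 1e-6
        # temporal sd in a cell-free corner patch drops after correction
        patch_in = stack[:, :20, :20].mean(axis=(1, 2))
        patch_out = out[:, :20, :20].mean(axis=(1, 2))
        assert patch_out.std() < patch_in.std()


class TestOverexposure:
    def test_clean_frames_not_flagged(self):
        ch = fl.FluorChannel("myog", saturation_value=100.0)
        frames = np.full((5, 4, 4), 50.0)
        assert not fl.flag_overexposed(frames, ch).any()

    def test_saturated_frame_flagged(self):
        ch = fl.FluorChannel("myog", saturation_value=100.0)
        frames = np.full((3, 4, 4), 50.0)
        frames[1] = 100.0
        assert fl.flag_overexposed(frames, ch).tolist() == [False, True, False]

    def test_exactly_injected_frames_flagged_in_long_sequence(self):
        rng = np.random.default_rng(0)
        ch = fl.FluorChannel("myog", saturation_value=4095.0)
        frames = rng.uniform(100, 1000, size=(217, 10, 10))
        for f in (50, 180):
            frames[f] = 4095.0
        flagged = np.where(fl.flag_overexposed(frames, ch))[0]
        assert flagged.tolist() == [50, 180]


class TestExtract:
    def _single_track_set(self, n_frames=5, shape=(10, 10)):
        imgs = [np.zeros(shape, dtype=np.uint16) for _ in range(n_frames)]
        for img in imgs:
            img[3:6, 3:6] = 1
        tracks = {1: trk.CellTrack(1, 0, 0, n_frames - 1)}
        return trk.TrackSet(tracks, n_frames, imgs)

    def test_uniform_image_gives_uniform_trace(self):
        ts = self._single_track_set()
        stack = np.full((5, 10, 10), 7.5)
        tr = fl.extract_trace(ts.tracks[1], stack, ts, "myog")
        assert np.allclose(tr.raw, 7.5)

    def test_flagged_frame_missing_neighbors_intact(self):
        ts = self._single_track_set()
        stack = np.full((5, 10, 10), 7.5)
        flagged = np.array([False, False, True, False, False])
        tr = fl.extract_trace(ts.tracks[1], stack, ts, "myog", flagged)
        assert tr.missing.tolist() == [False, False, True, False, False]
        assert np.allclose(tr.raw[[0, 1, 3, 4]], 7.5)

    def test_empty_mask_on_live_frame_raises(self):
        ts = self._single_track_set()
        ts.label_images[2][:] = 0
        stack = np.zeros((5, 10, 10))
        with pytest.raises(ValueError, match="track 1.*frame 2"):
            fl.extract_trace(ts.tracks[1], stack, ts, "myog")

    def test_raw_trace_tracks_truth_on_noiseless_fixture(self, pge2):
        clone = sim.simulate_lineage(pge2, 20.0, seed=1)
        dyn = sim.ReporterDynamics(trace_noise_sd=0.0)
        sim.simulate_traces(clone, dyn, seed=2)
        cfg = sim.RenderConfig(duration_h=20.0, flicker_sd=0.0,
                               pixel_noise_sd=0.0, seed=3)
        sim.render_sequence(clone, cfg)
        ts = trk.trackset_from_clone(clone)
        stack = clone.images[sim.COMMIT_CHANNEL]
        fit = fl.fit_temporal_trend(stack.mean(axis=(1, 2)), "linear")
        corrected = fl.homogenize(stack, fit)
        for cid in ts.tracks:
            true = clone.clean_traces[(cid, sim.COMMIT_CHANNEL)]
            if true.size < 5 or np.ptp(true) < 0.05:
                continue
            tr = fl.extract_trace(ts.tracks[cid], corrected, ts, "myog")
            r = np.corrcoef(tr.raw, true)[0, 1]
            assert r ** 2 > 0.99


def brute_force_windowed_mean(raw, missing, window):
    half = window // 2
    out = np.full(raw.size, np.nan)
    for i in range(raw.size):
        if missing[i]:
            continue
        vals = [raw[j] for j in range(max(0, i - half), min(raw.size, i + half + 1))
                if not missing[j]]
        out[i] = sum(vals) / len(vals)
    return out


class TestSmooth:
    def test_constant_trace_unchanged(self):
        tr = fl.smooth(make_trace([3.0] * 7))
        assert np.allclose(tr.smoothed, 3.0)

    def test_window_truncation_matches_hand_computation(self):
        tr = fl.smooth(make_trace([0, 0, 5, 0, 0]))
        # centered window of 5 truncated at the ends
        assert np.allclose(tr.smoothed, [5 / 3, 5 / 4, 1.0, 5 / 4, 5 / 3])

    def test_window_one_is_identity(self):
        vals = [1.0, 4.0, 2.0, 8.0]
        tr = fl.smooth(make_trace(vals), window=1)
        assert np.allclose(tr.smoothed, vals)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            fl.smooth(make_trace([1.0, 2.0]), window=4)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            fl.smooth(make_trace([1.0, 2.0], missing=[True, True]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.sampled_from([1, 3, 5, 7]))
    def test_matches_brute_force_oracle(self, seed, window):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 40))
        raw = rng.uniform(-10, 10, n)
        missing = rng.random(n) < 0.25
        if missing.all():
            missing[int(rng.integers(0, n))] = False
        tr = fl.smooth(make_trace(raw, missing), window=window)
        expected = brute_force_windowed_mean(raw, missing, window)
        ok = ~missing
        assert np.allclose(tr.smoothed[ok], expected[ok])


class TestNormalize:
    def test_span_maps_to_unit_interval(self):
        tr = make_trace([10.0, 60.0, 110.0])
        tr.smoothed = tr.raw.copy()
        fl.normalize(tr)
        assert np.allclose(tr.normalized, [0.0, 0.5, 1.0])

    def test_differentiation_reference_raises_maximum(self):
        tr = make_trace([20.0, 80.0])
        tr.smoothed = tr.raw.copy()
        fl.normalize(tr, differentiation_p99=120.0)
        assert np.allclose(tr.normalized, [0.0, 0.6])
        assert tr.norm_bounds[2] == "differentiation_p99"

    def test_observed_max_wins_when_higher(self):
        tr = make_trace([20.0, 150.0])
        tr.smoothed = tr.raw.copy()
        fl.normalize(tr, differentiation_p99=120.0)
        assert tr.norm_bounds == (20.0, 150.0, "observed")

    def test_bounds_shared_across_tracks_of_a_sequence(self):
        a = make_trace([0.0, 10.0], track_id=1)
        b = make_trace([40.0, 100.0], track_id=2)
        for t in (a, b):
            t.smoothed = t.raw.copy()
        fl.normalize_traces([a, b])
        assert np.allclose(a.normalized, [0.0, 0.1])
        assert np.allclose(b.normalized, [0.4, 1.0])

    def test_degenerate_range_rejected(self):
        tr = make_trace([5.0, 5.0])
        tr.smoothed = tr.raw.copy()
        with pytest.raises(ValueError, match="degenerate"):
            fl.normalize(tr)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(0.1, 50.0), st.floats(-100.0, 100.0))
    def test_invariant_to_affine_rescaling(self, scale, offset):
        rng = np.random.default_rng(1)
        raw = rng.uniform(0, 100, 20)
        a = make_trace(raw)
        b = make_trace(scale * raw + offset)
        for t in (a, b):
            t.smoothed = t.raw.copy()
        fl.normalize(a, differentiation_p99=120.0)
        fl.normalize(b, differentiation_p99=scale * 120.0 + offset)
        assert np.allclose(a.normalized, b.normalized, atol=1e-9)


class TestQuintiles:
    @pytest.mark.parametrize("value,expected",
                             [(0.0, 1), (0.19, 1), (0.2, 2), (0.45, 3),
                              (0.79, 4), (0.8, 5), (1.0, 5)])
    def test_bin_edges(self, value, expected):
        tr = make_trace([value])
        tr.normalized = np.array([value])
        assert fl.to_quintiles(tr).quintile[0] == expected

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=30))
    def test_monotone_in_signal(self, values):
        tr = make_trace(values)
        tr.normalized = np.asarray(values)
        q = fl.to_quintiles(tr).quintile
        order = np.argsort(values)
        assert (np.diff(q[order]) >= 0).all()


def test_process_sequence_normalized_traces_track_truth(rendered_clone):
    """End-to-end signal treatment on a rendered fixture with noise on."""
    ts = trk.trackset_from_clone(rendered_clone)
    traces, fits = fl.process_sequence(ts, rendered_clone.images)
    assert fits[sim.STEM_CHANNEL].form == "power_law"
    assert fits[sim.COMMIT_CHANNEL].form == "linear"
    checked = 0
    for (cid, ch), tr in traces.items():
        clean = rendered_clone.clean_traces[(cid, ch)]
        if clean.size < 8 or np.ptp(clean) < 0.1:
            continue
        ok = ~tr.missing
        r = np.corrcoef(tr.normalized[ok], clean[: len(tr)][ok])[0, 1]
        assert r > 0.9
        checked += 1
    assert checked >= 5
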