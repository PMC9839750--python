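"""38-feature division descriptors, standardization and scaling."""

import numpy as np
import pytest

from dualflit import features as feat
from dualflit import simulate as sim

from conftest import make_trace


def family_traces(parent_commit, high_commit, low_commit, parent_stem=None,
                  high_stem=None, low_stem=None, first=(0, 4, 4)):
    """Parent (track 1) and daughters (2=high, 3=low) on a 20-min grid."""
    traces = {}
    specs = [(1, parent_commit, parent_stem, first[0]),
             (2, high_commit, high_stem, first[1]),
             (3, low_commit, low_stem, first[2])]
    for tid, commit, stem, f0 in specs:
        commit = np.asarray(commit, dtype=float)
        stem = (np.asarray(stem, dtype=float) if stem is not None
                else 1.0 - commit)
        for ch, vals in ((sim.COMMIT_CHANNEL, commit), (sim.STEM_CHANNEL, stem)):
            tr = make_trace(vals, first_frame=f0, track_id=tid, channel=ch)
            tr.smoothed = tr.raw.copy()
            tr.normalized = tr.raw.copy()
            traces[(tid, ch)] = tr
    return traces


def make_event(traces, division_time_h=4 / 3.0, generation=0):
    return feat.make_division_event("seq", 1, 2, 3, division_time_h,
                                    generation, traces)


class TestExtraction:
    def test_identical_daughters_have_zero_contrasts(self):
        traces = family_traces([0.5] * 4, [0.3] * 5, [0.3] * 5)
        ev = make_event(traces)
        v = feat.extract_features(ev, traces, {})
        names = feat.FEATURE_NAMES
        assert v[names.index("lifetime_difference_h")] == 0.0
        assert v[names.index("daughter_stem_mean_contrast")] == 0.0
        assert v[names.index("daughter_commit_mean_contrast")] == 0.0

    def test_constant_trace_statistics(self):
        traces = family_traces([0.5] * 4, [0.3] * 5, [0.2] * 5)
        ev = make_event(traces)
        v = feat.extract_features(ev, traces, {})
        names = feat.FEATURE_NAMES
        assert v[names.index("parent_commit_var")] == 0.0
        assert v[names.index("parent_commit_min")] == \
               v[names.index("parent_commit_max")] == \
               v[names.index("parent_commit_mean")] == 0.5

    def test_linear_commitment_slope_closed_form(self):
        # 0.1 -> 0.9 over 4 h (13 frames at 20 min): slope 0.2/h exactly
        rise = np.linspace(0.1, 0.9, 13)
        traces = family_traces([0.1] * 4, rise, [0.1] * 13)
        ev = make_event(traces)
        v = feat.extract_features(ev, traces, {})
        assert ev.daughter_high == 2
        slope = v[feat.FEATURE_NAMES.index("daughter_high_commit_slope_per_h")]
        assert abs(slope - 0.2) < 1e-9

    def test_single_frame_daughter_slope_zero(self):
        traces = family_traces([0.5] * 4, [0.9], [0.1] * 5,
                               first=(0, 4, 4))
        ev = make_event(traces)
        v = feat.extract_features(ev, traces, {})
        assert v[feat.FEATURE_NAMES.index("daughter_high_commit_slope_per_h")] == 0.0

    def test_daughter_order_is_canonical(self):
        traces = family_traces([0.5] * 4, [0.9] * 5, [0.1] * 5)
        ev_ab = feat.make_division_event("s", 1, 2, 3, 1.0, 0, traces)
        ev_ba = feat.make_division_event("s", 1, 3, 2, 1.0, 0, traces)
        assert ev_ab == ev_ba
        va = feat.extract_features(ev_ab, traces, {2: True})
        vb = feat.extract_features(ev_ba, traces, {2: True})
        assert np.array_equal(va, vb)

    def test_frame_origin_shift_moves_only_division_time(self):
        tr0 = family_traces([0.5] * 4, [0.8] * 5, [0.1] * 5, first=(0, 4, 4))
        tr9 = family_traces([0.5] * 4, [0.8] * 5, [0.1] * 5, first=(9, 13, 13))
        v0 = feat.extract_features(make_event(tr0, division_time_h=4 / 3), tr0, {})
        v9 = feat.extract_features(
            feat.make_division_event("s", 1, 2, 3, 13 / 3, 0, tr9), tr9, {})
        i_t = feat.FEATURE_NAMES.index("division_time_h")
        mask = np.ones(feat.N_FEATURES, dtype=bool)
        mask[i_t] = False
        assert np.allclose(v0[mask], v9[mask])
        assert abs((v9[i_t] - v0[i_t]) - 3.0) < 1e-9

    def test_missing_daughter_trace_raises(self):
        traces = family_traces([0.5] * 4, [0.8] * 5, [0.1] * 5)
        del traces[(3, sim.COMMIT_CHANNEL)]
        with pytest.raises(ValueError, match="track 3"):
            feat.make_division_event("s", 1, 2, 3, 1.0, 0, traces)

    def test_vector_length_and_finiteness_on_simulated_divisions(self, small_cohort):
        clone = next(c for c in small_cohort if c.divisions())
        traces = feat.traces_from_clone(clone)
        events, da, labels = feat.events_from_clone(clone, traces)
        X = feat.feature_matrix(events, traces, da)
        assert X.shape == (len(events), feat.N_FEATURES)
        assert np.isfinite(X).all()
        assert len(labels) == len(events)


class TestStandardize:
    def test_constant_column_scales_to_zero(self):
        X = np.ones((5, feat.N_FEATURES))
        Xs, scaling = feat.standardize(X)
        assert np.allclose(Xs, 0.0)
        assert np.allclose(scaling.sd, 1.0)  # zero-sd guard

    def test_two_rows_give_plus_minus_one(self):
        # population sd of two points is half their separation
        X = np.zeros((2, feat.N_FEATURES))
        X[1, :] = 2.0
        Xs, _ = feat.standardize(X)
        assert np.allclose(Xs[0], -1.0)
        assert np.allclose(Xs[1], 1.0)

    def test_columns_have_zero_mean_and_weight_sd(self):
        rng = np.random.default_rng(3)
        X = rng.normal(5, 3, size=(40, feat.N_FEATURES))
        w = rng.uniform(0.5, 2.0, feat.N_FEATURES)
        Xs, _ = feat.standardize(X, weights=w)
        assert np.allclose(Xs.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(Xs.std(axis=0), w, atol=1e-9)

    def test_weights_zero_except_one_feature_controls_distances(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, feat.N_FEATURES))
        w = np.zeros(feat.N_FEATURES)
        i = feat.FEATURE_NAMES.index("daughter_commit_mean_contrast")
        w[i] = 1.0
        Xs, _ = feat.standardize(X, weights=w)
        d = np.linalg.norm(Xs[0] - Xs[1])
        assert abs(d - abs(Xs[0, i] - Xs[1, i])) < 1e-12

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            feat.standardize(np.ones((1, feat.N_FEATURES)))

    def test_applying_scaling_reproduces_training_matrix(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, feat.N_FEATURES))
        Xs, scaling = feat.standardize(X)
        assert np.array_equal(feat.apply_scaling(X, scaling), Xs)


class TestApplyScaling:
    def test_training_mean_maps_to_zero(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(15, feat.N_FEATURES))
        _, scaling = feat.standardize(X)
        assert np.allclose(feat.apply_scaling(X.mean(axis=0), scaling), 0.0)

    def test_identity_scaling(self):
        scaling = feat.FeatureScaling(np.zeros(feat.N_FEATURES),
                                      np.ones(feat.N_FEATURES),
                                      np.ones(feat.N_FEATURES))
        v = np.arange(feat.N_FEATURES, dtype=float)
        assert np.array_equal(feat.apply_scaling(v, scaling), v)

    def test_affine_in_its_argument(self):
        rng = np.random.default_rng(7)
        _, scaling = feat.standardize(rng.normal(size=(10, feat.N_FEATURES)))
        x, y = rng.normal(size=(2, feat.N_FEATURES))
        for alpha in (0.0, 0.3, 1.0):
            lhs = feat.apply_scaling(alpha * x + (1 - alpha) * y, scaling)
            rhs = (alpha * feat.apply_scaling(x, scaling)
                   + (1 - alpha) * feat.apply_scaling(y, scaling))
            assert np.allclose(lhs, rhs, atol=1e-9)

    def test_wrong_length_rejected(self):
        _, scaling = feat.standardize(np.ones((2, feat.N_FEATURES)) *
                                      np.arange(2)[:, None])
        with pytest.raises(ValueError):
            feat.apply_scaling(np.ones(10), scaling)


def test_scaling_json_round_trip(tmp_path):
    rng = np.random.default_rng(8)
    _, scaling = feat.standardize(rng.normal(size=(12, feat.N_FEATURES)))
    feat.write_scaling(scaling, tmp_path / "scaling.json")
    back = feat.read_scaling(tmp_path / "scaling.json")
    assert np.array_equal(back.mean, scaling.mean)
    assert np.array_equal(back.sd, scaling.sd)
    assert np.array_equal(back.weights, scaling.weights)
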