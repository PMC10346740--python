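"""Running/leg-shake window detection, gyro-variance discrimination,
feature moments and the confusion-matrix metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ovistep.behavior import (
    FAST_WALK,
    LEG_SHAKE,
    RUNNING,
    BehaviorWindow,
    classification_metrics,
    classify_candidate,
    cluster_behaviors,
    detect_leg_shake_candidates,
    detect_running,
    extract_features,
)
from ovistep.config import ThresholdConfig
from ovistep.extrema import ExtremaSet, detect_extrema
from ovistep.pipeline import count_steps
from ovistep.simulate import SegmentSpec, generate

from conftest import brute_force_moments


def make_extrema(peaks, paired_valleys, spacing=14, first=10):
    """ExtremaSet from (value, ...) lists; peak k sits at first + k*spacing
    and its paired valley halfway to the next peak (or as given)."""
    p_idx = np.array([first + k * spacing for k in range(len(peaks))])
    v_idx = np.array([idx for idx, _ in paired_valleys])
    v_val = np.array([val for _, val in paired_valleys])
    ext = ExtremaSet(
        peak_indices=p_idx, peak_values=np.asarray(peaks, float),
        valley_indices=v_idx, valley_values=v_val,
    )
    ext.paired_valley_indices = v_idx
    ext.paired_valley_values = v_val
    return ext


class TestDetectRunning:
    def test_running_burst_recognized(self):
        # peaks 32,35,33,31 with interior valleys 22,24,23, closed by a peak of 10
        ext = make_extrema(
            [32, 35, 33, 31, 10],
            [(17, 22), (31, 24), (45, 23), (70, 8), (75, 8)],
        )
        wins = detect_running(ext, ThresholdConfig())
        assert len(wins) == 1
        w = wins[0]
        assert w.label == RUNNING
        assert (w.start_index, w.end_index) == (10, 66)  # opening to closing peak
        assert w.peak_ids == [0, 1, 2, 3]
        assert w.W == 56

    def test_no_window_when_thr1_never_crossed(self):
        ext = make_extrema([25, 28, 30], [(17, 20), (31, 21), (45, 8)])
        assert detect_running(ext, ThresholdConfig()) == []

    def test_low_interior_valley_rejects_running_label(self):
        # one interior valley at 15 < thr4: window detected but not running
        ext = make_extrema(
            [32, 35, 33, 10],
            [(17, 22), (31, 15), (55, 8), (60, 8)],
        )
        wins = detect_running(ext, ThresholdConfig())
        assert len(wins) == 1 and wins[0].label is None

    def test_pair_condition_reduced_form_is_equivalent(self, rng):
        # acc_p - acc_v < acc_p - thr4  <=>  acc_v > thr4
        p = rng.uniform(10, 50, 200)
        v = rng.uniform(0, 40, 200)
        thr4 = 20.0
        np.testing.assert_array_equal((p - v) < (p - thr4), v > thr4)

    def test_open_at_series_end_is_truncated(self):
        ext = make_extrema([32, 35], [(17, 22), (31, 24)])
        wins = detect_running(ext, ThresholdConfig(), signal=np.full(60, 25.0))
        assert len(wins) == 1 and wins[0].truncated

    def test_closes_on_raw_sample_below_thr3(self):
        # no closing peak exists, but the signal dips under 12 at sample 40
        sig = np.full(80, 25.0)
        sig[40] = 9.0
        ext = make_extrema([32, 35], [(17, 22), (31, 24)])
        wins = detect_running(ext, ThresholdConfig(), signal=sig)
        assert wins[0].end_index == 40 and not wins[0].truncated

    def test_injected_burst_recovered_on_synthetic_trace(self):
        specs = [SegmentSpec("walk", 10 * 29 / 32), SegmentSpec("run", 8.0),
                 SegmentSpec("walk", 10 * 29 / 32)]
        series, truth = generate(specs, seed=7)
        _, results = count_steps(series)
        running = [w for w in results[0].windows if w.label == RUNNING]
        assert len(running) == 1
        seg = truth.segments[1]
        overlap = (min(running[0].end_index, seg.end_index)
                   - max(running[0].start_index, seg.start_index))
        assert overlap >= 0.9 * (seg.end_index - seg.start_index)


class TestLegShakeCandidates:
    def _signal(self, n=60, drop_at=40):
        sig = np.full(n, 13.0)
        sig[drop_at:] = 9.0
        return sig

    def test_shake_burst_is_candidate(self):
        ext = make_extrema([14, 16, 15], [(15, 13), (25, 13), (45, 9)], spacing=10)
        wins = detect_leg_shake_candidates(ext, self._signal(), ThresholdConfig())
        assert len(wins) == 1
        assert wins[0].start_index == 10 and wins[0].end_index == 40
        assert wins[0].peak_ids == [0, 1, 2]

    def test_regional_peak_restriction(self):
        # one peak above thr8=39 means running-scale motion, not shaking
        ext = make_extrema([14, 45, 15], [(15, 13), (25, 13), (45, 9)], spacing=10)
        assert detect_leg_shake_candidates(ext, self._signal(), ThresholdConfig()) == []

    def test_empty_extrema_gives_empty_list(self):
        ext = make_extrema([], [])
        assert detect_leg_shake_candidates(ext, self._signal(), ThresholdConfig()) == []

    def test_candidate_overlapping_running_window_discarded(self):
        ext = make_extrema([14, 16, 15], [(15, 13), (25, 13), (45, 9)], spacing=10)
        rw = BehaviorWindow(start_index=0, end_index=50, label=RUNNING)
        wins = detect_leg_shake_candidates(ext, self._signal(), ThresholdConfig(),
                                           running_windows=[rw])
        assert wins == []

    def test_isolated_pulse_without_pairs_is_not_a_candidate(self):
        # a lone walking pulse encloses no peak-valley pair
        sig = np.full(30, 9.0)
        sig[8:13] = [13, 15, 17, 15, 13]
        ext = make_extrema([17], [(20, 9)], first=10)
        assert detect_leg_shake_candidates(ext, sig, ThresholdConfig()) == []


class TestClassifyCandidate:
    def _window(self, n):
        return BehaviorWindow(start_index=0, end_index=n)

    def test_high_variance_is_leg_shake(self):
        v = np.sqrt(26.88633)
        gyro = np.tile([v, -v], 32)  # population variance 26.89
        assert classify_candidate(self._window(64), gyro) == LEG_SHAKE

    def test_constant_gyro_is_fast_walk(self):
        assert classify_candidate(self._window(64), np.full(64, 0.5)) == FAST_WALK

    def test_variance_exactly_at_cut_is_fast_walk(self):
        # population variance exactly 10 (float-exact): the cut is strict >
        gyro = np.tile([-4.0, -2.0, 2.0, 4.0], 16)
        assert np.var(gyro) == 10.0
        assert classify_candidate(self._window(64), gyro) == FAST_WALK

    def test_degenerate_window_warns_fast_walk(self):
        with pytest.warns(UserWarning, match="shorter"):
            label = classify_candidate(BehaviorWindow(0, 1), np.array([1.0, 2.0]))
        assert label == FAST_WALK

    def test_perfect_recovery_at_default_variance_separation(self, rng):
        for target, expected in ((2.0, FAST_WALK), (30.0, LEG_SHAKE)):
            for _ in range(10):
                gyro = rng.normal(0, np.sqrt(target), 160)
                # normalize the draw so the population variance is exact
                gyro = (gyro - gyro.mean()) / gyro.std() * np.sqrt(target)
                assert classify_candidate(self._window(160), gyro) == expected


class TestExtractFeatures:
    def test_constant_window_convention(self):
        with pytest.warns(UserWarning, match="constant"):
            f = extract_features([1.0, 1.0, 1.0, 1.0])
        assert (f.mean, f.var, f.std, f.kurt, f.skew) == (1, 0, 0, 0, 0)

    def test_two_point_window(self):
        f = extract_features([0.0, 2.0])
        assert f.mean == 1.0 and f.var == 1.0

    def test_matches_direct_summation_oracle(self, rng):
        x = rng.normal(2, 3, 64)
        f = extract_features(x)
        oracle = brute_force_moments(x)
        for name in ("mean", "var", "std", "kurt", "skew"):
            assert getattr(f, name) == pytest.approx(oracle[name], abs=1e-9)

    def test_std_squared_equals_var(self, rng):
        f = extract_features(rng.normal(0, 5, 32))
        assert f.std**2 == pytest.approx(f.var, abs=1e-9)


class TestClusterBehaviors:
    def test_separated_blobs_recovered_exactly(self, rng):
        pts = np.concatenate([rng.normal(mu, 0.1, 30) for mu in (-10, 0, 10)])
        labels, centroids = cluster_behaviors(pts.reshape(-1, 1), k=3, seed=0)
        blobs = [set(labels[i * 30:(i + 1) * 30]) for i in range(3)]
        assert all(len(b) == 1 for b in blobs)
        assert len(set.union(*blobs)) == 3
        assert sorted(centroids.ravel().round(1)) == [-10.0, 0.0, 10.0]

    def test_k_equals_one_gives_global_mean(self, rng):
        pts = rng.normal(3, 1, (20, 2))
        _, centroids = cluster_behaviors(pts, k=1, seed=0)
        np.testing.assert_allclose(centroids[0], pts.mean(axis=0), atol=1e-9)

    def test_fewer_rows_than_k_rejected(self):
        with pytest.raises(ValueError):
            cluster_behaviors(np.zeros((2, 5)), k=3)

    def test_deterministic_given_seed(self, rng):
        pts = rng.normal(0, 1, (30, 5))
        a = cluster_behaviors(pts, k=3, seed=42)
        b = cluster_behaviors(pts, k=3, seed=42)
        assert np.array_equal(a[0], b[0])


class TestClassificationMetrics:
    def test_perfect_prediction(self):
        m = classification_metrics([1, 1, 0, 0], [1, 1, 0, 0])
        assert (m.accuracy, m.precision, m.recall) == (1.0, 1.0, 1.0)

    def test_direct_substitution(self):
        # TP=9, FP=1, FN=1, TN=9
        actual = [1] * 10 + [0] * 10
        pred = [1] * 9 + [0] + [1] + [0] * 9
        m = classification_metrics(pred, actual)
        assert m.accuracy == pytest.approx(0.9)
        assert m.precision == pytest.approx(0.9)
        assert m.recall == pytest.approx(0.9)

    def test_undefined_precision_is_flagged(self):
        m = classification_metrics([0, 0, 0], [0, 0, 0])
        assert not m.precision_defined and not m.recall_defined
        assert m.accuracy == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics([1], [1, 0])

    @given(tp=st.integers(0, 20), tn=st.integers(0, 20),
           fp=st.integers(0, 20), fn=st.integers(0, 20))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_accuracy_identity_over_random_confusions(self, tp, tn, fp, fn):
        total = tp + tn + fp + fn
        if total == 0:
            return
        actual = [1] * tp + [0] * fp + [1] * fn + [0] * tn
        pred = [1] * tp + [1] * fp + [0] * fn + [0] * tn
        m = classification_metrics(pred, actual)
        assert (m.tp, m.tn, m.fp, m.fn) == (tp, tn, fp, fn)
        assert m.accuracy == pytest.approx((tp + tn) / total)
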