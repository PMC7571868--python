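"""Core metric tests: ensemble averaging, window enumeration, WFMR algebra.

The independent oracles here are deliberately naive: explicit Python loops
for the pairwise sums and exhaustive window enumeration, never the vectorized
production path.
"""

import numpy as np
import pytest

from wfmr import metric
from wfmr.beats import BeatSet, Epoch
from wfmr.errors import EpochInvalidError, InputError
from wfmr.metric import EnsembleSet


def naive_mse(f, g):
    total = 0.0
    for a, b in zip(f, g):
        total += (a - b) ** 2
    return total


def naive_wfmr(waveforms):
    n = len(waveforms)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                total += naive_mse(waveforms[i], waveforms[j])
    return np.log(max(total / (n * (n - 1)), metric.WFMR_EPS))


def _epoch(start=0.0, admitted=(), dominant="intrinsic", duration=20.0):
    return Epoch(start=start, duration=duration,
                 admitted=np.asarray(admitted, dtype=int), dominant_type=dominant)


def _dense_beat_set(rr=1.0, length=300.0):
    r = np.arange(0.5, length - 1.0, rr)
    crops = np.random.default_rng(0).normal(size=(len(r), 700))
    return BeatSet(r, np.asarray(["intrinsic"] * len(r), object), crops)


class TestEnsembleAverage:
    def test_identical_beats_pass_through(self):
        b = np.random.default_rng(1).normal(size=700)
        out = metric.ensemble_average(np.tile(b, (7, 1)))
        assert np.allclose(out, b, rtol=1e-14)

    def test_arithmetic_mean_of_two(self):
        out = metric.ensemble_average(np.array([[1.0] * 700, [3.0] * 700]))
        assert np.allclose(out, 2.0)

    def test_noise_suppression_follows_clt(self, rng):
        template = rng.normal(size=700)
        sigma = 0.5
        beats = template + rng.normal(0, sigma, size=(30, 700))
        resid = metric.ensemble_average(beats) - template
        assert resid.std() == pytest.approx(sigma / np.sqrt(30), rel=0.25)

    def test_empty_window_rejected(self):
        with pytest.raises(EpochInvalidError):
            metric.ensemble_average(np.empty((0, 700)))


class TestWindowEnumeration:
    @pytest.mark.parametrize("t_ea,expected", [(8.0, 12), (5.0, 15), (2.0, 18),
                                               (15.0, 5)])
    def test_dense_beats_window_count(self, t_ea, expected):
        bs = _dense_beat_set(rr=0.8)
        epoch = _epoch(admitted=np.flatnonzero((bs.r_times >= 0) & (bs.r_times < 20)))
        assert len(metric.window_beat_sets(epoch, bs.r_times, t_ea)) == expected

    def test_sparse_epoch_collapses_duplicates(self):
        # a single beat 2 s into the epoch: windows starting at 0, 1, 2 s all
        # hold exactly that beat, so only the first survives; the rest are
        # empty and dropped
        r = np.array([2.0])
        epoch = _epoch(admitted=[0])
        sets = metric.window_beat_sets(epoch, r, 8.0)
        assert len(sets) == 1
        assert sets[0].tolist() == [0]

    def test_exhaustive_enumeration_agreement(self):
        # oracle: brute-force sets per start, then manual dedupe in order
        rng = np.random.default_rng(5)
        r = np.sort(rng.uniform(0, 20, size=9))
        epoch = _epoch(admitted=np.arange(9))
        t_ea = 6.0
        expected, seen = [], set()
        for k in range(int(20 - t_ea)):
            members = tuple(i for i in range(9) if k <= r[i] < k + t_ea)
            if members and members not in seen:
                seen.add(members)
                expected.append(list(members))
        got = [s.tolist() for s in metric.window_beat_sets(epoch, r, t_ea)]
        assert got == expected

    def test_out_of_range_window_rejected(self):
        with pytest.raises(InputError):
            metric.window_beat_sets(_epoch(admitted=[0]), np.array([1.0]), 16.0)


class TestMse:
    def test_self_distance_zero(self, rng):
        f = rng.normal(size=700)
        assert metric.mse(f, f) == 0.0

    def test_toy_hand_value(self):
        assert metric.mse(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 2.0

    def test_matches_naive_loop(self, rng):
        f, g = rng.normal(size=(2, 700))
        assert metric.mse(f, g) == pytest.approx(naive_mse(f, g), rel=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            metric.mse(np.zeros(700), np.zeros(699))


def _es(waveforms, t_ea=8.0):
    w = np.asarray(waveforms, dtype=float)
    return EnsembleSet(epoch=_epoch(admitted=np.arange(w.shape[0])), t_ea=t_ea,
                       waveforms=w,
                       beat_index_sets=[np.array([i]) for i in range(w.shape[0])])


class TestWfmrEpoch:
    def test_identical_waveforms_hit_floor(self):
        w = np.tile(np.random.default_rng(2).normal(size=700), (5, 1))
        assert metric.wfmr_epoch(_es(w)) == pytest.approx(np.log(metric.WFMR_EPS))

    def test_pair_with_known_mse(self):
        # two waveforms at squared distance e^2 -> WFMR = ln(e^2) = 2
        f = np.zeros(700)
        g = np.zeros(700)
        g[0] = np.e
        assert metric.wfmr_epoch(_es([f, g])) == pytest.approx(2.0, rel=1e-12)

    def test_matches_naive_double_loop(self, rng):
        w = rng.normal(size=(12, 700))
        assert metric.wfmr_epoch(_es(w)) == pytest.approx(naive_wfmr(w), rel=1e-9)

    def test_single_waveform_rejected(self, rng):
        with pytest.raises(EpochInvalidError):
            metric.wfmr_epoch(_es(rng.normal(size=(1, 700))))

    def test_permutation_invariance(self, rng):
        w = rng.normal(size=(8, 700))
        perm = rng.permutation(8)
        assert metric.wfmr_epoch(_es(w)) == pytest.approx(
            metric.wfmr_epoch(_es(w[perm])), rel=1e-12)

    def test_shift_invariance(self, rng):
        w = rng.normal(size=(6, 700))
        assert metric.wfmr_epoch(_es(w + 17.3)) == pytest.approx(
            metric.wfmr_epoch(_es(w)), rel=1e-9)

    def test_scale_law(self, rng):
        w = rng.normal(size=(6, 700))
        a = 2.5
        assert metric.wfmr_epoch(_es(a * w)) == pytest.approx(
            metric.wfmr_epoch(_es(w)) + 2 * np.log(a), rel=1e-9)


class TestSweepAndElbow:
    def test_single_subject_single_epoch_curve(self):
        bs = _dense_beat_set(rr=0.8)
        epoch = _epoch(admitted=np.flatnonzero(bs.r_times < 20))
        res = metric.wfmr_subject(bs, [epoch], sweep=True)
        curve = metric.wfmr_sweep([res])
        assert len(curve) == 14
        for t, v in curve:
            assert v == pytest.approx(float(res.sweep[t][0]))

    def test_subjects_weighted_equally(self):
        # oracle: hand computation on a 2-subject toy with unequal epoch counts
        r1 = metric.WfmrResult("a", 8.0, np.array([1.0]), np.array([12]),
                               sweep={float(t): np.array([1.0])
                                      for t in metric.SWEEP_WINDOWS})
        r2 = metric.WfmrResult("b", 8.0, np.array([3.0, 5.0]), np.array([12, 12]),
                               sweep={float(t): np.array([3.0, 5.0])
                                      for t in metric.SWEEP_WINDOWS})
        curve = metric.wfmr_sweep([r1, r2])
        for _, v in curve:
            assert v == pytest.approx((1.0 + 4.0) / 2)  # not mean(1,3,5) = 3

    def test_sweep_decreases_with_window_size_on_average(self):
        # more beats per ensemble average -> less residual fluctuation
        from wfmr import pipeline
        curves = []
        for seed in range(6):
            cfg_vals = pipeline.subject_wfmr_fast  # noqa: F841  (fast path reused)
            from wfmr import beats as beats_mod, preprocess, simulate
            cfg = simulate.draw_subject_config("nonclinical", seed)
            rng = np.random.default_rng(seed)
            r, lab = simulate.simulate_beat_times(cfg, rng)
            bcg, _ = simulate.simulate_bcg(cfg, r, lab, rng=rng)
            bcg = preprocess.fir_filter(bcg, preprocess.HIGHPASS_2HZ)
            bs = beats_mod.BeatSet.from_record(bcg, r, lab)
            eps = beats_mod.select_epochs(bs, n_epochs=3, record_length=bcg.duration)
            res = metric.wfmr_subject(bs, eps, sweep=True)
            curves.append([v for _, v in metric.wfmr_sweep([res])])
        mean_curve = np.mean(curves, axis=0)
        assert mean_curve[0] > mean_curve[-1]
        # largely decreasing: at least 11 of 13 increments go down
        assert np.sum(np.diff(mean_curve) < 0) >= 11

    def test_elbow_on_convex_toy_curve(self):
        vs = [10.0, 6.0, 4.0, 3.0, 2.9, 2.85, 2.85]
        curve = list(zip(range(2, 2 + len(vs)), vs))
        assert metric.select_optimal_window(curve) == 5.0  # the 4th point

    def test_flat_curve_prefers_smallest_window(self):
        curve = [(t, 1.0) for t in range(2, 16)]
        assert metric.select_optimal_window(curve) == 2.0

    def test_linear_curve_has_no_elbow(self):
        curve = [(t, -0.5 * t) for t in range(2, 16)]
        assert metric.select_optimal_window(curve) == 15.0

    def test_nonfinite_curve_rejected(self):
        with pytest.raises(InputError):
            metric.select_optimal_window([(2, 1.0), (3, np.nan), (4, 0.0)])
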