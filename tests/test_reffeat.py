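"""Reference-feature tests: delineation, intervals, BP correction, windowing."""

import numpy as np
import pytest

import wfmr
from wfmr import metric, reffeat
from wfmr.beats import Epoch
from wfmr.errors import InputError
from wfmr.records import SignalRecord


class TestDelineate:
    def test_clean_simulated_ecg_accuracy(self, clean_ecg_with_truth):
        ecg, truth = clean_ecg_with_truth
        q, s, te, ok = reffeat.delineate(ecg, truth.r_times)
        within = (ok
                  & (np.abs(q - truth.q_times) < 0.010)
                  & (np.abs(s - truth.s_times) < 0.010)
                  & (np.abs(te - truth.tend_times) < 0.020))
        assert within.mean() >= 0.90

    def test_flat_t_wave_flagged(self):
        # R spikes with no T wave at all: T-end must be indeterminate
        fs = 1000.0
        x = np.zeros(int(10 * fs))
        r = np.arange(1.0, 9.0, 1.0)
        t_ax = np.arange(x.size) / fs
        for rt in r:
            x += np.exp(-0.5 * ((t_ax - rt) / 0.011) ** 2)
        _, _, _, ok = reffeat.delineate(SignalRecord("ecg", x, fs), r)
        assert not ok.any()

    def test_pvc_measures_wide_qrs(self):
        cfg = wfmr.SubjectSimConfig(pvc_prob=1.0, noise_sd=0.0, seed=9)
        ecg, truth = wfmr.simulate_ecg(cfg)
        q, s, _, ok = reffeat.delineate(ecg, truth.r_times)
        widths = (s - q)[ok]
        assert np.all(widths >= 0.120)


class TestBeatIntervals:
    def test_correction_vanishes_at_rr_one_second(self):
        assert reffeat.qt_corrected(0.400, 1.0) == pytest.approx(0.400)

    def test_correction_hand_value(self):
        # QT 0.400 s at RR 0.8 s: 0.400 + 0.154 * 0.2 = 0.4308
        assert reffeat.qt_corrected(0.400, 0.8) == pytest.approx(0.4308)

    def test_correction_slope_in_rr(self, rng):
        qt = 0.38
        rr = rng.uniform(0.5, 1.2, size=20)
        qtc = reffeat.qt_corrected(qt, rr)
        slope = np.polyfit(rr, qtc, 1)[0]
        assert slope == pytest.approx(-0.154, rel=1e-9)

    def test_narrow_qrs_leaves_qt_unchanged(self):
        r = np.array([1.0, 2.0])
        q = r - 0.04
        s = r + 0.06   # QRS = 100 ms < 120 ms
        te = q + 0.40
        iv = reffeat.beat_intervals(r, q, s, te)
        assert np.allclose(iv.qt_qrs, iv.qt_base)

    def test_wide_qrs_excess_removed(self):
        r = np.array([1.0, 2.0])
        q = r - 0.07
        s = r + 0.08   # QRS = 150 ms -> 30 ms excess
        te = q + 0.46
        iv = reffeat.beat_intervals(r, q, s, te)
        assert np.allclose(iv.qt_qrs, iv.qt_base - 0.030)
        assert np.all(iv.qt_qrs <= iv.qt_base)

    def test_rr_undefined_for_first_beat(self):
        r = np.array([1.0, 2.1, 3.0])
        iv = reffeat.beat_intervals(r, r - 0.04, r + 0.04, r + 0.36)
        assert np.isnan(iv.rr[0])
        assert iv.rr[1] == pytest.approx(1.1)


class TestBpOffsetCorrection:
    def test_simulator_offset_recovered(self):
        cfg = wfmr.SubjectSimConfig(bp_device_offset_mmhg=-12.0, seed=31)
        r = np.arange(0.5, 299.0, 0.9)
        sbp, _, ct, cs, _, truth = wfmr.simulate_bp(r, cfg, np.random.default_rng(31))
        corrected, constant = reffeat.bp_offset_correction(r, sbp, ct, cs)
        assert constant == pytest.approx(12.0, abs=1.0)
        assert abs(np.mean(corrected - truth.true_sbp)) < 1.0

    def test_zero_offset_zero_noise(self):
        bt = np.arange(0.5, 299.0, 1.0)
        dev = np.full_like(bt, 120.0)
        ct = np.arange(60.0, 301.0, 60.0)
        corrected, constant = reffeat.bp_offset_correction(
            bt, dev, ct, np.full_like(ct, 120.0))
        assert constant == 0.0
        assert np.array_equal(corrected, dev)

    def test_five_cuffs_give_five_differences(self):
        bt = np.arange(0.5, 299.0, 1.0)
        dev = np.full_like(bt, 100.0)
        ct = np.arange(60.0, 301.0, 60.0)
        cuffs = np.array([101.0, 102.0, 103.0, 104.0, 105.0])
        _, constant = reffeat.bp_offset_correction(bt, dev, ct, cuffs)
        assert constant == pytest.approx(3.0)  # mean of 1..5

    def test_all_windows_empty_is_an_error(self):
        with pytest.raises(InputError):
            reffeat.bp_offset_correction(np.array([500.0]), np.array([100.0]),
                                         np.array([60.0]), np.array([120.0]))


class TestWindowedStats:
    def _epoch(self, admitted, start=0.0):
        return Epoch(start=start, duration=20.0,
                     admitted=np.asarray(admitted, int), dominant_type="intrinsic")

    def test_dense_epoch_yields_twelve_window_means(self):
        r = np.arange(0.5, 20.0, 0.8)
        feat = np.full_like(r, 0.1)
        epoch = self._epoch(np.arange(len(r)))
        stats = reffeat.windowed_stats(feat, r, [epoch], t_ea=8.0)
        assert len(stats[0].window_means) == 12

    def test_window_counts_match_ensemble_windowing(self, rng):
        r = np.sort(rng.uniform(0, 20, size=17))
        epoch = self._epoch(np.arange(len(r)))
        for t_ea in (3.0, 8.0, 12.0):
            n_metric = len(metric.window_beat_sets(epoch, r, t_ea))
            stats = reffeat.windowed_stats(np.abs(rng.normal(size=len(r))) + 1.0,
                                           r, [epoch], t_ea)
            assert len(stats[0].window_means) == n_metric

    def test_constant_feature_sd_floored(self):
        r = np.arange(0.5, 20.0, 0.8)
        stats = reffeat.windowed_stats(np.full_like(r, 0.42), r,
                                       [self._epoch(np.arange(len(r)))], 8.0)
        st = stats[0]
        assert st.mean_log == pytest.approx(np.log(0.42))
        assert st.sd_log == pytest.approx(np.log(metric.WFMR_EPS))

    def test_hand_built_toy_epoch(self):
        # beats at 1, 6, 13 s with T_EA = 8 s; enumerating starts 0..11 by
        # hand gives the distinct member sets {0,1}, {1}, {1,2}, {2}
        r = np.array([1.0, 6.0, 13.0])
        feat = np.array([2.0, 4.0, 8.0])
        epoch = self._epoch([0, 1, 2])
        stats = reffeat.windowed_stats(feat, r, [epoch], 8.0)
        means = stats[0].window_means
        assert means.tolist() == [3.0, 4.0, 6.0, 8.0]
        assert stats[0].mean_log == pytest.approx(np.log(np.mean([3, 4, 6, 8])))
        assert stats[0].sd_log == pytest.approx(
            np.log(np.std([3, 4, 6, 8], ddof=1)))

    def test_nan_features_left_out_of_window_means(self):
        r = np.arange(0.5, 20.0, 1.0)
        feat = np.full_like(r, 5.0)
        feat[3] = np.nan
        stats = reffeat.windowed_stats(feat, r, [self._epoch(np.arange(len(r)))], 8.0)
        assert np.allclose(stats[0].window_means, 5.0)
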