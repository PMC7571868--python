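"""Generator unit tests: determinism, jitter calibration, ground-truth sanity."""

import numpy as np
import pytest

import wfmr
from wfmr import simulate
from wfmr.errors import ConfigurationError, InputError


def _cfg(**kw) -> wfmr.SubjectSimConfig:
    return wfmr.SubjectSimConfig(**kw)


class TestBeatTimes:
    def test_jitter_free_rr_is_constant(self):
        cfg = _cfg(rr_jitter_sd_s=0.0, pvc_prob=0.0, paced_fraction=0.0,
                   mean_hr_bpm=60.0)
        r, types = simulate.simulate_beat_times(cfg, np.random.default_rng(0))
        assert np.allclose(np.diff(r), 1.0, atol=1e-3)
        assert all(t == "intrinsic" for t in types)

    def test_rr_floor_enforced(self):
        cfg = _cfg(mean_hr_bpm=150.0, rr_jitter_sd_s=0.3)
        r, _ = simulate.simulate_beat_times(cfg, np.random.default_rng(0))
        assert np.diff(r).min() >= simulate.RR_FLOOR - 1e-12


class TestEcg:
    def test_study_protocol_sample_count(self):
        ecg, _ = wfmr.simulate_ecg(_cfg(recording_length_s=300.0, fs_hz=1000.0))
        assert ecg.n == 300_000

    def test_seeded_runs_are_bit_identical(self):
        a, _ = wfmr.simulate_ecg(_cfg(seed=5))
        b, _ = wfmr.simulate_ecg(_cfg(seed=5))
        assert np.array_equal(a.samples, b.samples)

    def test_r_times_sit_on_ecg_maxima(self, clean_ecg_with_truth):
        ecg, truth = clean_ecg_with_truth
        for rt in truth.r_times[1:-1]:
            i = int(round(rt * ecg.fs))
            w = ecg.samples[i - 30:i + 31]
            assert abs(int(np.argmax(w)) - 30) <= 1

    def test_fiducials_ordered(self, clean_ecg_with_truth):
        _, truth = clean_ecg_with_truth
        assert np.all(truth.q_times < truth.r_times)
        assert np.all(truth.r_times < truth.s_times)
        assert np.all(truth.s_times < truth.tend_times)

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigurationError, match="rr_jitter_sd_s"):
            wfmr.simulate_ecg(_cfg(rr_jitter_sd_s=-1.0))
        with pytest.raises(ConfigurationError, match="fs_hz"):
            wfmr.simulate_ecg(_cfg(fs_hz=0.0))


class TestBcg:
    def test_degenerate_config_repeats_template(self):
        cfg = _cfg(amplitude_jitter_sd=0.0, phase_jitter_sd_s=0.0,
                   shape_innovation_sd=0.0, resp_mod_depth=0.0,
                   noise_sd=0.0, drift_sd=0.0)
        r = np.arange(0.5, 119.0, 1.0)
        bcg, _ = wfmr.simulate_bcg(cfg, r, rng=np.random.default_rng(0))
        crops = np.stack([bcg.samples[int(t * 1000):int(t * 1000) + 700]
                          for t in r[:-1]])
        assert np.allclose(crops, crops[0], atol=1e-9)

    def test_amplitude_jitter_scales_peak_sd(self):
        # doubling the lognormal sigma should roughly double the SD of the
        # per-beat peak amplitude (oracle: direct moments of the peak series)
        r = np.arange(0.5, 250.0, 1.0)[:200]
        sds = []
        for sigma in (0.1, 0.2):
            cfg = _cfg(amplitude_jitter_sd=sigma, phase_jitter_sd_s=0.0,
                       shape_innovation_sd=0.0, resp_mod_depth=0.0,
                       noise_sd=0.0, drift_sd=0.0, recording_length_s=260.0)
            bcg, _ = wfmr.simulate_bcg(cfg, r, rng=np.random.default_rng(9))
            peaks = [bcg.samples[int(t * 1000):int(t * 1000) + 700].max() for t in r]
            sds.append(np.std(peaks))
        assert sds[1] / sds[0] == pytest.approx(2.0, rel=0.25)

    def test_respiratory_envelope_recoverable(self):
        cfg = _cfg(amplitude_jitter_sd=0.0, phase_jitter_sd_s=0.0,
                   shape_innovation_sd=0.0, resp_mod_depth=0.2,
                   resp_rate_hz=0.25, noise_sd=0.0, drift_sd=0.0)
        r = np.arange(0.5, 119.0, 0.9)
        bcg, _ = wfmr.simulate_bcg(cfg, r, rng=np.random.default_rng(1))
        peaks = np.array([bcg.samples[int(t * 1000):int(t * 1000) + 700].max()
                          for t in r])
        # least-squares fit of a 0.25 Hz sinusoid to the peak series
        design = np.column_stack([np.sin(2 * np.pi * 0.25 * r),
                                  np.cos(2 * np.pi * 0.25 * r),
                                  np.ones_like(r)])
        resid = peaks - design @ np.linalg.lstsq(design, peaks, rcond=None)[0]
        r2 = 1 - resid.var() / peaks.var()
        assert r2 > 0.9

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            wfmr.simulate_bcg(_cfg(), np.array([1.0, 2.0]), ["intrinsic"])

    def test_fluctuation_dial_monotone(self):
        # beat-to-beat crop variance must not decrease as jitter grows
        r = np.arange(0.5, 110.0, 1.0)[:100]
        variances = []
        for sigma in (0.05, 0.15, 0.3):
            cfg = _cfg(amplitude_jitter_sd=sigma, phase_jitter_sd_s=0.0,
                       shape_innovation_sd=0.0, resp_mod_depth=0.0,
                       noise_sd=0.0, drift_sd=0.0)
            bcg, _ = wfmr.simulate_bcg(cfg, r, rng=np.random.default_rng(3))
            crops = np.stack([bcg.samples[int(t * 1000):int(t * 1000) + 700]
                              for t in r])
            variances.append(crops.var(axis=0).mean())
        assert variances[0] < variances[1] < variances[2]


class TestBp:
    def test_zero_offset_zero_noise_is_identity(self):
        cfg = _cfg(bp_device_offset_mmhg=0.0, bp_noise_sd_mmhg=0.0)
        r = np.arange(0.5, 299.0, 1.0)
        sbp, dbp, *_, truth = wfmr.simulate_bp(r, cfg, np.random.default_rng(0))
        assert np.allclose(sbp, truth.true_sbp)
        assert np.allclose(dbp, truth.true_dbp)

    def test_injected_offset_visible_in_mean(self):
        cfg = _cfg(bp_device_offset_mmhg=12.0)
        r = np.arange(0.5, 299.0, 1.0)
        sbp, *_ , truth = wfmr.simulate_bp(r, cfg, np.random.default_rng(0))
        assert np.mean(sbp - truth.true_sbp) == pytest.approx(12.0, abs=0.3)

    def test_five_minute_record_gives_five_cuffs(self):
        r = np.arange(0.5, 299.0, 1.0)
        *_, cuff_t, cuff_s, cuff_d, _ = wfmr.simulate_bp(r, _cfg())
        assert len(cuff_t) == len(cuff_s) == len(cuff_d) == 5


class TestSubjectsAndCohort:
    def test_nonclinical_profile_has_no_ectopy(self, nonclinical_subject):
        assert set(nonclinical_subject.truth.beat_types) == {"intrinsic"}

    def test_same_seed_same_subject(self):
        a = wfmr.simulate_subject("clinical", seed=3)
        b = wfmr.simulate_subject("clinical", seed=3)
        assert np.array_equal(a.bcg.samples, b.bcg.samples)
        assert np.array_equal(a.ecg.samples, b.ecg.samples)
        assert np.array_equal(a.device_sbp, b.device_sbp)

    def test_unknown_profile_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown profile"):
            wfmr.simulate_subject("outpatient", seed=1)

    def test_study_design_cohort_sizes(self):
        seeds_n, seeds_c = simulate.cohort_seeds(1, 29, 26)
        assert len(seeds_n) == 29 and len(seeds_c) == 26
        assert all(0 <= s < 2 ** 31 for s in seeds_n + seeds_c)
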