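# Default simulation profiles for the two study populations.
#
# Every numeric entry is either a fixed value (same for all subjects) or a
# two-element [low, high] range sampled uniformly once per subject, so the
# clinical cohort draws its beat-to-beat jitter from a wider prior than the
# non-clinical cohort.  Units are noted per field; fractions are in [0, 1].
#
# The clinical profile is deliberately *qualitative*: it reproduces the
# direction and rough magnitude of the clinical/non-clinical fluctuation
# contrast (larger amplitude/phase/shape jitter, occasional ectopy, some
# pacemaker subjects), not any subject-level measurement.

nonclinical:
  recording_length_s: 300.0
  fs_hz: 1000.0
  mean_hr_bpm: [58.0, 78.0]
  rr_jitter_sd_s: [0.02, 0.05]
  amplitude_jitter_sd: [0.03, 0.07]       # lognormal sigma of per-beat scale
  phase_jitter_sd_s: [0.002, 0.006]       # per-component timing shift SD
  shape_ar_coef: 0.7
  shape_innovation_sd: [0.01, 0.03]       # AR(1) innovation on component gains
  resp_rate_hz: [0.2, 0.3]
  resp_mod_depth: [0.05, 0.15]
  pvc_prob: 0.0
  paced_subject_prob: 0.0
  paced_fraction: 0.0
  pacing_spike_amplitude: 2.5             # ECG units, relative to R ~ 1
  noise_sd: 0.05                          # white noise, BCG force units
  drift_sd: 0.10                          # low-frequency baseline wander
  sbp_mean_mmhg: [105.0, 130.0]
  sbp_sd_mmhg: 4.0
  dbp_mean_mmhg: [65.0, 85.0]
  dbp_sd_mmhg: 3.0
  bp_device_offset_mmhg: [-15.0, 15.0]
  bp_noise_sd_mmhg: 1.0

clinical:
  recording_length_s: 300.0
  fs_hz: 1000.0
  mean_hr_bpm: [55.0, 85.0]
  rr_jitter_sd_s: [0.03, 0.08]
  amplitude_jitter_sd: [0.15, 0.35]
  phase_jitter_sd_s: [0.010, 0.030]
  shape_ar_coef: 0.8
  shape_innovation_sd: [0.05, 0.12]
  resp_rate_hz: [0.2, 0.3]
  resp_mod_depth: [0.10, 0.25]
  pvc_prob: [0.0, 0.06]
  paced_subject_prob: 0.3
  paced_fraction: 0.97
  pacing_spike_amplitude: 2.5
  noise_sd: 0.05
  drift_sd: 0.10
  sbp_mean_mmhg: [95.0, 140.0]
  sbp_sd_mmhg: 5.0
  dbp_mean_mmhg: [60.0, 90.0]
  dbp_sd_mmhg: 4.0
  bp_device_offset_mmhg: [-15.0, 15.0]
  bp_noise_sd_mmhg: 1.0
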