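"""Synthetic seated-recording generator: BCG + ECG + blood pressure.

The study recordings this pipeline targets are not publicly available, so
every downstream stage is validated against this generator, which emulates a
five-minute stationary sitting recording: a quasi-periodic BCG built from the
canonical H/I/J/K/L/M/N wave sequence with controllable per-beat amplitude,
phase and shape jitter, respiratory amplitude modulation, baseline wander and
additive white noise; a surrogate ECG with intrinsic, pacemaker-driven and
premature-ventricular (PVC) beats and exact fiducial ground truth; and
beat-to-beat blood pressure with a constant device offset plus one cuff
reading per minute.

The generator is *not* a hemodynamic model.  Beat waves are Gaussian bumps;
only the ordering, sign pattern and jitter structure matter.  Clinical vs
non-clinical default parameter sets live in ``profiles.yaml`` next to this
module so the effect size used in the validation suite is auditable.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from typing import Sequence

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter1d

from .errors import ConfigurationError, InputError
from .records import SignalRecord

INTRINSIC, PACED, PVC = "intrinsic", "paced", "pvc"
BEAT_TYPES = (INTRINSIC, PACED, PVC)

#: minimum RR interval (s); keeps consecutive beats separable
RR_FLOOR = 0.35

# ---------------------------------------------------------------------------
# templates


@dataclasses.dataclass(frozen=True)
class BeatTemplate:
    """Sum-of-Gaussians beat morphology.

    ``components`` is a tuple of (center offset s, amplitude, width s)
    triples.  For the canonical BCG template the J wave carries the largest
    positive amplitude and all centers lie within the 0.7-s crop.
    """

    components: tuple[tuple[float, float, float], ...]
    beat_type: str = INTRINSIC

    def render(self, t: np.ndarray, center_shift: np.ndarray | None = None,
               gain: np.ndarray | None = None) -> np.ndarray:
        """Evaluate the template on time axis *t* (seconds, 0 = R wave)."""
        out = np.zeros_like(t, dtype=float)
        for k, (c, a, w) in enumerate(self.components):
            if center_shift is not None:
                c = c + center_shift[k]
            if gain is not None:
                a = a * gain[k]
            out += a * np.exp(-0.5 * ((t - c) / w) ** 2)
        return out


#: canonical seated-BCG morphology: H, I, J, K, L, M, N waves
BCG_TEMPLATE = BeatTemplate(components=(
    (0.10, 0.25, 0.018),   # H
    (0.15, -0.45, 0.016),  # I
    (0.21, 1.00, 0.020),   # J — largest positive deflection
    (0.27, -0.55, 0.022),  # K
    (0.34, 0.28, 0.030),   # L
    (0.42, -0.18, 0.035),  # M
    (0.50, 0.12, 0.040),   # N
))

#: weak-ejection variant used for PVC beats: lower amplitude, broader waves
BCG_TEMPLATE_PVC = BeatTemplate(components=tuple(
    (c, 0.6 * a, 1.2 * w) for c, a, w in BCG_TEMPLATE.components), beat_type=PVC)

# ECG component tables per beat type: (center offset s, amplitude, width s).
# The pacing spike is rendered separately so ground-truth QRS boundaries can
# be measured on the spike-free complex.
_ECG_SHAPES = {
    INTRINSIC: (
        (-0.160, 0.15, 0.025),   # P
        (-0.028, -0.12, 0.008),  # Q dip
        (0.000, 1.00, 0.011),    # R
        (0.028, -0.20, 0.008),   # S dip
        (0.300, 0.30, 0.050),    # T
    ),
    PVC: (
        (0.000, 1.30, 0.028),    # wide R, no P wave
        (0.055, -0.80, 0.018),   # deep slurred S
        (0.330, -0.35, 0.055),   # discordant T
    ),
    PACED: (
        (0.000, 0.90, 0.020),    # widened R, no P wave
        (0.045, -0.45, 0.014),   # S
        (0.320, 0.25, 0.050),    # T
    ),
}
_PACING_SPIKE = (-0.060, 0.0015)  # center offset s, width s; amplitude from config
_T_COMPONENT_INDEX = {INTRINSIC: 4, PVC: 2, PACED: 2}

# ---------------------------------------------------------------------------
# configuration


@dataclasses.dataclass
class SubjectSimConfig:
    """Per-subject generator parameters (all SDs >= 0, fractions in [0, 1])."""

    population: str = "nonclinical"
    recording_length_s: float = 300.0
    fs_hz: float = 1000.0
    mean_hr_bpm: float = 65.0
    rr_jitter_sd_s: float = 0.03
    amplitude_jitter_sd: float = 0.05
    phase_jitter_sd_s: float = 0.004
    shape_ar_coef: float = 0.7
    shape_innovation_sd: float = 0.02
    resp_rate_hz: float = 0.25
    resp_mod_depth: float = 0.1
    pvc_prob: float = 0.0
    paced_fraction: float = 0.0
    pacing_spike_amplitude: float = 2.5
    noise_sd: float = 0.05
    drift_sd: float = 0.10
    sbp_mean_mmhg: float = 120.0
    sbp_sd_mmhg: float = 4.0
    dbp_mean_mmhg: float = 75.0
    dbp_sd_mmhg: float = 3.0
    bp_device_offset_mmhg: float = 0.0
    bp_noise_sd_mmhg: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        sd_fields = ("rr_jitter_sd_s", "amplitude_jitter_sd", "phase_jitter_sd_s",
                     "shape_innovation_sd", "noise_sd", "drift_sd", "sbp_sd_mmhg",
                     "dbp_sd_mmhg", "bp_noise_sd_mmhg")
        for f in sd_fields:
            if getattr(self, f) < 0:
                raise ConfigurationError(f"{f} must be >= 0, got {getattr(self, f)}")
        for f in ("resp_mod_depth", "pvc_prob", "paced_fraction"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{f} must lie in [0, 1], got {v}")
        if self.fs_hz <= 0:
            raise ConfigurationError(f"fs_hz must be > 0, got {self.fs_hz}")
        if self.mean_hr_bpm <= 0:
            raise ConfigurationError(f"mean_hr_bpm must be > 0, got {self.mean_hr_bpm}")
        if self.resp_rate_hz <= 0:
            raise ConfigurationError(f"resp_rate_hz must be > 0, got {self.resp_rate_hz}")
        if self.recording_length_s < 120.0:
            raise ConfigurationError(
                f"recording_length_s must be >= 120 s, got {self.recording_length_s}")


@dataclasses.dataclass
class GroundTruth:
    """Simulator ground truth emitted alongside the signals."""

    r_times: np.ndarray
    beat_types: np.ndarray
    q_times: np.ndarray | None = None
    s_times: np.ndarray | None = None
    tend_times: np.ndarray | None = None
    true_sbp: np.ndarray | None = None
    true_dbp: np.ndarray | None = None
    clean_bcg: np.ndarray | None = None


@dataclasses.dataclass
class SubjectRecord:
    """All channels of one simulated subject plus ground truth."""

    subject_id: str
    population: str
    config: SubjectSimConfig
    ecg: SignalRecord
    bcg: SignalRecord
    bp: "np.ndarray"          # structured via dict below for simplicity
    cuff_times: np.ndarray
    cuff_sbp: np.ndarray
    cuff_dbp: np.ndarray
    truth: GroundTruth

    @property
    def device_sbp(self) -> np.ndarray:
        return self.bp[0]

    @property
    def device_dbp(self) -> np.ndarray:
        return self.bp[1]


# ---------------------------------------------------------------------------
# beat timing


def simulate_beat_times(config: SubjectSimConfig, rng: np.random.Generator
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Draw R-wave times and beat-type labels for one recording.

    RR intervals are i.i.d. Gaussian around 60/HR, floored at 0.35 s.  Beat
    types are drawn independently per beat: PVC with ``pvc_prob``, otherwise
    paced with ``paced_fraction``, otherwise intrinsic.
    """
    config.validate()
    mean_rr = 60.0 / config.mean_hr_bpm
    # leave room for the 700-ms crop and the T wave at the record end
    t_max = config.recording_length_s - 0.8
    times = []
    t = 0.5
    while t < t_max:
        times.append(t)
        rr = mean_rr + rng.normal(0.0, config.rr_jitter_sd_s)
        t += max(rr, RR_FLOOR)
    r_times = np.asarray(times)
    u = rng.random(r_times.size)
    v = rng.random(r_times.size)
    types = np.where(u < config.pvc_prob, PVC,
                     np.where(v < config.paced_fraction, PACED, INTRINSIC))
    return r_times, types.astype(object)


# ---------------------------------------------------------------------------
# ECG


def _ecg_ground_truth_fiducials(beat_type: str, fs: float
                                ) -> tuple[float, float, float]:
    """QRS onset/offset and T-end offsets (s, relative to R) for a clean beat.

    Onset is where the spike-free complex last crosses 5% of the R-peak
    amplitude before R; offset is the first *sustained* return below that
    level after R (within twice the level for the following 8 ms, so brief
    zero crossings inside a wide complex do not count); T-end is the tangent
    intersection of the Gaussian T wave with the baseline, which for a
    Gaussian of width sigma falls at center + 2*sigma.
    """
    comps = _ECG_SHAPES[beat_type]
    t = np.arange(-0.15, 0.20, 1.0 / fs)
    qrs = np.zeros_like(t)
    t_idx = _T_COMPONENT_INDEX[beat_type]
    for k, (c, a, w) in enumerate(comps):
        if k == t_idx or (beat_type == INTRINSIC and k == 0):  # skip T and P
            continue
        qrs += a * np.exp(-0.5 * ((t - c) / w) ** 2)
    r_amp = np.abs(qrs[np.argmin(np.abs(t))])
    thr = 0.05 * r_amp
    above = np.abs(qrs) >= thr
    i_r = int(np.argmin(np.abs(t)))
    i = i_r
    while i > 0 and above[i]:
        i -= 1
    q_off = t[i]
    dwell = int(round(0.008 * fs))
    j = i_r
    while j < t.size - 1 and (above[j]
                              or np.max(np.abs(qrs[j:j + dwell])) >= 2 * thr):
        j += 1
    s_off = t[j]
    c_t, _, w_t = comps[t_idx]
    return float(q_off), float(s_off), float(c_t + 2.0 * w_t)


def simulate_ecg(config: SubjectSimConfig,
                 rng: np.random.Generator | None = None,
                 r_times: np.ndarray | None = None,
                 beat_types: np.ndarray | None = None
                 ) -> tuple[SignalRecord, GroundTruth]:
    """Synthesize a surrogate ECG with known fiducials.

    Paced beats carry a narrow high-amplitude stimulus spike 60 ms before a
    widened QRS; PVC beats have a wide (>= 120 ms) QRS and no P wave.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if r_times is None:
        r_times, beat_types = simulate_beat_times(config, rng)
    elif beat_types is None or len(beat_types) != len(r_times):
        raise InputError("beat_types must be given with r_times, same length")

    fs = config.fs_hz
    n = int(round(config.recording_length_s * fs))
    x = np.zeros(n)

    fid_cache = {bt: _ecg_ground_truth_fiducials(bt, fs) for bt in BEAT_TYPES}
    q_times = np.empty(r_times.size)
    s_times = np.empty(r_times.size)
    tend_times = np.empty(r_times.size)

    for i, (rt, bt) in enumerate(zip(r_times, beat_types)):
        comps = list(_ECG_SHAPES[bt])
        if bt == PACED:
            c_sp, w_sp = _PACING_SPIKE
            comps.append((c_sp, config.pacing_spike_amplitude, w_sp))
        i0 = max(0, int(round((rt - 0.30) * fs)))
        i1 = min(n, int(round((rt + 0.60) * fs)))
        tt = np.arange(i0, i1) / fs - rt
        seg = np.zeros_like(tt)
        for c, a, w in comps:
            seg += a * np.exp(-0.5 * ((tt - c) / w) ** 2)
        x[i0:i1] += seg
        dq, ds, dt_end = fid_cache[bt]
        q_times[i], s_times[i], tend_times[i] = rt + dq, rt + ds, rt + dt_end

    if config.noise_sd > 0:
        # ECG noise is kept a fraction of the BCG noise: the surrogate ECG is
        # an analysis aid, not the signal under study
        x = x + rng.normal(0.0, 0.3 * config.noise_sd, size=n)

    truth = GroundTruth(r_times=r_times, beat_types=np.asarray(beat_types, dtype=object),
                        q_times=q_times, s_times=s_times, tend_times=tend_times)
    return SignalRecord("ecg", x, fs, units="mV"), truth


# ---------------------------------------------------------------------------
# BCG


def simulate_bcg(config: SubjectSimConfig, r_times: np.ndarray,
                 beat_types: Sequence[str] | None = None,
                 rng: np.random.Generator | None = None
                 ) -> tuple[SignalRecord, GroundTruth]:
    """Synthesize the seated BCG for the given beat times.

    Each beat is the canonical template subjected to, in order: a lognormal
    per-beat amplitude scale (sigma = ``amplitude_jitter_sd``), independent
    Gaussian per-component timing shifts (SD = ``phase_jitter_sd_s``), an
    AR(1) random walk on per-component gains (shape drift), and sinusoidal
    respiratory amplitude modulation.  White noise and low-frequency baseline
    wander are added on top; the noise-free sum is returned as ground truth.
    """
    config.validate()
    r_times = np.asarray(r_times, dtype=float)
    if r_times.size and np.any(np.diff(r_times) <= 0):
        raise InputError("r_times must be strictly increasing")
    if beat_types is None:
        beat_types = [INTRINSIC] * r_times.size
    if len(beat_types) != r_times.size:
        raise InputError(
            f"beat_types length {len(beat_types)} != r_times length {r_times.size}")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    fs = config.fs_hz
    n = int(round(config.recording_length_s * fs))
    clean = np.zeros(n)
    n_comp = len(BCG_TEMPLATE.components)

    # AR(1) shape-drift state, one gain perturbation per template component
    ar = config.shape_ar_coef
    innov = config.shape_innovation_sd
    drift_state = np.zeros(n_comp)

    for rt, bt in zip(r_times, beat_types):
        template = BCG_TEMPLATE_PVC if bt == PVC else BCG_TEMPLATE
        amp = rng.lognormal(mean=0.0, sigma=config.amplitude_jitter_sd)
        shifts = rng.normal(0.0, config.phase_jitter_sd_s, size=n_comp)
        drift_state = ar * drift_state + rng.normal(0.0, innov, size=n_comp)
        resp = 1.0 + config.resp_mod_depth * np.sin(2 * np.pi * config.resp_rate_hz * rt)
        gains = amp * resp * (1.0 + drift_state)
        i0 = max(0, int(round((rt - 0.05) * fs)))
        i1 = min(n, int(round((rt + 0.78) * fs)))
        tt = np.arange(i0, i1) / fs - rt
        clean[i0:i1] += template.render(tt, center_shift=shifts, gain=gains)

    x = clean.copy()
    if config.noise_sd > 0:
        x += rng.normal(0.0, config.noise_sd, size=n)
    if config.drift_sd > 0:
        # wander below ~0.25 Hz: smoothed coarse noise on a 2-Hz grid,
        # interpolated up to the sampling rate
        coarse_fs = 2.0
        m = int(np.ceil(config.recording_length_s * coarse_fs)) + 4
        coarse = gaussian_filter1d(rng.normal(size=m), sigma=2.0, mode="reflect")
        s = coarse.std()
        if s > 0:
            t_coarse = np.arange(m) / coarse_fs
            x += np.interp(np.arange(n) / fs, t_coarse, coarse) * (config.drift_sd / s)

    truth = GroundTruth(r_times=r_times,
                        beat_types=np.asarray(beat_types, dtype=object),
                        clean_bcg=clean)
    return SignalRecord("bcg", x, fs, units="N"), truth


# ---------------------------------------------------------------------------
# blood pressure


def simulate_bp(r_times: np.ndarray, config: SubjectSimConfig,
                rng: np.random.Generator | None = None
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, GroundTruth]:
    """Beat-to-beat SBP/DBP from the continuous device plus per-minute cuff readings.

    Returns ``(device_sbp, device_dbp, cuff_times, cuff_sbp, cuff_dbp, truth)``.
    The device series equals the true beat-to-beat series plus a constant
    offset and white noise; each cuff reading is the mean of the *true* series
    over the preceding minute.
    """
    r_times = np.asarray(r_times, dtype=float)
    if r_times.size == 0:
        raise InputError("r_times must be non-empty")
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    phi = 0.95  # slow physiological wandering of true BP
    nb = r_times.size

    def _ar1(mean: float, sd: float) -> np.ndarray:
        x = np.empty(nb)
        x[0] = mean + rng.normal(0.0, sd)
        c = sd * np.sqrt(1.0 - phi * phi)
        for i in range(1, nb):
            x[i] = mean + phi * (x[i - 1] - mean) + rng.normal(0.0, c)
        return x

    true_sbp = _ar1(config.sbp_mean_mmhg, config.sbp_sd_mmhg)
    true_dbp = _ar1(config.dbp_mean_mmhg, config.dbp_sd_mmhg)

    off = config.bp_device_offset_mmhg
    dev_sbp = true_sbp + off + rng.normal(0.0, config.bp_noise_sd_mmhg, nb)
    dev_dbp = true_dbp + off + rng.normal(0.0, config.bp_noise_sd_mmhg, nb)

    cuff_times = np.arange(60.0, config.recording_length_s + 1e-9, 60.0)
    cuff_sbp = np.empty(cuff_times.size)
    cuff_dbp = np.empty(cuff_times.size)
    for k, ct in enumerate(cuff_times):
        in_win = (r_times >= ct - 60.0) & (r_times < ct)
        cuff_sbp[k] = true_sbp[in_win].mean()
        cuff_dbp[k] = true_dbp[in_win].mean()

    truth = GroundTruth(r_times=r_times, beat_types=np.asarray([], dtype=object),
                        true_sbp=true_sbp, true_dbp=true_dbp)
    return dev_sbp, dev_dbp, cuff_times, cuff_sbp, cuff_dbp, truth


# ---------------------------------------------------------------------------
# profiles and subjects


def load_profiles(path: str | None = None) -> dict:
    """Load the profile parameter file (defaults to the packaged one)."""
    if path is None:
        text = importlib.resources.files("wfmr").joinpath("profiles.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


def draw_subject_config(profile: str, seed: int,
                        profiles: dict | None = None) -> SubjectSimConfig:
    """Materialize one subject's config from a profile's fixed values and ranges."""
    profiles = profiles if profiles is not None else load_profiles()
    if profile not in profiles:
        raise ConfigurationError(
            f"unknown profile {profile!r}; available: {sorted(profiles)}")
    params = dict(profiles[profile])
    rng = np.random.default_rng(seed)

    def _draw(v):
        if isinstance(v, (list, tuple)):
            lo, hi = v
            return float(rng.uniform(lo, hi))
        return float(v)

    drawn = {k: _draw(v) for k, v in params.items()}
    paced_prob = drawn.pop("paced_subject_prob", 0.0)
    paced_fraction = drawn.pop("paced_fraction", 0.0)
    is_paced_subject = rng.random() < paced_prob
    cfg = SubjectSimConfig(population=profile, seed=seed,
                           paced_fraction=paced_fraction if is_paced_subject else 0.0,
                           **drawn)
    cfg.validate()
    return cfg


def simulate_subject(profile: str, seed: int,
                     profiles: dict | None = None,
                     subject_id: str | None = None) -> SubjectRecord:
    """Simulate one subject: shared beat times drive ECG, BCG and BP."""
    cfg = draw_subject_config(profile, seed, profiles)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    r_times, beat_types = simulate_beat_times(cfg, rng)
    ecg, ecg_truth = simulate_ecg(cfg, rng=rng, r_times=r_times, beat_types=beat_types)
    bcg, bcg_truth = simulate_bcg(cfg, r_times, beat_types, rng=rng)
    dev_sbp, dev_dbp, cuff_t, cuff_s, cuff_d, bp_truth = simulate_bp(r_times, cfg, rng=rng)

    truth = GroundTruth(r_times=r_times, beat_types=ecg_truth.beat_types,
                        q_times=ecg_truth.q_times, s_times=ecg_truth.s_times,
                        tend_times=ecg_truth.tend_times,
                        true_sbp=bp_truth.true_sbp, true_dbp=bp_truth.true_dbp,
                        clean_bcg=bcg_truth.clean_bcg)
    sid = subject_id or f"{'C' if profile == 'clinical' else 'N'}{seed}"
    return SubjectRecord(subject_id=sid, population=profile, config=cfg,
                         ecg=ecg, bcg=bcg, bp=np.vstack([dev_sbp, dev_dbp]),
                         cuff_times=cuff_t, cuff_sbp=cuff_s, cuff_dbp=cuff_d,
                         truth=truth)


def cohort_seeds(seed: int, n_nonclinical: int, n_clinical: int
                 ) -> tuple[list[int], list[int]]:
    """Deterministic per-subject seeds below 2**31 derived from one cohort seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_nonclinical + n_clinical)
    vals = [int(c.generate_state(1, dtype=np.uint32)[0] % (2 ** 31)) for c in children]
    return vals[:n_nonclinical], vals[n_nonclinical:]


def simulate_cohort(seed: int, n_nonclinical: int = 29, n_clinical: int = 26,
                    profiles: dict | None = None) -> list[SubjectRecord]:
    """Simulate the full study cohort (default 29 non-clinical + 26 clinical)."""
    seeds_n, seeds_c = cohort_seeds(seed, n_nonclinical, n_clinical)
    subjects = [simulate_subject("nonclinical", s, profiles, subject_id=f"N{i + 1}")
                for i, s in enumerate(seeds_n)]
    subjects += [simulate_subject("clinical", s, profiles, subject_id=f"C{i + 1}")
                 for i, s in enumerate(seeds_c)]
    return subjects
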