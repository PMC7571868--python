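"""Heartbeat segmentation: R-peak detection, beat typing, cropping, epochs.

R waves are found with a simplified Pan–Tompkins detector; beat types
(intrinsic / paced / PVC) are assigned by morphological rules standing in for
the cardiologist-supervised labels of a clinical workflow; BCG heartbeats are
cropped to 700 samples starting at the R wave; and 20-s analysis epochs are
placed so that each contains only the record's dominant beat type.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import signal as sps

from .errors import EpochSelectionError, InputError
from .records import SignalRecord
from .simulate import INTRINSIC, PACED, PVC

logger = logging.getLogger(__name__)

CROP_SAMPLES = 700      # beat crop length at 1000 Hz (700 ms from the R wave)
EPOCH_SECONDS = 20.0
MIN_BEATS_PER_EPOCH = 8

# ---------------------------------------------------------------------------
# R-peak detection


def detect_r_peaks(ecg: SignalRecord) -> np.ndarray:
    """Simplified Pan–Tompkins QRS detector.

    Chain: 5–15 Hz band-pass, derivative, squaring, 150-ms moving-window
    integration, adaptive threshold tracking running signal/noise peak levels,
    250-ms refractory period.  Each detection is then localized to the maximum
    of the input ECG within +-50 ms of the integrated-signal peak.
    """
    fs = ecg.fs
    if ecg.duration < 5.0:
        raise InputError("detect_r_peaks needs at least 5 s of ECG")
    x = ecg.samples
    if np.ptp(x) == 0:
        logger.warning("flat ECG: no R peaks detected")
        return np.array([])

    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    sq = np.gradient(bp) ** 2
    win = max(1, int(round(0.150 * fs)))
    integ = np.convolve(sq, np.ones(win) / win, mode="same")

    refractory = int(round(0.250 * fs))
    cand, _ = sps.find_peaks(integ, distance=refractory)
    if cand.size == 0:
        logger.warning("no candidate peaks in integrated signal")
        return np.array([])

    # adaptive threshold (running estimates of signal and noise peak levels)
    init = integ[: int(2 * fs)]
    spki = float(init.max()) / 3.0
    npki = float(np.mean(init)) / 2.0
    kept: list[int] = []
    for i in cand:
        thr = npki + 0.25 * (spki - npki)
        if integ[i] > thr:
            spki = 0.125 * integ[i] + 0.875 * spki
            kept.append(i)
        else:
            npki = 0.125 * integ[i] + 0.875 * npki

    # localize to the raw-ECG maximum within +-50 ms
    half = int(round(0.050 * fs))
    r_idx = []
    for i in kept:
        lo, hi = max(0, i - half), min(x.size, i + half + 1)
        r_idx.append(lo + int(np.argmax(x[lo:hi])))
    r_idx = np.unique(r_idx)
    # enforce refractory after localization
    final = []
    for i in r_idx:
        if final and i - final[-1] < refractory:
            if x[i] > x[final[-1]]:
                final[-1] = i
            continue
        final.append(i)
    return np.asarray(final) / fs


# ---------------------------------------------------------------------------
# beat typing


def _local_mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x)))) + 1e-12


def _qrs_width_ms(x: np.ndarray, fs: float, i_r: int, frac: float = 0.2) -> float:
    """Width (ms) of the contiguous region around R where |signal| stays
    above ``frac`` of the R amplitude, allowing brief zero crossings."""
    amp = abs(x[i_r])
    if amp == 0:
        return 0.0
    thr = frac * amp
    span = int(round(0.12 * fs))  # search up to 120 ms either side
    gap_allow = int(round(0.012 * fs))
    lo = i_r
    gap = 0
    for j in range(i_r - 1, max(0, i_r - span) - 1, -1):
        if abs(x[j]) >= thr:
            lo = j
            gap = 0
        else:
            gap += 1
            if gap > gap_allow:
                break
    hi = i_r
    gap = 0
    for j in range(i_r + 1, min(x.size, i_r + span)):
        if abs(x[j]) >= thr:
            hi = j
            gap = 0
        else:
            gap += 1
            if gap > gap_allow:
                break
    return (hi - lo) / fs * 1000.0


def _has_pacing_spike(x: np.ndarray, fs: float, i_r: int) -> bool:
    """Narrow (< 10 ms) high spike (>= 5x local baseline MAD-scale amplitude)
    within 100–40 ms before the QRS.

    Candidate regions are measured on a wider segment so that a wide-QRS
    upstroke clipped at the search-window edge is not mistaken for a narrow
    spike; supra-threshold samples closer than 3 ms are merged into one
    region before its width is judged.
    """
    wide_lo = max(0, i_r - int(round(0.120 * fs)))
    wide_hi = max(0, i_r - int(round(0.020 * fs)))
    if wide_hi - wide_lo < 5:
        return False
    base_lo = max(0, i_r - int(round(0.40 * fs)))
    base_hi = max(1, i_r - int(round(0.20 * fs)))
    baseline = x[base_lo:base_hi]
    scale = max(_local_mad(baseline), 1e-6)
    # 5x the local baseline amplitude, but never below a fifth of the R wave
    # (keeps measurement noise from minting spikes on very quiet baselines)
    thr = max(5.0 * scale, 0.2 * abs(x[i_r] - np.median(baseline)))
    above = np.flatnonzero(np.abs(x[wide_lo:wide_hi] - np.median(baseline)) > thr)
    if above.size == 0:
        return False
    gap = int(round(0.003 * fs))
    win_lo = i_r - int(round(0.100 * fs)) - wide_lo
    win_hi = i_r - int(round(0.040 * fs)) - wide_lo
    # split into regions separated by > 3 ms of sub-threshold samples
    breaks = np.flatnonzero(np.diff(above) > gap)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [above.size - 1]))
    for s, e in zip(starts, ends):
        lo_i, hi_i = above[s], above[e]
        # a region reaching the QRS-side edge continues into the QRS body
        if hi_i >= wide_hi - wide_lo - 1 - gap:
            continue
        if hi_i - lo_i + 1 < 0.010 * fs and win_lo <= lo_i <= win_hi:
            return True
    return False


def label_beat_types(ecg: SignalRecord, r_times: np.ndarray) -> np.ndarray:
    """Rule-based beat typing.

    PVC: local QRS width >= 120 ms with no pacing spike.  Paced: a narrow
    high-amplitude stimulus spike precedes the QRS.  Everything else (and any
    beat the rules cannot assess, e.g. at the record edge) is intrinsic.
    """
    x = ecg.samples
    fs = ecg.fs
    labels = []
    for rt in np.asarray(r_times, dtype=float):
        i_r = int(round(rt * fs))
        if i_r < 0.12 * fs or i_r > x.size - 0.12 * fs:
            logger.warning("beat at %.3f s too close to the record edge; "
                           "labelled intrinsic", rt)
            labels.append(INTRINSIC)
            continue
        if _has_pacing_spike(x, fs, i_r):
            labels.append(PACED)
        elif _qrs_width_ms(x, fs, i_r) >= 120.0:
            labels.append(PVC)
        else:
            labels.append(INTRINSIC)
    return np.asarray(labels, dtype=object)


# ---------------------------------------------------------------------------
# cropping


def crop_heartbeats(bcg: SignalRecord, r_times: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Crop 700 samples from each R wave; returns ``(beats, kept_mask)``.

    The crop length is defined in samples at 1000 Hz, so the BCG must be at
    that rate.  Beats whose crop would run past the record end are dropped
    (mask False) with a warning.
    """
    if bcg.fs != 1000.0:
        raise InputError(f"crop_heartbeats requires fs = 1000 Hz, got {bcg.fs}")
    r_times = np.asarray(r_times, dtype=float)
    idx = np.round(r_times * bcg.fs).astype(int)
    kept = (idx >= 0) & (idx + CROP_SAMPLES <= bcg.n)
    if not kept.all():
        logger.warning("%d beat(s) dropped: crop extends past the record end",
                       int((~kept).sum()))
    if not kept.any():
        raise InputError("no beat crop fits inside the record")
    beats = np.stack([bcg.samples[i:i + CROP_SAMPLES] for i in idx[kept]])
    return beats, kept


@dataclasses.dataclass
class BeatSet:
    """Detected beats of one record: times, type labels, 700-sample crops."""

    r_times: np.ndarray
    labels: np.ndarray
    crops: np.ndarray      # (n_beats, 700)

    def __post_init__(self) -> None:
        if not (len(self.r_times) == len(self.labels) == len(self.crops)):
            raise InputError("r_times, labels and crops must have equal length")
        if len(self.r_times) > 1 and np.any(np.diff(self.r_times) <= 0):
            raise InputError("r_times must be strictly increasing")
        if self.crops.ndim != 2 or self.crops.shape[1] != CROP_SAMPLES:
            raise InputError(f"crops must be (n, {CROP_SAMPLES})")

    @classmethod
    def from_record(cls, bcg: SignalRecord, r_times: np.ndarray,
                    labels: np.ndarray) -> "BeatSet":
        crops, kept = crop_heartbeats(bcg, r_times)
        return cls(np.asarray(r_times, dtype=float)[kept],
                   np.asarray(labels, dtype=object)[kept], crops)


@dataclasses.dataclass
class Epoch:
    """A 20-s analysis segment and the beats admitted to it."""

    start: float
    duration: float
    admitted: np.ndarray       # indices into the BeatSet
    dominant_type: str

    @property
    def end(self) -> float:
        return self.start + self.duration


# ---------------------------------------------------------------------------
# epoch selection


def dominant_beat_type(labels: np.ndarray) -> str:
    """Majority beat type over the record; ties break toward intrinsic."""
    types, counts = np.unique(np.asarray(labels, dtype=object), return_counts=True)
    best = counts.max()
    winners = set(types[counts == best])
    if INTRINSIC in winners:
        return INTRINSIC
    # deterministic order beyond the intrinsic preference
    for t in (PACED, PVC):
        if t in winners:
            return t
    return str(types[np.argmax(counts)])


def select_epochs(beat_set: BeatSet, n_epochs: int = 5,
                  record_length: float | None = None,
                  duration: float = EPOCH_SECONDS,
                  min_beats: int = MIN_BEATS_PER_EPOCH) -> list[Epoch]:
    """Place non-overlapping 20-s epochs containing only dominant-type beats.

    Candidate starts lie on a 1-s grid.  Pure windows (no non-dominant beat)
    are taken greedily left to right; if fewer than *n_epochs* exist, the
    remaining slots are filled with the non-overlapping windows holding the
    fewest non-dominant beats, which are excluded from the admitted set.
    Every epoch must admit at least *min_beats* dominant-type beats.
    """
    if n_epochs == 0:
        return []
    if record_length is None:
        record_length = float(beat_set.r_times[-1]) + 1.0
    if record_length < n_epochs * duration:
        raise EpochSelectionError(
            f"record ({record_length:.0f} s) cannot hold {n_epochs} x "
            f"{duration:.0f}-s epochs", 0)
    dom = dominant_beat_type(beat_set.labels)
    r = beat_set.r_times
    lab = beat_set.labels

    starts = np.arange(0.0, record_length - duration + 1e-9, 1.0)
    info = []
    for s in starts:
        in_win = (r >= s) & (r < s + duration)
        n_dom = int(np.sum(in_win & (lab == dom)))
        n_other = int(np.sum(in_win & (lab != dom)))
        info.append((s, n_dom, n_other))

    chosen: list[tuple[float, int, int]] = []

    def _overlaps(s: float) -> bool:
        return any(abs(s - c[0]) < duration for c in chosen)

    # pass 1: pure windows, greedy left to right
    for s, n_dom, n_other in info:
        if len(chosen) == n_epochs:
            break
        if n_other == 0 and n_dom >= min_beats and not _overlaps(s):
            chosen.append((s, n_dom, n_other))
    # pass 2: fill with least-contaminated windows
    if len(chosen) < n_epochs:
        rest = sorted((c for c in info if c[2] > 0 and c[1] >= min_beats),
                      key=lambda c: (c[2], c[0]))
        for s, n_dom, n_other in rest:
            if len(chosen) == n_epochs:
                break
            if not _overlaps(s):
                chosen.append((s, n_dom, n_other))
                logger.warning("epoch at %.0f s admits %d beats but excludes %d "
                               "non-dominant beat(s)", s, n_dom, n_other)
    if len(chosen) < n_epochs:
        raise EpochSelectionError(
            f"only {len(chosen)} of {n_epochs} epochs could be placed with "
            f">= {min_beats} {dom} beats each", len(chosen))

    chosen.sort(key=lambda c: c[0])
    epochs = []
    for s, _, _ in chosen:
        admitted = np.flatnonzero((r >= s) & (r < s + duration) & (lab == dom))
        epochs.append(Epoch(start=float(s), duration=duration,
                            admitted=admitted, dominant_type=dom))
    return epochs
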