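"""Reference physiological features: ECG intervals and blood pressure.

The WFMR is characterized against classical features: RR, QRS and QT
intervals from the ECG (with the linear heart-rate correction
``QT_c = QT + 0.154 (1 - RR)``, RR and QT in seconds), and beat-to-beat
SBP/DBP after cuff-based offset correction.  Per-beat values are then
windowed exactly like the WFMR ensemble windows so that each 20-s epoch
yields the same number of window means as it yields ensemble averages,
summarized as a log-transformed epoch mean and SD.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import signal as sps

from .beats import Epoch
from .errors import InputError
from .metric import WFMR_EPS, window_beat_sets
from .records import SignalRecord

logger = logging.getLogger(__name__)

#: QRS duration (s) beyond which the excess is removed from QT_QRS
QRS_EXCESS_THRESHOLD = 0.120

#: slope of the linear QT correction (s per s of RR deviation from 1 s)
QT_CORRECTION_SLOPE = 0.154


# ---------------------------------------------------------------------------
# delineation


def _baseline(x: np.ndarray, fs: float, i_r: int) -> float:
    lo = max(0, i_r - int(round(0.40 * fs)))
    hi = max(lo + 1, i_r - int(round(0.22 * fs)))
    return float(np.median(x[lo:hi]))


def delineate(ecg: SignalRecord, r_times: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Rule-based Q, S and T-end delineation.

    Q is the last return to baseline (within 5% of the R amplitude) in the
    80 ms before R; S is the first return to baseline within 120 ms after R;
    T-end comes from the tangent method — the steepest tangent on the T-wave
    downslope is extended to the baseline inside [S + 80 ms, S + 400 ms].

    Returns ``(q_times, s_times, tend_times, ok_mask)``; beats for which any
    fiducial cannot be determined are flagged (mask False) and should be
    excluded from interval features.
    """
    x = ecg.samples
    fs = ecg.fs
    r_times = np.asarray(r_times, dtype=float)
    n = r_times.size
    q_t = np.full(n, np.nan)
    s_t = np.full(n, np.nan)
    te_t = np.full(n, np.nan)
    ok = np.zeros(n, dtype=bool)

    for b, rt in enumerate(r_times):
        i_r = int(round(rt * fs))
        if i_r < 0.45 * fs or i_r > x.size - 0.55 * fs:
            continue
        base = _baseline(x, fs, i_r)
        r_amp = abs(x[i_r] - base)
        if r_amp == 0:
            continue
        thr = 0.05 * r_amp

        # Q: scan backwards from R, skip the QRS body, stop at baseline return
        i_q = None
        for j in range(i_r - 1, i_r - int(round(0.080 * fs)) - 1, -1):
            if abs(x[j] - base) < thr:
                i_q = j
                break
        # S: forwards from R; the return to baseline must be sustained (a
        # brief zero crossing inside a wide slurred QRS does not end it)
        i_s = None
        dwell = int(round(0.008 * fs))
        for j in range(i_r + 1, i_r + int(round(0.120 * fs)) + 1):
            if abs(x[j] - base) < thr and \
                    np.max(np.abs(x[j:j + dwell] - base)) < 2 * thr:
                i_s = j
                break
        if i_q is None or i_s is None:
            logger.warning("beat %d at %.3f s: QRS boundary not found", b, rt)
            continue

        # T-end: tangent method inside [S + 80 ms, S + 400 ms]
        lo = i_s + int(round(0.080 * fs))
        hi = min(x.size - 1, i_s + int(round(0.400 * fs)))
        if hi - lo < int(0.05 * fs):
            continue
        # smooth the low-frequency T wave so the tangent is not noise-driven
        win = max(5, int(round(0.030 * fs)) | 1)
        seg = x[lo:hi] - base
        if seg.size <= win:
            continue
        seg = sps.savgol_filter(seg, win, 3)
        i_pk_rel = int(np.argmax(np.abs(seg)))
        i_pk = lo + i_pk_rel
        t_amp = float(seg[i_pk_rel])
        if abs(t_amp) < 0.02 * r_amp:
            logger.warning("beat %d at %.3f s: flat T wave, T-end indeterminate", b, rt)
            continue
        # tangent on the downslope: fit a line over the 70%..30%-of-peak span
        # after the T peak and extend it to the baseline (single-sample slopes
        # are too noise-sensitive)
        tail = seg[i_pk_rel:] / t_amp  # normalized, peak = 1, either T polarity
        i70 = np.argmax(tail < 0.7) if (tail < 0.7).any() else 0
        i30 = np.argmax(tail < 0.3) if (tail < 0.3).any() else 0
        if i70 == 0 or i30 <= i70 + 2:
            continue
        tt = (np.arange(i70, i30 + 1) + i_pk_rel + lo) / fs
        m_fit, b_fit = np.polyfit(tt, seg[i_pk_rel + i70: i_pk_rel + i30 + 1], 1)
        if m_fit * t_amp >= 0:  # downslope must head back toward baseline
            continue
        te = -b_fit / m_fit
        if not (lo / fs <= te <= hi / fs + 0.1):
            continue
        q_t[b], s_t[b], te_t[b] = i_q / fs, i_s / fs, te
        ok[b] = True
    return q_t, s_t, te_t, ok


# ---------------------------------------------------------------------------
# intervals


@dataclasses.dataclass
class BeatIntervals:
    """Per-beat interval features (seconds); NaN where undefined."""

    r_times: np.ndarray
    rr: np.ndarray
    qrs: np.ndarray
    qt_base: np.ndarray
    qt_qrs: np.ndarray
    qtc_base: np.ndarray
    qtc_qrs: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"rr": self.rr, "qrs": self.qrs, "qt_base": self.qt_base,
                "qt_qrs": self.qt_qrs, "qtc_base": self.qtc_base,
                "qtc_qrs": self.qtc_qrs}


def qt_corrected(qt: np.ndarray | float, rr: np.ndarray | float
                 ) -> np.ndarray | float:
    """Linear heart-rate correction: ``QT_c = QT + 0.154 (1 - RR)``."""
    return qt + QT_CORRECTION_SLOPE * (1.0 - np.asarray(rr, dtype=float))


def beat_intervals(r_times: np.ndarray, q_times: np.ndarray,
                   s_times: np.ndarray, tend_times: np.ndarray,
                   ok: np.ndarray | None = None) -> BeatIntervals:
    """Interval features from fiducials.

    ``RR_i = R_i - R_{i-1}`` (undefined for the first beat); ``QRS = S - Q``;
    ``QT_BASE = T_end - Q``; ``QT_QRS`` removes the part of QRS beyond 120 ms;
    both QT variants get the linear RR correction.  Beats with missing
    fiducials (or an undefined RR) carry NaN.
    """
    r = np.asarray(r_times, dtype=float)
    q = np.asarray(q_times, dtype=float).copy()
    s = np.asarray(s_times, dtype=float).copy()
    te = np.asarray(tend_times, dtype=float).copy()
    if not (r.size == q.size == s.size == te.size):
        raise InputError("fiducial arrays must match r_times in length")
    if ok is not None:
        bad = ~np.asarray(ok, dtype=bool)
        q[bad] = s[bad] = te[bad] = np.nan
    rr = np.full(r.size, np.nan)
    if r.size > 1:
        rr[1:] = np.diff(r)
    qrs = s - q
    qt_base = te - q
    qt_qrs = qt_base - np.maximum(0.0, qrs - QRS_EXCESS_THRESHOLD)
    qtc_base = qt_corrected(qt_base, rr)
    qtc_qrs = qt_corrected(qt_qrs, rr)
    return BeatIntervals(r_times=r, rr=rr, qrs=qrs, qt_base=qt_base,
                         qt_qrs=qt_qrs, qtc_base=qtc_base, qtc_qrs=qtc_qrs)


# ---------------------------------------------------------------------------
# blood pressure offset correction


def bp_offset_correction(beat_times: np.ndarray, device: np.ndarray,
                         cuff_times: np.ndarray, cuff_values: np.ndarray,
                         window_s: float = 60.0
                         ) -> tuple[np.ndarray, float]:
    """Shift the continuous-device series onto the cuff scale.

    For each cuff reading, the device samples in the minute before it are
    averaged and the cuff-minus-device difference recorded; the mean of those
    differences is the correction constant added to the whole series.
    Returns ``(corrected_series, constant)``.  SBP and DBP are corrected by
    separate calls.
    """
    bt = np.asarray(beat_times, dtype=float)
    dev = np.asarray(device, dtype=float)
    ct = np.asarray(cuff_times, dtype=float)
    cv = np.asarray(cuff_values, dtype=float)
    if ct.size == 0:
        raise InputError("bp_offset_correction needs >= 1 cuff reading")
    if bt.size != dev.size:
        raise InputError("beat_times and device series must have equal length")
    diffs = []
    for t, v in zip(ct, cv):
        in_win = (bt >= t - window_s) & (bt < t)
        if not in_win.any():
            logger.warning("no device samples in the minute before the cuff "
                           "reading at %.0f s; difference skipped", t)
            continue
        diffs.append(v - float(dev[in_win].mean()))
    if not diffs:
        raise InputError("no cuff reading had device samples in its window; "
                         "offset correction impossible")
    constant = float(np.mean(diffs))
    return dev + constant, constant


# ---------------------------------------------------------------------------
# windowed epoch statistics


@dataclasses.dataclass
class EpochStats:
    """Windowed summary of one feature over one epoch (natural-log scale)."""

    epoch: Epoch
    t_ea: float
    window_means: np.ndarray       # raw (pre-log) per-window means
    mean_log: float
    sd_log: float
    flagged: bool = False          # < 2 retained windows: SD undefined


def windowed_stats(feature: np.ndarray, r_times: np.ndarray,
                   epochs: list[Epoch], t_ea: float) -> list[EpochStats]:
    """Window means + log-scale epoch mean/SD, on the WFMR windowing.

    The sliding windows (1-s step, duplicate and empty windows dropped) are
    exactly those of the ensemble-average machinery, so an 8-s window over a
    dense 20-s epoch yields 12 window means.  Beats whose feature value is
    NaN (delineation failures) are left out of their windows' means.
    """
    feature = np.asarray(feature, dtype=float)
    r = np.asarray(r_times, dtype=float)
    if feature.size != r.size:
        raise InputError("feature and r_times must have equal length")
    out = []
    for epoch in epochs:
        sets = window_beat_sets(epoch, r, t_ea)
        means = []
        for members in sets:
            vals = feature[members]
            vals = vals[np.isfinite(vals)]
            if vals.size:
                means.append(float(vals.mean()))
        means = np.asarray(means)
        if means.size < 2:
            logger.warning("epoch at %.0f s: %d retained window(s), SD undefined",
                           epoch.start, means.size)
            mean_log = float(np.log(max(means.mean(), WFMR_EPS))) if means.size else float("nan")
            out.append(EpochStats(epoch=epoch, t_ea=t_ea, window_means=means,
                                  mean_log=mean_log, sd_log=float("nan"),
                                  flagged=True))
            continue
        m = float(means.mean())
        sd = float(means.std(ddof=1))
        out.append(EpochStats(epoch=epoch, t_ea=t_ea, window_means=means,
                              mean_log=float(np.log(max(m, WFMR_EPS))),
                              sd_log=float(np.log(max(sd, WFMR_EPS)))))
    return out
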