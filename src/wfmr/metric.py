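"""The waveform fluctuation metric at rest (WFMR).

Within each 20-s epoch a window of length ``T_EA`` slides in 1-s steps; the
700-sample R-aligned BCG heartbeats inside each window are ensemble averaged,

    f_EA(t) = (1/N_EA) * sum_i f_i(t),        t = 1..700,

and the squared discrepancy between every pair of ensemble averages,

    MSE(f, g) = sum_t (f(t) - g(t))^2,

is averaged over all non-diagonal pairs and log-transformed:

    WFMR = ln( mean_{i != j} MSE_ij ).

A perfectly repeating beat gives ensemble averages that are all alike and a
very negative WFMR; beat-to-beat amplitude, phase or shape instability pushes
the metric up.  The MSE is the plain sum of squared differences (no 1/n);
dividing by the fixed crop length n = 700 would only shift every WFMR by the
constant ln(700), which cancels in any comparison.

Windows that contain exactly the same set of beats as an earlier window are
counted once; empty windows are skipped.  With dense beats and no duplicates
a 20-s epoch yields ``20 - T_EA`` ensemble averages (12 at T_EA = 8 s, 15 at
T_EA = 5 s): the window whose end would coincide with the epoch boundary is
not generated.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .beats import CROP_SAMPLES, BeatSet, Epoch
from .errors import EpochInvalidError, InputError

#: floor inside the logarithm, keeps zero-fluctuation epochs finite
WFMR_EPS = 1e-12

#: window sizes of the standard sweep (s)
SWEEP_WINDOWS = tuple(range(2, 16))

#: window size adopted for the main analysis (s)
DEFAULT_T_EA = 8.0


def ensemble_average(beats: np.ndarray) -> np.ndarray:
    """Sample-wise mean of the R-aligned beats in one window."""
    beats = np.asarray(beats, dtype=float)
    if beats.ndim != 2 or beats.shape[0] < 1:
        raise EpochInvalidError("ensemble_average needs at least one beat")
    return beats.mean(axis=0)


def window_beat_sets(epoch: Epoch, r_times: np.ndarray, t_ea: float,
                     step: float = 1.0) -> list[np.ndarray]:
    """Admitted-beat index sets of the retained sliding windows.

    Window k covers ``[start + k*step, start + k*step + t_ea)`` for
    k = 0 .. (duration - t_ea - 1); duplicates (identical index sets) beyond
    the first and empty windows are dropped.  Shared by the WFMR ensemble
    machinery and the reference-feature windowing so their window counts agree
    by construction.
    """
    if not 2.0 <= t_ea <= 15.0:
        raise InputError(f"T_EA must lie in [2, 15] s, got {t_ea}")
    if t_ea >= epoch.duration:
        raise InputError(f"T_EA ({t_ea}) must be smaller than the epoch "
                         f"duration ({epoch.duration})")
    r = np.asarray(r_times, dtype=float)
    n_starts = int(round(epoch.duration - t_ea))  # end-touching window excluded
    seen: set[tuple[int, ...]] = set()
    sets = []
    for k in range(n_starts):
        w0 = epoch.start + k * step
        members = epoch.admitted[(r[epoch.admitted] >= w0)
                                 & (r[epoch.admitted] < w0 + t_ea)]
        if members.size == 0:
            continue
        key = tuple(int(m) for m in members)
        if key in seen:
            continue
        seen.add(key)
        sets.append(members)
    return sets


@dataclasses.dataclass
class EnsembleSet:
    """Sliding-window ensemble averages of one epoch at one window size."""

    epoch: Epoch
    t_ea: float
    waveforms: np.ndarray          # (N_Total, 700)
    beat_index_sets: list[np.ndarray]

    @property
    def n_total(self) -> int:
        return self.waveforms.shape[0]


def sliding_ensemble_averages(epoch: Epoch, beat_set: BeatSet,
                              t_ea: float) -> EnsembleSet:
    """Ensemble averages of the 1-s-step sliding windows of one epoch."""
    sets = window_beat_sets(epoch, beat_set.r_times, t_ea)
    if not sets:
        raise EpochInvalidError(
            f"epoch at {epoch.start:.0f} s retains no non-empty window at "
            f"T_EA = {t_ea} s")
    waveforms = np.stack([ensemble_average(beat_set.crops[m]) for m in sets])
    assert waveforms.shape[1] == CROP_SAMPLES
    return EnsembleSet(epoch=epoch, t_ea=t_ea, waveforms=waveforms,
                       beat_index_sets=sets)


def mse(f: np.ndarray, g: np.ndarray) -> float:
    """Sum of squared sample-wise differences between two waveforms."""
    f = np.asarray(f, dtype=float)
    g = np.asarray(g, dtype=float)
    if f.shape != g.shape:
        raise InputError(f"waveform shapes differ: {f.shape} vs {g.shape}")
    d = f - g
    return float(np.dot(d, d))


def wfmr_epoch(es: EnsembleSet) -> float:
    """WFMR of one epoch: ln of the mean non-diagonal pairwise MSE.

    Computed via the Gram identity ``MSE_ij = ||f_i||^2 + ||f_j||^2 -
    2 <f_i, f_j>`` rather than an explicit double loop; the mean over ordered
    pairs equals the mean over unordered pairs by symmetry.
    """
    w = es.waveforms
    n = es.n_total
    if n < 2:
        raise EpochInvalidError(
            f"WFMR needs >= 2 ensemble averages, epoch at {es.epoch.start:.0f} s "
            f"has {n}")
    sq = np.einsum("ij,ij->i", w, w)
    gram = w @ w.T
    mse_mat = sq[:, None] + sq[None, :] - 2.0 * gram
    off_sum = float(mse_mat.sum() - np.trace(mse_mat))
    mean_mse = off_sum / (n * (n - 1))
    return float(np.log(max(mean_mse, WFMR_EPS)))


@dataclasses.dataclass
class WfmrResult:
    """Per-epoch WFMR values of one subject plus the window-size sweep."""

    subject_id: str
    t_ea: float
    epoch_values: np.ndarray               # WFMR per epoch at t_ea
    n_totals: np.ndarray                   # retained windows per epoch
    sweep: dict[float, np.ndarray] | None = None  # T_EA -> per-epoch WFMR

    @property
    def subject_mean(self) -> float:
        return float(np.mean(self.epoch_values))


def wfmr_subject(beat_set: BeatSet, epochs: list[Epoch], t_ea: float = DEFAULT_T_EA,
                 subject_id: str = "", sweep: bool = False) -> WfmrResult:
    """Per-epoch WFMR for one subject, optionally with the 2–15-s sweep."""
    if not epochs:
        raise InputError("wfmr_subject needs at least one epoch")
    ens = [sliding_ensemble_averages(e, beat_set, t_ea) for e in epochs]
    values = np.array([wfmr_epoch(es) for es in ens])
    n_totals = np.array([es.n_total for es in ens])
    sweep_curves = None
    if sweep:
        sweep_curves = {}
        for t in SWEEP_WINDOWS:
            sweep_curves[float(t)] = np.array([
                wfmr_epoch(sliding_ensemble_averages(e, beat_set, float(t)))
                for e in epochs])
    return WfmrResult(subject_id=subject_id, t_ea=t_ea, epoch_values=values,
                      n_totals=n_totals, sweep=sweep_curves)


def wfmr_sweep(results: list[WfmrResult]) -> list[tuple[float, float]]:
    """Grand-mean sweep curve: epochs -> subject mean -> cohort mean.

    Each subject contributes one value per window size (the mean over its
    epochs) so subjects with unequal epoch counts are weighted equally.
    """
    if not results:
        raise InputError("wfmr_sweep needs at least one subject")
    for r in results:
        if r.sweep is None:
            raise InputError(f"subject {r.subject_id!r} has no sweep curves; "
                             "run wfmr_subject(..., sweep=True)")
    curve = []
    for t in SWEEP_WINDOWS:
        subject_means = [float(np.mean(r.sweep[float(t)])) for r in results]
        curve.append((float(t), float(np.mean(subject_means))))
    return curve


def select_optimal_window(curve: list[tuple[float, float]],
                          elbow_frac: float = 0.10) -> float:
    """Elbow of the mean-WFMR vs window-size curve.

    The elbow is the first point whose following marginal decrease falls below
    ``elbow_frac`` of the total decrease *after* at least one steep marginal
    (>= threshold) has occurred.  A flat (or rising) curve has nothing to
    trade off and returns the smallest window; a curve with no steep segment
    never levels off and returns the largest.
    """
    if len(curve) < 3:
        raise InputError("select_optimal_window needs >= 3 curve points")
    ts = np.array([c[0] for c in curve], dtype=float)
    vs = np.array([c[1] for c in curve], dtype=float)
    if not np.all(np.isfinite(vs)):
        raise InputError("curve contains non-finite values")
    total = vs[0] - vs[-1]
    if total <= 0:
        return float(ts[0])
    thr = elbow_frac * total
    seen_steep = False
    for i in range(len(vs) - 1):
        marginal = vs[i] - vs[i + 1]
        if marginal >= thr:
            seen_steep = True
        elif seen_steep:
            return float(ts[i])
    return float(ts[-1])
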