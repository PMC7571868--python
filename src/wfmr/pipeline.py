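"""End-to-end orchestration: simulate -> preprocess -> beats -> WFMR -> compare.

Two entry points matter in practice:

* :func:`analyze_subject` — the full signal chain on one subject's channels
  (filtering/denoising, R detection, beat typing, epoch placement, WFMR and
  reference features), as a deployed tool would run it.
* :func:`cohort_wfmr_replicate` — a reduced-cost replicate used for power and
  classification studies: the BCG is simulated and segmented using the
  generator's ground-truth beats so that hundreds of cohorts can be evaluated
  in minutes.  The WFMR computation itself is identical.

Everything is seeded; re-running with the same configuration reproduces
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import beats as beats_mod
from . import cohort as cohort_mod
from . import metric, preprocess, reffeat, simulate
from .errors import ConfigurationError
from .records import SignalRecord, write_beat_table

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration


@dataclasses.dataclass
class RunConfig:
    """Pipeline-wide settings; round-trips through YAML unchanged."""

    seed: int = 1
    t_ea: float = 8.0
    n_epochs: int = 5
    n_nonclinical: int = 29
    n_clinical: int = 26
    sweep: bool = False
    out_dir: str = "wfmr_out"
    profiles_path: str | None = None

    def validate(self) -> None:
        if not 2.0 <= self.t_ea <= 15.0:
            raise ConfigurationError(
                f"t_ea must lie in the sweep range [2, 15] s, got {self.t_ea}")
        if self.n_epochs < 0:
            raise ConfigurationError(f"n_epochs must be >= 0, got {self.n_epochs}")
        if self.n_nonclinical < 0 or self.n_clinical < 0:
            raise ConfigurationError("cohort sizes must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# per-subject analysis


def preprocess_channels(ecg: SignalRecord, bcg: SignalRecord,
                        population: str,
                        r_times_hint: np.ndarray | None = None
                        ) -> tuple[SignalRecord, SignalRecord]:
    """Standard conditioning: 2-Hz high-pass everywhere; BCG 25-Hz low-pass;
    ECG 40-Hz low-pass for non-clinical recordings, stationary-wavelet
    denoising (which spares pacemaker spikes) for clinical ones."""
    if ecg.fs != bcg.fs:
        ecg = preprocess.resample(ecg, bcg.fs)
    ecg_hp = preprocess.fir_filter(ecg, preprocess.HIGHPASS_2HZ)
    bcg_hp = preprocess.fir_filter(bcg, preprocess.HIGHPASS_2HZ)
    bcg_clean = preprocess.fir_filter(bcg_hp, preprocess.LOWPASS_BCG_25HZ)
    if population == "nonclinical":
        ecg_clean = preprocess.fir_filter(ecg_hp, preprocess.LOWPASS_ECG_40HZ)
    else:
        # thresholds are tuned on the first minute (representative of the
        # stationary recording) and applied to the whole channel
        n_tune = min(ecg_hp.n, int(60 * ecg_hp.fs))
        tune_rec = ecg_hp.copy_with(ecg_hp.samples[:n_tune])
        hint = None
        if r_times_hint is not None:
            r = np.asarray(r_times_hint, dtype=float)
            hint = r[r < n_tune / ecg_hp.fs - 0.5]
        spec = preprocess.tune_swt_thresholds(tune_rec, r_times=hint)
        ecg_clean = preprocess.swt_denoise(ecg_hp, spec)
    return ecg_clean, bcg_clean


@dataclasses.dataclass
class SubjectAnalysis:
    """Everything the per-subject chain produces."""

    subject_id: str
    population: str
    beat_set: beats_mod.BeatSet
    epochs: list[beats_mod.Epoch]
    wfmr: metric.WfmrResult
    feature_stats: dict[str, list[reffeat.EpochStats]] | None = None


def analyze_subject(subject: simulate.SubjectRecord, t_ea: float = 8.0,
                    n_epochs: int = 5, sweep: bool = False,
                    reference_features: bool = True,
                    do_preprocess: bool = True,
                    use_ground_truth_beats: bool = False) -> SubjectAnalysis:
    """Run the full analysis chain on one subject.

    With ``use_ground_truth_beats`` the simulator's R times and type labels
    replace detection/labeling (useful when benchmarking the metric itself
    rather than the detectors).
    """
    if do_preprocess:
        ecg, bcg = preprocess_channels(
            subject.ecg, subject.bcg, subject.population,
            r_times_hint=subject.truth.r_times if use_ground_truth_beats else None)
    else:
        ecg, bcg = subject.ecg, subject.bcg

    if use_ground_truth_beats:
        r_times = subject.truth.r_times
        labels = subject.truth.beat_types
    else:
        r_times = beats_mod.detect_r_peaks(ecg)
        labels = beats_mod.label_beat_types(ecg, r_times)

    beat_set = beats_mod.BeatSet.from_record(bcg, r_times, labels)
    epochs = beats_mod.select_epochs(beat_set, n_epochs=n_epochs,
                                     record_length=bcg.duration)
    wf = metric.wfmr_subject(beat_set, epochs, t_ea=t_ea,
                             subject_id=subject.subject_id, sweep=sweep)

    feature_stats = None
    if reference_features:
        q, s, te, ok = reffeat.delineate(ecg, beat_set.r_times)
        iv = reffeat.beat_intervals(beat_set.r_times, q, s, te, ok)
        feature_stats = {
            name: reffeat.windowed_stats(vals, beat_set.r_times, epochs, t_ea)
            for name, vals in iv.as_dict().items()}
        # blood pressure, offset-corrected against the cuff readings
        for name, series in (("sbp", subject.device_sbp), ("dbp", subject.device_dbp)):
            cuff = subject.cuff_sbp if name == "sbp" else subject.cuff_dbp
            corrected, _ = reffeat.bp_offset_correction(
                subject.truth.r_times, series, subject.cuff_times, cuff)
            # BP samples are indexed by the simulator's beats; map onto the
            # detected beats by nearest R time
            idx = np.searchsorted(subject.truth.r_times, beat_set.r_times)
            idx = np.clip(idx, 0, corrected.size - 1)
            feature_stats[name] = reffeat.windowed_stats(
                corrected[idx], beat_set.r_times, epochs, t_ea)
    return SubjectAnalysis(subject_id=subject.subject_id,
                           population=subject.population, beat_set=beat_set,
                           epochs=epochs, wfmr=wf, feature_stats=feature_stats)


# ---------------------------------------------------------------------------
# fast cohort replicates (power / classification studies)


def subject_wfmr_fast(profile: str, seed: int, t_ea: float = 8.0,
                      n_epochs: int = 5,
                      profiles: dict | None = None) -> np.ndarray:
    """Per-epoch WFMR of one subject at reduced cost.

    Only the BCG is synthesized and conditioned (2-Hz high-pass, 25-Hz
    low-pass, exactly as in the full chain); the generator's beat times and
    labels stand in for ECG-based detection.  The WFMR computation is the
    production code path.
    """
    cfg = simulate.draw_subject_config(profile, seed, profiles)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    r_times, labels = simulate.simulate_beat_times(cfg, rng)
    bcg, _ = simulate.simulate_bcg(cfg, r_times, labels, rng=rng)
    bcg = preprocess.fir_filter(bcg, preprocess.HIGHPASS_2HZ)
    bcg = preprocess.fir_filter(bcg, preprocess.LOWPASS_BCG_25HZ)
    beat_set = beats_mod.BeatSet.from_record(bcg, r_times, labels)
    epochs = beats_mod.select_epochs(beat_set, n_epochs=n_epochs,
                                     record_length=bcg.duration)
    return metric.wfmr_subject(beat_set, epochs, t_ea=t_ea).epoch_values


def cohort_wfmr_replicate(seed: int, n_nonclinical: int = 29, n_clinical: int = 26,
                          t_ea: float = 8.0, n_epochs: int = 5,
                          profiles: dict | None = None
                          ) -> list[cohort_mod.SubjectFeatures]:
    """One simulated study cohort's WFMR features via the fast path."""
    seeds_n, seeds_c = simulate.cohort_seeds(seed, n_nonclinical, n_clinical)
    feats = []
    for i, s in enumerate(seeds_n):
        vals = subject_wfmr_fast("nonclinical", s, t_ea, n_epochs, profiles)
        feats.append(cohort_mod.SubjectFeatures(f"N{i + 1}", "nonclinical", vals))
    for i, s in enumerate(seeds_c):
        vals = subject_wfmr_fast("clinical", s, t_ea, n_epochs, profiles)
        feats.append(cohort_mod.SubjectFeatures(f"C{i + 1}", "clinical", vals))
    return feats


# ---------------------------------------------------------------------------
# full study run


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Simulate the cohort, run every stage, write tables + manifest.

    Outputs (delimited text) in ``config.out_dir``: per-epoch WFMR table,
    per-beat table, reference-feature table, the window-size sweep curve, and
    the cohort comparison summary; ``manifest.json`` records parameters and a
    checksum per table.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    profiles = (simulate.load_profiles(config.profiles_path)
                if config.profiles_path else None)

    subjects = simulate.simulate_cohort(config.seed, config.n_nonclinical,
                                        config.n_clinical, profiles)
    wfmr_rows, beat_rows, feat_rows = [], [], []
    analyses = []
    for subj in subjects:
        ana = analyze_subject(subj, t_ea=config.t_ea, n_epochs=config.n_epochs,
                              sweep=config.sweep)
        analyses.append(ana)
        for i, (v, n_tot) in enumerate(zip(ana.wfmr.epoch_values, ana.wfmr.n_totals)):
            wfmr_rows.append(dict(subject_id=ana.subject_id,
                                  population=ana.population, epoch_id=i,
                                  t_ea=config.t_ea, n_total=int(n_tot),
                                  wfmr=float(v)))
        for e_id, epoch in enumerate(ana.epochs):
            for b in epoch.admitted:
                beat_rows.append(dict(subject_id=ana.subject_id,
                                      time_s=float(ana.beat_set.r_times[b]),
                                      type=str(ana.beat_set.labels[b]),
                                      epoch_id=e_id))
        if ana.feature_stats:
            for feat, stats_list in ana.feature_stats.items():
                for e_id, st in enumerate(stats_list):
                    feat_rows.append(dict(subject_id=ana.subject_id,
                                          epoch_id=e_id, feature=feat,
                                          epoch_mean_log=st.mean_log,
                                          epoch_sd_log=st.sd_log))
        logger.info("%s: %d beats, %d epochs", ana.subject_id,
                    len(ana.beat_set.r_times), len(ana.epochs))

    write_beat_table(out / "wfmr.tsv", pd.DataFrame(wfmr_rows))
    write_beat_table(out / "beats.tsv", pd.DataFrame(beat_rows))
    if feat_rows:
        write_beat_table(out / "features.tsv", pd.DataFrame(feat_rows))

    if config.sweep:
        curve = metric.wfmr_sweep([a.wfmr for a in analyses])
        write_beat_table(out / "sweep.tsv",
                         pd.DataFrame(curve, columns=["t_ea", "mean_wfmr"]))

    feats = [cohort_mod.SubjectFeatures(a.subject_id, a.population,
                                        a.wfmr.epoch_values) for a in analyses]
    res = cohort_mod.compare_populations(feats, seed=config.seed)
    summary = {
        "welch_t": res.t_stat, "welch_df": res.df, "welch_p_one_sided": res.p_one_sided,
        "loso_accuracy_pct": {k: v.accuracy_pct for k, v in res.loso.items()},
        "decision_tree_best_max_splits": res.loso["decision_tree"].max_splits,
        "misclassified_subjects": {k: v.misclassified_subjects
                                   for k, v in res.loso.items()},
    }
    (out / "cohort_summary.json").write_text(json.dumps(summary, indent=2) + "\n")

    manifest = {
        "config": dataclasses.asdict(config),
        "checksums": {p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
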