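"""End-to-end orchestration: preprocess -> detect -> features -> classify
-> activity refinement -> alarm rules -> evaluation report.

Also houses the training drivers (models are trained from recordings with
ground truth) and the leave-one-subject-out evaluation used for cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import classify, features, rules
from .preprocess import TimeSeries, ecg_bandpass, robust_zscore
from .qrs import BeatAnnotation, DetectorParams, detect_beats
from .synthetic import Recording

#: detected beat matched to a scheduled beat within this window
BEAT_MATCH_TOL_S = 0.075


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the pipeline, serialisable to YAML/JSON.

    Defaults are the framework's stated operating point: 15/5 Hz
    second-order Butterworth cutoffs, 5-s segments with 0.5-s windows
    shifted by 0.25 s, k = 3 neighbours, 60-160 bpm exercise and
    60-100 bpm resting heart-rate bands.
    """

    lowpass_hz: float = 15.0
    highpass_hz: float = 5.0
    filter_order: int = 2
    zero_phase: bool = True
    detector: DetectorParams = field(default_factory=DetectorParams)
    segment_s: float = 5.0
    window_s: float = 0.5
    window_shift_s: float = 0.25
    k: int = 3
    hr_ranges: rules.HeartRateRanges = field(default_factory=rules.HeartRateRanges)
    disabled_rules: tuple = ()
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["detector"] = dataclasses.asdict(self.detector)
        d["hr_ranges"] = dataclasses.asdict(self.hr_ranges)
        d["disabled_rules"] = list(self.disabled_rules)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("detector"), dict):
            d["detector"] = DetectorParams(**d["detector"])
        if isinstance(d.get("hr_ranges"), dict):
            d["hr_ranges"] = rules.HeartRateRanges(**d["hr_ranges"])
        if "disabled_rules" in d:
            d["disabled_rules"] = tuple(d["disabled_rules"])
        return cls(**d)


def prepare_ecg(ecg: TimeSeries,
                config: PipelineConfig) -> tuple[TimeSeries, TimeSeries]:
    """Return (normalised, band-passed) ECG.

    The band-passed trace drives QRS detection; the robust-Z-scored trace
    feeds the morphology features and R-peak refinement.
    """
    norm = robust_zscore(ecg)
    band = ecg_bandpass(norm, zero_phase=config.zero_phase)
    return norm, band


def detect(ecg: TimeSeries, config: PipelineConfig) -> tuple[TimeSeries, list]:
    """Normalise, band-pass and detect beats; returns (normalised, beats)."""
    norm, band = prepare_ecg(ecg, config)
    beats = detect_beats(band, config.detector, refine_on=norm)
    return norm, beats


def match_beats_to_truth(beats: list[BeatAnnotation], truth_times: np.ndarray,
                         truth_types, fs: float,
                         tol_s: float = BEAT_MATCH_TOL_S) -> list[str | None]:
    """Per detected beat, the type of the nearest scheduled beat within
    tolerance, else None (spurious detection)."""
    out = []
    truth_times = np.asarray(truth_times)
    for b in beats:
        t = b.r_index / fs
        if truth_times.size == 0:
            out.append(None)
            continue
        j = int(np.argmin(np.abs(truth_times - t)))
        out.append(truth_types[j] if abs(truth_times[j] - t) <= tol_s else None)
    return out


def _beat_truth_labels(matched: list[str | None]) -> list[str]:
    """Training/evaluation labels: pvc -> abnormal, else normal."""
    return ["abnormal" if m == "pvc" else "normal" for m in matched]


def accel_features(rec: Recording, normalise: bool = True) -> np.ndarray:
    """Per-segment deviation magnitude of (optionally Z-scored) axes."""
    axes = [robust_zscore(a) for a in rec.accel] if normalise else list(rec.accel)
    return features.segment_activity_matrix(*axes)


def train_models(recordings: list[Recording],
                 config: PipelineConfig | None = None) -> dict:
    """Fit the three k-NN models from ground-truth-labelled recordings."""
    config = config or PipelineConfig()
    bx, by, qx, qy, ax_, ay_ = [], [], [], [], [], []
    for rec in recordings:
        norm, beats = detect(rec.ecg, config)
        F, idx = features.beat_feature_matrix(norm, beats)
        matched = match_beats_to_truth(
            [beats[i] for i in idx], rec.truth.beat_times,
            rec.truth.beat_types, rec.ecg.fs)
        keep = [j for j, m in enumerate(matched) if m is not None]
        if keep:
            bx.append(F[keep])
            by.extend(_beat_truth_labels([matched[j] for j in keep]))

        Q = features.segment_quality_matrix(norm)
        n = min(Q.shape[0], len(rec.truth.segment_quality))
        qx.append(Q[:n])
        qy.extend(rec.truth.segment_quality[:n])

        A = accel_features(rec)
        n = min(A.shape[0], len(rec.truth.segment_activity_raw))
        ax_.append(A[:n])
        ay_.extend(rec.truth.segment_activity_raw[:n])

    models = {
        "quality": classify.TieBreakKNN(k=config.k, negative_label="high")
        .fit(np.vstack(qx), np.asarray(qy)),
        "activity": classify.TieBreakKNN(k=config.k, negative_label="static")
        .fit(np.vstack(ax_), np.asarray(ay_)),
    }
    if bx:
        models["beats"] = classify.TieBreakKNN(
            k=config.k, negative_label="normal").fit(np.vstack(bx), np.asarray(by))
    return models


@dataclass
class PipelineResult:
    """Everything a downstream report or test needs from one run."""

    beats: list
    beat_labels: list           # per detected beat, incl. 'unclassified'
    quality_labels: np.ndarray  # per segment
    activity_labels: np.ndarray  # per segment, raw static/non-static
    segments: list              # refined SegmentContext sequence
    decisions: list             # per classified beat
    matched_truth: list         # per detected beat: 'normal'|'pvc'|None


def run_pipeline(rec: Recording, models: dict,
                 config: PipelineConfig | None = None) -> PipelineResult:
    """Run the two-phase framework on one recording."""
    config = config or PipelineConfig()
    norm, beats = detect(rec.ecg, config)
    beat_labels = classify.classify_beats(models["beats"], norm, beats)

    Q = features.segment_quality_matrix(norm)
    quality_labels = classify.classify_segments(models["quality"], Q)
    A = accel_features(rec)
    activity_labels = classify.classify_segments(models["activity"], A)

    n_seg = min(len(quality_labels), len(activity_labels))
    seg_len = int(round(config.segment_s * rec.ecg.fs))
    contexts = []
    for k in range(n_seg):
        lo, hi = k * seg_len, (k + 1) * seg_len
        in_seg = [(i, b) for i, b in enumerate(beats) if lo <= b.r_index < hi]
        hr = rules.heart_rate([b.r_index for _, b in in_seg], rec.ecg.fs)
        classified = [(beat_labels[i], b.r_index) for i, b in in_seg
                      if beat_labels[i] != classify.UNCLASSIFIED]
        contexts.append(rules.SegmentContext(
            index=k,
            quality=str(quality_labels[k]),
            activity_raw=str(activity_labels[k]),
            beat_labels=tuple(lab for lab, _ in classified),
            beat_r_indices=tuple(r for _, r in classified),
            hr=hr,
        ))
    contexts = rules.refine_activity(contexts, config.disabled_rules)
    decisions = rules.apply_rules(contexts, config.hr_ranges,
                                  disabled_rules=config.disabled_rules)
    matched = match_beats_to_truth(beats, rec.truth.beat_times,
                                   rec.truth.beat_types, rec.ecg.fs)
    return PipelineResult(
        beats=beats, beat_labels=beat_labels, quality_labels=quality_labels,
        activity_labels=activity_labels, segments=contexts,
        decisions=decisions, matched_truth=matched,
    )


def evaluate_run(rec: Recording, result: PipelineResult) -> dict:
    """Confusion matrices, metrics, alarm counts and rates for one run."""
    fs = rec.ecg.fs
    # align decisions (per classified beat) with truth via r_index
    truth_by_r = {}
    for b, m in zip(result.beats, result.matched_truth):
        truth_by_r[b.r_index] = (m == "pvc")
    truth = [truth_by_r.get(d.r_index, False) for d in result.decisions]
    rates = rules.false_alarm_rate(result.decisions, truth)

    n_seg = len(result.segments)
    q_cm = classify.confusion_from_labels(
        [str(x) for x in result.quality_labels[:n_seg]],
        rec.truth.segment_quality[:n_seg], positive=rules.LOW)
    a_cm = classify.confusion_from_labels(
        [str(x) for x in result.activity_labels[:n_seg]],
        rec.truth.segment_activity_raw[:n_seg], positive=rules.NON_STATIC)

    # beat-level confusion over classified beats with matched truth
    pred, tr = [], []
    for b, lab, m in zip(result.beats, result.beat_labels, result.matched_truth):
        if lab != classify.UNCLASSIFIED and m is not None:
            pred.append(lab)
            tr.append("abnormal" if m == "pvc" else "normal")
    b_cm = (classify.confusion_from_labels(pred, tr, positive="abnormal")
            if pred else None)

    rule_hist: dict[str, int] = {}
    for d in result.decisions:
        if d.rule_id:
            rule_hist[d.rule_id] = rule_hist.get(d.rule_id, 0) + 1

    report = {
        "alarms": rates,
        "rule_histogram": rule_hist,
        "quality": {"counts": dataclasses.asdict(q_cm),
                    "metrics": classify.format_metrics(q_cm)},
        "activity": {"counts": dataclasses.asdict(a_cm),
                     "metrics": classify.format_metrics(a_cm)},
    }
    if b_cm is not None:
        report["beats"] = {"counts": dataclasses.asdict(b_cm),
                           "metrics": classify.format_metrics(b_cm)}
    return report


def _segment_xy(recordings, config, task: str):
    """Per-recording (features, truth-labels) for one segment task."""
    out = []
    for rec in recordings:
        if task == "quality":
            norm, _band = prepare_ecg(rec.ecg, config)
            X = features.segment_quality_matrix(norm)
            y = rec.truth.segment_quality
        else:
            X = accel_features(rec)
            y = rec.truth.segment_activity_raw
        n = min(X.shape[0], len(y))
        out.append((X[:n], np.asarray(y[:n])))
    return out


def loso_segment_accuracy(recordings: list[Recording],
                          config: PipelineConfig | None = None,
                          task: str = "quality") -> float:
    """Leave-one-subject-out accuracy of a segment-level task."""
    config = config or PipelineConfig()
    negative = "high" if task == "quality" else "static"
    data = _segment_xy(recordings, config, task)
    correct = total = 0
    for hold in range(len(recordings)):
        X_tr = np.vstack([x for j, (x, _) in enumerate(data) if j != hold])
        y_tr = np.concatenate([y for j, (_, y) in enumerate(data) if j != hold])
        X_te, y_te = data[hold]
        if X_te.shape[0] == 0:
            continue
        model = classify.TieBreakKNN(k=config.k, negative_label=negative)
        pred = model.fit(X_tr, y_tr).predict(X_te)
        correct += int(np.sum(pred == y_te))
        total += y_te.size
    if total == 0:
        raise ValueError("no test segments")
    return correct / total


def _beat_xy(recordings, config):
    """Per-recording (features, truth labels) of matched classifiable beats."""
    out = []
    for rec in recordings:
        norm, beats = detect(rec.ecg, config)
        F, idx = features.beat_feature_matrix(norm, beats)
        matched = match_beats_to_truth(
            [beats[i] for i in idx], rec.truth.beat_times,
            rec.truth.beat_types, rec.ecg.fs)
        keep = [j for j, m in enumerate(matched) if m is not None]
        y = _beat_truth_labels([matched[j] for j in keep])
        out.append((F[keep], np.asarray(y)))
    return out


def loso_beat_confusion(recordings: list[Recording],
                        config: PipelineConfig | None = None
                        ) -> classify.ConfusionMatrix:
    """Leave-one-subject-out beat classification vs. generator truth.

    Features are extracted once per recording; only the k-NN training set
    changes per fold.
    """
    config = config or PipelineConfig()
    data = _beat_xy(recordings, config)
    cm = classify.ConfusionMatrix(0, 0, 0, 0)
    for hold in range(len(recordings)):
        X_tr = np.vstack([x for j, (x, _) in enumerate(data) if j != hold])
        y_tr = np.concatenate([y for j, (_, y) in enumerate(data) if j != hold])
        X_te, y_te = data[hold]
        if X_te.shape[0] == 0:
            continue
        model = classify.TieBreakKNN(k=config.k, negative_label="normal")
        pred = model.fit(X_tr, y_tr).predict(X_te)
        cm = cm + classify.confusion_from_labels(pred, y_te, positive="abnormal")
    return cm


def cohort_alarm_rates(recordings: list[Recording], models: dict,
                       config: PipelineConfig | None = None) -> dict:
    """Pooled before/after false-alarm rates across a cohort."""
    config = config or PipelineConfig()
    n = fp_before = fp_after = 0
    for rec in recordings:
        result = run_pipeline(rec, models, config)
        truth_by_r = {b.r_index: (m == "pvc")
                      for b, m in zip(result.beats, result.matched_truth)}
        for d in result.decisions:
            n += 1
            truly_abnormal = truth_by_r.get(d.r_index, False)
            if d.raw_alarm and not truly_abnormal:
                fp_before += 1
                if not d.suppressed:
                    fp_after += 1
    if n == 0:
        raise ValueError("no classified beats in cohort")
    return {"classified_beats": n, "false_before": fp_before,
            "false_after": fp_after, "rate_before": fp_before / n,
            "rate_after": fp_after / n}
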