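"""Rule-based false-alarm suppression.

Phase two of the framework: each 5-s segment carries a predicted signal
quality (high/low), a predicted activity (static/non-static), and the
heart rate extracted from its beats. Rules R1-R2 refine non-static
segments into activity transitions vs. sustained dynamic activity; rules
R3-R7 decide, per abnormal-labelled beat, whether the arrhythmia alarm is
accepted or suppressed:

R1  non-static segment flanked by static segments -> transition
R2  any other non-static segment -> dynamic
R3  suppress alarms during an activity transition
R4  suppress alarms in a static segment immediately after a transition
    (electrode movement often continues briefly)
R5  suppress alarms from high-quality signal during dynamic activity when
    the heart rate lies in the exercise range (60-160 bpm)
R6  suppress alarms from high-quality signal during static activity when
    the heart rate lies in the resting range (60-100 bpm)
R7  suppress alarms from low-quality signal

Range endpoints are inclusive. Suppression uses any-fire semantics; the
recorded rule id is the first firing rule in the fixed priority
R3 > R4 > R7 > R5 > R6 (bookkeeping only — the verdict is
priority-independent). Segments with fewer than 2 beats have no heart
rate and are evaluated only against the heart-rate-free rules R3, R4, R7.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

STATIC = "static"
NON_STATIC = "non-static"
TRANSITION = "transition"
DYNAMIC = "dynamic"
HIGH = "high"
LOW = "low"

RULE_PRIORITY = ("R3", "R4", "R7", "R5", "R6")


@dataclass(frozen=True)
class HeartRateRanges:
    """Plausible heart-rate bands of a normal middle-aged subject (bpm)."""

    exercise_lo: float = 60.0
    exercise_hi: float = 160.0
    resting_lo: float = 60.0
    resting_hi: float = 100.0

    def __post_init__(self) -> None:
        if not (self.exercise_lo < self.exercise_hi
                and self.resting_lo < self.resting_hi):
            raise ValueError("range lo must be < hi")


@dataclass(frozen=True)
class SegmentContext:
    """Everything the rule layer knows about one 5-s segment."""

    index: int
    quality: str                      # 'high' | 'low'
    activity_raw: str                 # 'static' | 'non-static'
    activity_refined: str | None = None  # 'static' | 'transition' | 'dynamic'
    beat_labels: tuple = ()           # labels of beats whose R lies inside
    beat_r_indices: tuple = ()        # their R sample indices
    hr: float | None = None           # bpm; None when < 2 beats

    def __post_init__(self) -> None:
        if self.quality not in (HIGH, LOW):
            raise ValueError(f"quality must be high|low, got {self.quality!r}")
        if self.activity_raw not in (STATIC, NON_STATIC):
            raise ValueError("activity_raw must be static|non-static")
        if self.hr is not None and self.hr <= 0:
            raise ValueError("hr must be positive when present")


@dataclass(frozen=True)
class AlarmDecision:
    """Verdict for one classified beat."""

    r_index: int
    segment_index: int
    raw_alarm: bool
    suppressed: bool
    rule_id: str | None = None

    def __post_init__(self) -> None:
        if self.suppressed and not self.raw_alarm:
            raise ValueError("cannot suppress a beat that did not alarm")
        if (self.rule_id is not None) != self.suppressed:
            raise ValueError("rule_id must be set iff suppressed")


def refine_activity(seq: list[SegmentContext],
                    disabled_rules: tuple = ()) -> list[SegmentContext]:
    """Apply R1/R2: split non-static segments into transition vs. dynamic.

    A missing neighbour at a recording boundary counts as static, so an
    isolated leading/trailing non-static segment becomes a transition
    (conservative: more suppression at the edges). Disabling R1 forces all
    non-static segments to dynamic; disabling R2 forces them to transition
    (R1 wins if both are disabled and dynamic is the fallback).
    """
    r1 = "R1" not in disabled_rules
    r2 = "R2" not in disabled_rules
    n = len(seq)
    out = []
    for i, seg in enumerate(seq):
        if seg.activity_raw == STATIC:
            refined = STATIC
        elif not r1:
            refined = DYNAMIC
        elif not r2:
            refined = TRANSITION
        else:
            prev_static = i == 0 or seq[i - 1].activity_raw == STATIC
            next_static = i == n - 1 or seq[i + 1].activity_raw == STATIC
            refined = TRANSITION if (prev_static and next_static) else DYNAMIC
        out.append(replace(seg, activity_refined=refined))
    return out


def heart_rate(r_indices, fs: float) -> float | None:
    """60 / mean RR (s) over the beats inside one segment; None if < 2."""
    r = np.sort(np.asarray(r_indices, dtype=float))
    if r.size < 2:
        return None
    rr = np.diff(r) / fs
    return float(60.0 / rr.mean())


def _firing_rules(seg: SegmentContext, prev: SegmentContext | None,
                  ranges: HeartRateRanges,
                  enabled: frozenset) -> list[str]:
    act = seg.activity_refined
    if act is None:
        raise ValueError("refine_activity must run before apply_rules")
    fired = []
    if "R3" in enabled and act == TRANSITION:
        fired.append("R3")
    if ("R4" in enabled and act == STATIC and prev is not None
            and prev.activity_refined == TRANSITION):
        fired.append("R4")
    if "R7" in enabled and seg.quality == LOW:
        fired.append("R7")
    if seg.hr is not None:
        if ("R5" in enabled and seg.quality == HIGH and act == DYNAMIC
                and ranges.exercise_lo <= seg.hr <= ranges.exercise_hi):
            fired.append("R5")
        if ("R6" in enabled and seg.quality == HIGH and act == STATIC
                and ranges.resting_lo <= seg.hr <= ranges.resting_hi):
            fired.append("R6")
    return fired


def apply_rules(
    seq: list[SegmentContext],
    ranges: HeartRateRanges | None = None,
    abnormal_label: str = "abnormal",
    disabled_rules: tuple = (),
) -> list[AlarmDecision]:
    """Accept or suppress each raw arrhythmia alarm.

    Every beat labelled ``abnormal_label`` is a raw alarm; it is suppressed
    iff any enabled rule among R3-R7 fires on its segment. Individual rules
    can be disabled for ablation studies.
    """
    ranges = ranges or HeartRateRanges()
    enabled = frozenset(RULE_PRIORITY) - frozenset(disabled_rules)
    decisions = []
    for i, seg in enumerate(seq):
        prev = seq[i - 1] if i > 0 else None
        fired = _firing_rules(seg, prev, ranges, enabled)
        rule_id = next((r for r in RULE_PRIORITY if r in fired), None)
        for label, r_idx in zip(seg.beat_labels, seg.beat_r_indices):
            raw = label == abnormal_label
            suppressed = raw and rule_id is not None
            decisions.append(AlarmDecision(
                r_index=int(r_idx), segment_index=seg.index, raw_alarm=raw,
                suppressed=suppressed,
                rule_id=rule_id if suppressed else None,
            ))
    return decisions


def alarm_counts(decisions: list[AlarmDecision]) -> dict[str, int]:
    """Beats counted as normal/abnormal before and after suppression."""
    total = len(decisions)
    raw = sum(d.raw_alarm for d in decisions)
    surviving = sum(d.raw_alarm and not d.suppressed for d in decisions)
    return {
        "classified_beats": total,
        "normal_before": total - raw,
        "abnormal_before": raw,
        "normal_after": total - surviving,
        "abnormal_after": surviving,
    }


def false_alarm_rate(decisions: list[AlarmDecision],
                     truth: list[bool] | None = None) -> dict[str, float]:
    """Fraction of classified beats that alarm falsely, before and after.

    ``truth`` gives the per-beat abnormality (True = truly abnormal),
    aligned with ``decisions``; ``None`` means all beats are truly normal
    (every alarm is false).
    """
    if not decisions:
        raise ValueError("no classified beats")
    if truth is None:
        truth = [False] * len(decisions)
    if len(truth) != len(decisions):
        raise ValueError("decisions and truth must be aligned")
    n = len(decisions)
    fp_before = sum(d.raw_alarm and not t for d, t in zip(decisions, truth))
    fp_after = sum(d.raw_alarm and not d.suppressed and not t
                   for d, t in zip(decisions, truth))
    counts = alarm_counts(decisions)
    counts_rates = {
        "rate_before": fp_before / n,
        "rate_after": fp_after / n,
    }
    return {**counts, **counts_rates}


def rate_from_counts(classified: int, raw_alarms: int,
                     surviving_alarms: int) -> tuple[float, float]:
    """Before/after false-alarm rates from aggregate all-normal counts."""
    if classified <= 0:
        raise ValueError("no classified beats")
    return raw_alarms / classified, surviving_alarms / classified
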