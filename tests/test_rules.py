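"""Activity refinement (R1/R2) and alarm suppression (R3-R7)."""

import itertools

import numpy as np
import pytest

from ecgalarm.rules import (
    DYNAMIC,
    HIGH,
    LOW,
    NON_STATIC,
    STATIC,
    TRANSITION,
    AlarmDecision,
    SegmentContext,
    apply_rules,
    false_alarm_rate,
    heart_rate,
    rate_from_counts,
    refine_activity,
)


def seg(i, quality=HIGH, raw=STATIC, labels=(), hr=None, r_indices=None):
    if r_indices is None:
        r_indices = tuple(100 * i + 10 * j for j in range(len(labels)))
    return SegmentContext(index=i, quality=quality, activity_raw=raw,
                          beat_labels=tuple(labels),
                          beat_r_indices=tuple(r_indices), hr=hr)


def make_seq(raw_kinds):
    return [seg(i, raw=k) for i, k in enumerate(raw_kinds)]


def refined(raw_kinds):
    return [s.activity_refined for s in refine_activity(make_seq(raw_kinds))]


def test_isolated_non_static_becomes_transition():
    assert refined([STATIC, NON_STATIC, STATIC]) == [STATIC, TRANSITION, STATIC]


def test_sustained_non_static_becomes_dynamic():
    assert refined([STATIC, NON_STATIC, NON_STATIC, STATIC]) == [
        STATIC, DYNAMIC, DYNAMIC, STATIC]


def test_all_static_unchanged():
    assert refined([STATIC] * 4 ) == [STATIC] * 4


def test_missing_neighbour_counts_as_static():
    # leading/trailing lone non-static segments become transitions
    assert refined([NON_STATIC, STATIC]) == [TRANSITION, STATIC]
    assert refined([STATIC, NON_STATIC]) == [STATIC, TRANSITION]
    assert refined([]) == []


def test_r1_r2_ablation():
    kinds = [STATIC, NON_STATIC, STATIC]
    out = refine_activity(make_seq(kinds), disabled_rules=("R1",))
    assert out[1].activity_refined == DYNAMIC
    out = refine_activity(make_seq([STATIC, NON_STATIC, NON_STATIC]),
                          disabled_rules=("R2",))
    assert [s.activity_refined for s in out[1:]] == [TRANSITION, TRANSITION]


def test_heart_rate_examples():
    fs = 100.0
    assert heart_rate([0, 100, 200], fs) == pytest.approx(60.0)
    assert heart_rate([0, 50, 100], fs) == pytest.approx(120.0)
    assert heart_rate([42], fs) is None
    assert heart_rate([], fs) is None


def test_heart_rate_matches_mean_rr_oracle(rng):
    idx = np.sort(rng.choice(5000, size=12, replace=False))
    fs = 100.0
    rr = np.diff(idx) / fs
    assert heart_rate(idx, fs) == pytest.approx(60.0 / rr.mean())


def _decide(quality, refined_act, hr, prev_refined=STATIC):
    """Run apply_rules on a 2-segment sequence; segment 1 holds the alarm."""
    s0 = SegmentContext(index=0, quality=HIGH, activity_raw=STATIC,
                        activity_refined=prev_refined)
    s1 = SegmentContext(index=1, quality=quality, activity_raw=(
        STATIC if refined_act == STATIC else NON_STATIC),
        activity_refined=refined_act,
        beat_labels=("abnormal",), beat_r_indices=(600,), hr=hr)
    decisions = apply_rules([s0, s1])
    (d,) = [d for d in decisions if d.segment_index == 1]
    return d


@pytest.mark.parametrize("quality,act,hr,suppressed,rule", [
    (HIGH, TRANSITION, 75.0, True, "R3"),
    (LOW, STATIC, None, True, "R7"),
    (HIGH, STATIC, 75.0, True, "R6"),
    (HIGH, STATIC, 180.0, False, None),
    (HIGH, DYNAMIC, 150.0, True, "R5"),
    (HIGH, DYNAMIC, 170.0, False, None),
    (HIGH, DYNAMIC, None, False, None),   # hr absent: R5 cannot fire
    (HIGH, STATIC, None, False, None),    # hr absent: R6 cannot fire
    (LOW, TRANSITION, 75.0, True, "R3"),  # R3 outranks R7 for bookkeeping
])
def test_rule_examples(quality, act, hr, suppressed, rule):
    d = _decide(quality, act, hr)
    assert d.suppressed is suppressed
    assert d.rule_id == rule


def test_alarm_after_transition_suppressed_by_r4():
    d = _decide(HIGH, STATIC, 180.0, prev_refined=TRANSITION)
    assert d.suppressed and d.rule_id == "R4"


def test_range_endpoints_inclusive():
    for hr in (60.0, 100.0):
        assert _decide(HIGH, STATIC, hr).rule_id == "R6"
    assert not _decide(HIGH, STATIC, 59.9).suppressed
    assert not _decide(HIGH, STATIC, 100.1).suppressed
    assert _decide(HIGH, DYNAMIC, 60.0).rule_id == "R5"
    assert _decide(HIGH, DYNAMIC, 160.0).rule_id == "R5"
    assert not _decide(HIGH, DYNAMIC, 160.1).suppressed


def expected_verdict(quality, act, hr, after_transition):
    """Independent truth table of R3-R7 (any-fire semantics)."""
    if act == TRANSITION:
        return True                                   # R3
    if act == STATIC and after_transition:
        return True                                   # R4
    if quality == LOW:
        return True                                   # R7
    if hr is not None and quality == HIGH:
        if act == DYNAMIC and 60 <= hr <= 160:
            return True                               # R5
        if act == STATIC and 60 <= hr <= 100:
            return True                               # R6
    return False


def test_full_truth_table_is_deterministic_and_documented():
    hr_buckets = {"below": 40.0, "resting": 80.0, "exercise-only": 130.0,
                  "above": 175.0, "absent": None}
    cases = itertools.product(
        (HIGH, LOW), (STATIC, TRANSITION, DYNAMIC), (False, True),
        hr_buckets.items())
    for quality, act, after_trans, (_, hr) in cases:
        if act != STATIC and after_trans:
            continue  # R4 antecedent only concerns static segments
        prev = TRANSITION if after_trans else STATIC
        d1 = _decide(quality, act, hr, prev_refined=prev)
        d2 = _decide(quality, act, hr, prev_refined=prev)
        assert (d1.suppressed, d1.rule_id) == (d2.suppressed, d2.rule_id)
        assert d1.suppressed == expected_verdict(quality, act, hr, after_trans)


def test_suppression_is_monotone_and_consistent(rng):
    # random segment sequences: accepted alarms are a subset of raw alarms
    kinds = (STATIC, NON_STATIC)
    for trial in range(20):
        g = np.random.default_rng(trial)
        segs = []
        for i in range(8):
            labels = tuple(g.choice(["normal", "abnormal"], size=3))
            segs.append(seg(
                i, quality=str(g.choice([HIGH, LOW])),
                raw=str(g.choice(kinds)), labels=labels,
                hr=float(g.uniform(40, 180)) if g.random() < 0.8 else None))
        decisions = apply_rules(refine_activity(segs))
        for d in decisions:
            if d.suppressed:
                assert d.raw_alarm and d.rule_id is not None
            else:
                assert d.rule_id is None
        normals = [d for d in decisions if not d.raw_alarm]
        assert all(not d.suppressed for d in normals)


def test_normal_beats_never_alarm():
    s = seg(0, quality=LOW, raw=STATIC, labels=("normal", "normal"))
    decisions = apply_rules(refine_activity([s]))
    assert all(not d.raw_alarm and not d.suppressed for d in decisions)


def test_invariants_of_alarm_decision():
    with pytest.raises(ValueError):
        AlarmDecision(r_index=0, segment_index=0, raw_alarm=False,
                      suppressed=True, rule_id="R3")
    with pytest.raises(ValueError):
        AlarmDecision(r_index=0, segment_index=0, raw_alarm=True,
                      suppressed=True, rule_id=None)


def test_false_alarm_rate_counting(rng):
    segs = refine_activity([
        seg(0, quality=LOW, raw=STATIC, labels=("abnormal", "normal")),
        seg(1, quality=HIGH, raw=STATIC, labels=("abnormal",), hr=150.0),
    ])
    decisions = apply_rules(segs)
    out = false_alarm_rate(decisions)
    assert out["classified_beats"] == 3
    assert out["abnormal_before"] == 2
    assert out["abnormal_after"] == 1      # only the low-quality alarm dies
    assert out["rate_before"] == pytest.approx(2 / 3)
    assert out["rate_after"] == pytest.approx(1 / 3)


def test_no_raw_alarms_means_zero_rate():
    segs = refine_activity([seg(0, labels=("normal",) * 4)])
    out = false_alarm_rate(apply_rules(segs))
    assert out["rate_before"] == out["rate_after"] == 0.0
    with pytest.raises(ValueError):
        false_alarm_rate([])


def test_accuracy_never_decreases_on_all_normal_truth(rng):
    # every suppression converts a false positive into a true negative
    for trial in range(10):
        g = np.random.default_rng(100 + trial)
        segs = [seg(i, quality=str(g.choice([HIGH, LOW])),
                    raw=str(g.choice([STATIC, NON_STATIC])),
                    labels=tuple(g.choice(["normal", "abnormal"], size=4)),
                    hr=float(g.uniform(50, 170)))
                for i in range(6)]
        decisions = apply_rules(refine_activity(segs))
        out = false_alarm_rate(decisions)
        n = out["classified_beats"]
        acc_before = out["normal_before"] / n
        acc_after = out["normal_after"] / n
        assert acc_after >= acc_before


def test_rate_from_aggregate_counts():
    before, after = rate_from_counts(21870, 2095, 312)
    assert f"{100 * before:.2f}%" == "9.58%"
    assert f"{100 * after:.2f}%" == "1.43%"
    with pytest.raises(ValueError):
        rate_from_counts(0, 0, 0)
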