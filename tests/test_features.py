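"""Beat, quality and activity feature extraction."""

import numpy as np
import pytest

from ecgalarm.features import (
    BEAT_FEATURE_NAMES,
    ContextError,
    beat_features,
    calibrate_features,
    deviation_magnitude,
    quality_features,
    window_stats,
)
from ecgalarm.preprocess import TimeSeries, robust_zscore
from ecgalarm.qrs import BeatAnnotation

FS = 100.0


def _beats(r_indices):
    return [BeatAnnotation(r, r) for r in r_indices]


def naive_beat_features(s, fs, r):
    """Independent straight-line recomputation of the 13 beat features.

    ``r`` lists R indices of beats i-2 .. i+1; windows use
    half = round(w*fs/2) samples on each side, population variances,
    central-difference gradients.
    """
    rm2, rm1, ri, rp1 = r

    def pvar(v):
        v = np.asarray(v, dtype=float)
        return np.mean((v - v.mean()) ** 2)

    def win(arr, w):
        half = int(round(w * fs / 2))
        return arr[max(0, ri - half): min(len(arr), ri + half + 1)]

    grad = np.zeros_like(s)
    for t in range(1, len(s) - 1):
        grad[t] = s[t + 1] - s[t - 1]

    rr_prev, rr_i, rr_next = (rm1 - rm2) / fs, (ri - rm1) / fs, (rp1 - ri) / fs
    between = s[rm1:ri + 1]
    return [
        rr_i,
        pvar([rr_i, rr_next]),
        pvar([rr_prev, rr_i, rr_next]),
        float(np.mean(between)),
        abs(s[rm1] - s[ri]),
        abs(s[ri] - s[rp1]),
        float(np.mean(win(s, 0.12))),
        float(np.mean(win(s, 0.16))),
        float(np.mean(win(grad, 0.12))),
        float(np.mean(win(grad, 0.16))),
        float(np.mean(win(grad, 0.23))),
        pvar(win(grad, 0.06)),
        float(np.max(win(s, 0.08)) - np.min(win(s, 0.08))),
    ]


def test_beat_features_match_independent_recomputation(rng):
    s = rng.standard_normal(500)
    r = [80, 160, 250, 330, 420]
    x = TimeSeries(s, FS)
    got = beat_features(x, _beats(r), 2)
    expected = naive_beat_features(s, FS, r[0:4])
    np.testing.assert_allclose(got, expected, atol=1e-12)
    assert got.shape == (len(BEAT_FEATURE_NAMES),)


def test_periodic_beats_have_zero_rr_variance(rng):
    s = rng.standard_normal(600)
    x = TimeSeries(s, FS)
    f = beat_features(x, _beats([100, 180, 260, 340, 420]), 2)
    assert f[1] == pytest.approx(0.0, abs=1e-24)  # var_rr2
    assert f[2] == pytest.approx(0.0, abs=1e-24)  # var_rr3
    assert f[0] == pytest.approx(0.8)


def test_constant_inter_peak_signal():
    s = np.full(600, 2.5)
    s[50] = 3.0  # keep the series non-degenerate elsewhere
    x = TimeSeries(s, FS)
    f = beat_features(x, _beats([100, 180, 260, 340, 420]), 2)
    assert f[3] == 2.5        # mean_amp_between
    assert f[4] == 0.0        # absdiff_amp_prev


def test_boundary_beats_raise_context_error(rng):
    x = TimeSeries(rng.standard_normal(600), FS)
    beats = _beats([100, 180, 260, 340])
    for i in (0, 1, 3):
        with pytest.raises(ContextError):
            beat_features(x, beats, i)
    beat_features(x, beats, 2)  # only the interior beat is classifiable


def test_five_second_segment_yields_19_windows(rng):
    seg = TimeSeries(rng.standard_normal(500), FS)
    ws = window_stats(seg)
    assert len(ws) == 19
    np.testing.assert_allclose([w.start_s for w in ws],
                               np.arange(0, 4.75, 0.25))


def test_constant_segment_windows_have_zero_variance():
    ws = window_stats(TimeSeries(np.full(500, 1.5), FS))
    assert all(w.var == 0 for w in ws)
    assert all(w.max == w.min == 1.5 for w in ws)


def test_window_stats_match_sliding_oracle(rng):
    s = rng.standard_normal(500)
    ws = window_stats(TimeSeries(s, FS))
    for k, w in enumerate(ws):
        chunk = s[k * 25: k * 25 + 50]
        assert w.mean == pytest.approx(np.mean(chunk))
        assert w.var == pytest.approx(np.var(chunk))
        assert w.abs_mean == pytest.approx(np.mean(np.abs(chunk)))


def test_quality_features_on_identical_windows(rng):
    s = np.tile(rng.standard_normal(25), 20)  # period 0.25 s: identical windows
    f = quality_features(window_stats(TimeSeries(s, FS)))
    var_of_vars, grad_of_vars, range_of_vars = f[2], f[3], f[6]
    assert var_of_vars == pytest.approx(0, abs=1e-12)
    assert grad_of_vars == pytest.approx(0, abs=1e-12)
    assert range_of_vars == pytest.approx(0, abs=1e-12)


def test_variance_gradient_recovers_arithmetic_progression(rng):
    # windows whose variances step by exactly d have LS slope d
    from ecgalarm.features import WindowStats
    d = 0.37
    ws = [WindowStats(0.25 * k, mean=0.0, var=1.0 + d * k, min=-1, max=1,
                      abs_mean=0.5, abs_var=0.2) for k in range(19)]
    f = quality_features(ws)
    assert f[3] == pytest.approx(d, abs=1e-9)


def test_quality_features_match_naive_loop_oracle(rng):
    s = rng.standard_normal(500)
    ws = window_stats(TimeSeries(s, FS))
    f = quality_features(ws)
    means = [w.mean for w in ws]
    vars_ = [w.var for w in ws]
    abs_means = [w.abs_mean for w in ws]
    abs_vars = [w.abs_var for w in ws]
    slope = np.polyfit(range(len(ws)), vars_, 1)[0]
    oracle = [np.mean(means), np.mean(vars_), np.var(vars_), slope,
              min(means), min(vars_), max(vars_) - min(vars_),
              max(abs_vars) - min(abs_vars), np.mean(abs_means)]
    np.testing.assert_allclose(f, oracle, atol=1e-12)


def test_deviation_magnitude_examples():
    n = 500
    const = TimeSeries(np.full(n, 0.98), FS)
    assert deviation_magnitude(const, const, const) == pytest.approx(0.0, abs=1e-9)
    t = np.arange(n) / FS
    sine = TimeSeries(np.sin(2 * np.pi * 1.0 * t), FS)  # full periods
    zero = TimeSeries(np.zeros(n) + 1e-12, FS)
    dev = deviation_magnitude(sine, zero, zero)
    assert dev == pytest.approx(np.sqrt(0.5), rel=1e-6)


def test_deviation_magnitude_rotation_invariant(rng):
    from scipy.spatial.transform import Rotation
    a = np.array([0.0, 0.0, 1.0])[:, None] + 0.05 * rng.standard_normal((3, 500))
    rot = Rotation.from_euler("xyz", [30, -45, 60], degrees=True).as_matrix()
    b = rot @ a
    mk = lambda m: [TimeSeries(m[i], FS) for i in range(3)]
    assert deviation_magnitude(*mk(a)) == pytest.approx(
        deviation_magnitude(*mk(b)), rel=1e-9)


def test_axis_length_mismatch_rejected():
    a = TimeSeries(np.zeros(100) + np.arange(100.0), FS)
    b = TimeSeries(np.zeros(99) + np.arange(99.0), FS)
    with pytest.raises(ValueError):
        deviation_magnitude(a, a, b)


def test_calibration_examples(rng):
    ref_means = np.array([2.0, 4.0])
    target = np.array([[1.0, 2.0], [1.0, 2.0]])  # means exactly half
    cal = calibrate_features(ref_means, target)
    np.testing.assert_allclose(cal, 2 * target)
    same = rng.uniform(1, 3, size=(50, 4))
    np.testing.assert_allclose(
        calibrate_features(same.mean(axis=0), same), same)


def test_calibration_aligns_means(rng):
    ref = rng.uniform(0.5, 2.0, size=(80, 5))
    target = rng.uniform(1.0, 6.0, size=(60, 5))
    cal = calibrate_features(ref.mean(axis=0), target)
    np.testing.assert_allclose(cal.mean(axis=0), ref.mean(axis=0), atol=1e-9)


def test_calibration_zero_target_mean_errors():
    with pytest.raises(ValueError, match="zero target mean"):
        calibrate_features(np.array([1.0]), np.array([[1.0], [-1.0]]))


def test_features_invariant_to_input_offset(rng):
    s = rng.standard_normal(1200)
    r = [200, 300, 400, 500, 600]
    f0 = beat_features(robust_zscore(TimeSeries(s, FS)), _beats(r), 2)
    f1 = beat_features(robust_zscore(TimeSeries(s + 17.3, FS)), _beats(r), 2)
    np.testing.assert_allclose(f0, f1, atol=1e-9)


def test_noise_raises_mean_of_window_variances():
    t = np.arange(500) / FS
    clean = np.sin(2 * np.pi * 1.2 * t)
    wins = 0
    for seed in range(20):
        g = np.random.default_rng(seed)
        f_lo = quality_features(window_stats(
            TimeSeries(clean + 0.1 * g.standard_normal(500), FS)))
        g = np.random.default_rng(seed)
        f_hi = quality_features(window_stats(
            TimeSeries(clean + 1.0 * g.standard_normal(500), FS)))
        wins += f_hi[1] > f_lo[1]  # mean_of_vars
    assert wins == 20
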