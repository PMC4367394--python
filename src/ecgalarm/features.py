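"""Feature extraction for the three classification tasks.

* 13 R-peak-based beat features (RR intervals, inter-peak morphology,
  fixed-width windows centred at the R peak) for normal/abnormal beat
  classification;
* 9 two-level statistical features (0.5-s windows shifted by 0.25 s,
  aggregated over a 5-s segment) for high/low signal-quality
  classification;
* the tri-axial acceleration deviation magnitude over a 5-s segment for
  static/non-static activity classification;
* cross-population feature calibration (mean-ratio rescaling).

All ECG features are computed on the robust-Z-scored signal. Variances are
population variances (divide by n): the 2- and 3-element RR variances make
the n-1 convention unusable.

Conventions where the underlying definitions are not published and are
fixed here: the "gradient" at a sample is the two-sample central
difference (matching the detector's slope); the "gradient of signal
amplitude variances" across a segment's windows is the least-squares slope
of variance against window index; "deviation magnitude" is the square root
of the summed per-axis variances (an alternative — the SD of the vector
magnitude signal — is available via ``vector_magnitude_sd``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import TimeSeries
from .qrs import BeatAnnotation

BEAT_FEATURE_NAMES = (
    "rr_i",
    "var_rr2",
    "var_rr3",
    "mean_amp_between",
    "absdiff_amp_prev",
    "absdiff_amp_next",
    "mean_amp_w012",
    "mean_amp_w016",
    "mean_grad_w012",
    "mean_grad_w016",
    "mean_grad_w023",
    "var_grad_w006",
    "range_amp_w008",
)

QUALITY_FEATURE_NAMES = (
    "mean_of_means",
    "mean_of_vars",
    "var_of_vars",
    "grad_of_vars",
    "min_of_means",
    "min_of_vars",
    "range_of_vars",
    "range_of_absvars",
    "mean_of_absmeans",
)

SEGMENT_S = 5.0
WINDOW_S = 0.5
WINDOW_SHIFT_S = 0.25


class ContextError(ValueError):
    """A beat lacks the i-2 ... i+1 neighbour context and is unclassifiable."""


@dataclass(frozen=True)
class WindowStats:
    """Statistics of one 0.5-s window."""

    start_s: float
    mean: float
    var: float
    min: float
    max: float
    abs_mean: float
    abs_var: float


def _centered_window(samples: np.ndarray, center: int, width_s: float,
                     fs: float) -> np.ndarray:
    """Odd-count window of ~width_s seconds centred at ``center``.

    half = round(width_s * fs / 2), so the window spans 2*half + 1 samples,
    truncated at the record edges.
    """
    half = int(round(width_s * fs / 2))
    lo = max(0, center - half)
    hi = min(samples.size, center + half + 1)
    return samples[lo:hi]


def _gradient(samples: np.ndarray) -> np.ndarray:
    """Two-sample central difference, zero-padded at the endpoints."""
    g = np.zeros_like(samples, dtype=float)
    if samples.size >= 3:
        g[1:-1] = samples[2:] - samples[:-2]
    return g


def beat_features(x: TimeSeries, beats: list[BeatAnnotation], i: int) -> np.ndarray:
    """The 13-component feature vector of beat ``i``.

    Requires beats i-2 ... i+1 to exist; boundary beats raise
    :class:`ContextError` and are treated as unclassifiable upstream.
    Column order follows :data:`BEAT_FEATURE_NAMES`.
    """
    if i - 2 < 0 or i + 1 >= len(beats):
        raise ContextError(f"beat {i} lacks i-2..i+1 context (n={len(beats)})")
    s = x.samples
    fs = x.fs
    r = [beats[j].r_index for j in range(i - 2, i + 2)]  # R[i-2..i+1]
    rm2, rm1, ri, rp1 = r
    rr_prev = (rm1 - rm2) / fs  # RR[i-1]
    rr_i = (ri - rm1) / fs
    rr_next = (rp1 - ri) / fs   # RR[i+1]

    grad = _gradient(s)
    between = s[rm1:ri + 1]  # inclusive of both R samples

    w012 = _centered_window(s, ri, 0.12, fs)
    w016 = _centered_window(s, ri, 0.16, fs)
    g012 = _centered_window(grad, ri, 0.12, fs)
    g016 = _centered_window(grad, ri, 0.16, fs)
    g023 = _centered_window(grad, ri, 0.23, fs)
    g006 = _centered_window(grad, ri, 0.06, fs)
    w008 = _centered_window(s, ri, 0.08, fs)

    return np.array([
        rr_i,
        np.var([rr_i, rr_next]),
        np.var([rr_prev, rr_i, rr_next]),
        np.mean(between),
        abs(s[rm1] - s[ri]),
        abs(s[ri] - s[rp1]),
        np.mean(w012),
        np.mean(w016),
        np.mean(g012),
        np.mean(g016),
        np.mean(g023),
        np.var(g006),
        np.max(w008) - np.min(w008),
    ])


def beat_feature_matrix(
    x: TimeSeries, beats: list[BeatAnnotation]
) -> tuple[np.ndarray, np.ndarray]:
    """Feature vectors for every classifiable beat.

    Returns ``(F, idx)``: ``F[k]`` is the 13-vector of beat ``idx[k]``;
    beats without full context are omitted.
    """
    rows, idx = [], []
    for i in range(2, len(beats) - 1):
        rows.append(beat_features(x, beats, i))
        idx.append(i)
    if not rows:
        return np.empty((0, len(BEAT_FEATURE_NAMES))), np.empty(0, dtype=int)
    return np.vstack(rows), np.asarray(idx, dtype=int)


def window_stats(segment: TimeSeries) -> list[WindowStats]:
    """0.5-s windows shifted by 0.25 s over one segment.

    Only fully contained windows are emitted; a nominal 5-s segment yields
    19 windows starting at 0, 0.25, ..., 4.5 s.
    """
    n_win = int(round(WINDOW_S * segment.fs))
    n_shift = int(round(WINDOW_SHIFT_S * segment.fs))
    s = segment.samples
    if s.size < n_win:
        raise ValueError("segment shorter than one window")
    out = []
    for start in range(0, s.size - n_win + 1, n_shift):
        w = s[start:start + n_win]
        a = np.abs(w)
        out.append(WindowStats(
            start_s=start / segment.fs,
            mean=float(np.mean(w)),
            var=float(np.var(w)),
            min=float(np.min(w)),
            max=float(np.max(w)),
            abs_mean=float(np.mean(a)),
            abs_var=float(np.var(a)),
        ))
    return out


def quality_features(ws: list[WindowStats]) -> np.ndarray:
    """The 9 segment-level aggregates of the window statistics.

    Column order follows :data:`QUALITY_FEATURE_NAMES`.
    """
    if len(ws) < 2:
        raise ValueError("need at least 2 windows")
    means = np.array([w.mean for w in ws])
    vars_ = np.array([w.var for w in ws])
    abs_means = np.array([w.abs_mean for w in ws])
    abs_vars = np.array([w.abs_var for w in ws])
    k = np.arange(len(ws), dtype=float)
    # least-squares slope of window variance vs. window index
    grad_of_vars = float(np.polyfit(k, vars_, 1)[0])
    return np.array([
        np.mean(means),
        np.mean(vars_),
        np.var(vars_),
        grad_of_vars,
        np.min(means),
        np.min(vars_),
        np.max(vars_) - np.min(vars_),
        np.max(abs_vars) - np.min(abs_vars),
        np.mean(abs_means),
    ])


def segment_quality_matrix(x: TimeSeries) -> np.ndarray:
    """Quality feature vectors for each consecutive 5-s segment.

    The recording is partitioned into non-overlapping 5-s segments
    (half-open [k*5, (k+1)*5) in seconds); a trailing remainder < 5 s is
    discarded.
    """
    n_seg = int(round(SEGMENT_S * x.fs))
    n = x.samples.size // n_seg
    rows = []
    for k in range(n):
        seg = TimeSeries(x.samples[k * n_seg:(k + 1) * n_seg], x.fs,
                         t0=x.t0 + k * SEGMENT_S)
        rows.append(quality_features(window_stats(seg)))
    if not rows:
        return np.empty((0, len(QUALITY_FEATURE_NAMES)))
    return np.vstack(rows)


def deviation_magnitude(ax: TimeSeries, ay: TimeSeries, az: TimeSeries) -> float:
    """sqrt(var(ax) + var(ay) + var(az)) over one segment, in g.

    Rotation-invariant for rigid re-orientation of the sensor frame (the
    trace of the covariance is preserved).
    """
    if not (len(ax) == len(ay) == len(az)):
        raise ValueError("axis segments must have equal length")
    return float(np.sqrt(np.var(ax.samples) + np.var(ay.samples)
                         + np.var(az.samples)))


def vector_magnitude_sd(ax: TimeSeries, ay: TimeSeries, az: TimeSeries) -> float:
    """Alternative activity feature: SD of the acceleration vector norm."""
    if not (len(ax) == len(ay) == len(az)):
        raise ValueError("axis segments must have equal length")
    norm = np.sqrt(ax.samples ** 2 + ay.samples ** 2 + az.samples ** 2)
    return float(np.std(norm))


def segment_activity_matrix(ax: TimeSeries, ay: TimeSeries,
                            az: TimeSeries) -> np.ndarray:
    """Per-5-s-segment deviation magnitude as an (n_segments, 1) matrix."""
    n_seg = int(round(SEGMENT_S * ax.fs))
    n = min(len(ax), len(ay), len(az)) // n_seg
    out = []
    for k in range(n):
        sl = slice(k * n_seg, (k + 1) * n_seg)
        out.append(deviation_magnitude(
            TimeSeries(ax.samples[sl], ax.fs),
            TimeSeries(ay.samples[sl], ay.fs),
            TimeSeries(az.samples[sl], az.fs),
        ))
    return np.asarray(out, dtype=float).reshape(-1, 1)


def calibrate_features(reference_means: np.ndarray,
                       target: np.ndarray) -> np.ndarray:
    """Rescale a target population's features onto a reference population.

    Each target column is multiplied by mean_ref / mean_target for that
    feature, so the calibrated target means equal the reference means.
    Used to compensate for systematically weaker movements in one cohort
    (e.g. elderly vs. young subjects).
    """
    target = np.atleast_2d(np.asarray(target, dtype=float))
    ref = np.asarray(reference_means, dtype=float)
    t_means = target.mean(axis=0)
    if np.any(t_means == 0):
        bad = np.nonzero(t_means == 0)[0].tolist()
        raise ValueError(f"zero target mean for feature column(s) {bad}")
    return target * (ref / t_means)
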