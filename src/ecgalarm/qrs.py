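"""QRS detection with a low-sampling-rate slope-threshold algorithm.

The detector is a modification of the So-and-Chan slope family aimed at
wearable nodes sampling at ~100 Hz:

* the slope uses only two samples, ``Slope(t) = S(t+1) - S(t-1)``;
* a QRS onset is declared by comparing the slope at a single sample with
  an adaptive threshold (a fraction of a running maximum slope).

An inverted-polarity pass (reverse R-wave detection) can be run alongside
the normal pass; the pass producing the more regular RR series is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import TimeSeries


@dataclass(frozen=True)
class BeatAnnotation:
    """One detected or reference heartbeat.

    onset_index <= r_index; r_index is the sample of maximal |amplitude|
    within the search window after onset.
    """

    onset_index: int
    r_index: int
    source: str = "detected"
    label: str | None = None

    def __post_init__(self) -> None:
        if self.onset_index > self.r_index:
            raise ValueError("onset_index must not exceed r_index")


@dataclass(frozen=True)
class DetectorParams:
    """Tunables of the slope detector.

    The source algorithm's internal constants are not published alongside
    the two-sample/single-sample modifications, so they are explicit,
    config-exposed parameters here.
    """

    slope_threshold_fraction: float = 0.7
    refractory_s: float = 0.25
    rpeak_search_s: float = 0.12
    init_window_s: float = 2.0
    maxslope_update_weight: float = 1.0 / 16.0
    maxslope_growth_cap: float = 1.2
    dropout_s: float = 2.0
    detect_inverted: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.slope_threshold_fraction < 1:
            raise ValueError("slope_threshold_fraction must be in (0, 1)")
        for name in ("refractory_s", "rpeak_search_s", "init_window_s",
                     "maxslope_update_weight", "dropout_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.maxslope_growth_cap <= 1.0:
            raise ValueError("maxslope_growth_cap must exceed 1")
        if self.refractory_s < self.rpeak_search_s:
            raise ValueError("refractory_s must be >= rpeak_search_s")


def slope_series(x: TimeSeries) -> tuple[np.ndarray, np.ndarray]:
    """Two-sample slope ``Slope(t) = S(t+1) - S(t-1)``.

    Returns ``(slope, valid)`` where slope has the input length, is zero at
    the two endpoints, and ``valid`` marks the interior samples where the
    definition applies — keeping downstream windowing length-aligned.
    """
    s = x.samples
    if s.size < 3:
        raise ValueError("slope_series needs at least 3 samples")
    slope = np.zeros_like(s)
    slope[1:-1] = s[2:] - s[:-2]
    valid = np.zeros(s.size, dtype=bool)
    valid[1:-1] = True
    return slope, valid


def _detect_onepass(
    samples: np.ndarray, refine: np.ndarray, fs: float, p: DetectorParams
) -> list[BeatAnnotation]:
    """Single-polarity scan: positive slope vs. adaptive threshold."""
    n = samples.size
    slope = np.zeros(n)
    slope[1:-1] = samples[2:] - samples[:-2]

    init_n = min(n, max(3, int(round(p.init_window_s * fs))))
    maxslope = float(np.max(slope[:init_n]))
    if maxslope <= 0:
        # no positive excursion in the init window; seed from the whole
        # record so a late first beat is still detectable
        maxslope = float(np.max(slope))
        if maxslope <= 0:
            return []

    refractory_n = int(round(p.refractory_s * fs))
    search_n = max(1, int(round(p.rpeak_search_s * fs)))
    dropout_n = int(round(p.dropout_s * fs))
    w = p.maxslope_update_weight

    beats: list[BeatAnnotation] = []
    t = 1
    last_event = 0
    while t < n - 1:
        if t - last_event > dropout_n:
            # no QRS for a while (noise burst inflated the running max):
            # halve the threshold reference and keep scanning
            maxslope *= 0.5
            last_event = t
        if slope[t] > p.slope_threshold_fraction * maxslope:
            onset = t
            hi = min(n, onset + search_n + 1)
            r = onset + int(np.argmax(np.abs(refine[onset:hi])))
            # slew-limited adaptation: an artifact's huge slopes may not
            # ratchet the threshold far above true QRS slopes
            local_max = min(float(np.max(slope[onset:hi])),
                            p.maxslope_growth_cap * maxslope)
            maxslope = (1 - w) * maxslope + w * local_max
            beats.append(BeatAnnotation(onset_index=onset, r_index=r))
            last_event = onset
            t = onset + refractory_n
        else:
            t += 1
    return beats


def _pass_score(beats: list[BeatAnnotation], refine: np.ndarray) -> tuple:
    """Ranking key for polarity-pass selection (lower is better).

    Primary: RR coefficient of variation, rounded so that near-ties fall
    through to the secondary criterion; secondary: larger median |amplitude|
    at the detected R positions (true R peaks dominate trailing edges).
    """
    if len(beats) < 3:
        return (np.inf, 0.0)
    r = np.array([b.r_index for b in beats], dtype=int)
    rr = np.diff(r).astype(float)
    m = rr.mean()
    cv = float(rr.std() / m) if m > 0 else np.inf
    med_amp = float(np.median(np.abs(refine[r])))
    return (round(cv, 2), -med_amp)


def detect_beats(x: TimeSeries, p: DetectorParams | None = None,
                 refine_on: TimeSeries | None = None) -> list[BeatAnnotation]:
    """Detect heartbeats on a band-passed ECG.

    Parameters
    ----------
    x : TimeSeries
        Band-passed ECG (output of :func:`ecgalarm.preprocess.ecg_bandpass`).
    p : DetectorParams
        Detector tunables; defaults per :class:`DetectorParams`.
    refine_on : TimeSeries, optional
        Signal on which the R-peak position is refined (the normalised,
        unfiltered ECG); defaults to ``x`` itself. Band-passing distorts the
        R amplitude that the morphology features read, so callers normally
        pass the normalised trace here.

    When ``p.detect_inverted`` is set, a second pass runs on the negated
    signal and the pass whose RR series has the smaller coefficient of
    variation is kept (reverse R-wave detection).
    """
    p = p or DetectorParams()
    refine = (refine_on.samples if refine_on is not None else x.samples)
    if refine.size != x.samples.size:
        raise ValueError("refine_on must be length-aligned with x")

    beats = _detect_onepass(x.samples, refine, x.fs, p)
    if p.detect_inverted:
        inv = _detect_onepass(-x.samples, refine, x.fs, p)
        if _pass_score(inv, refine) < _pass_score(beats, refine):
            beats = inv
    return beats


def rr_intervals(beats: list[BeatAnnotation], fs: float) -> np.ndarray:
    """RR[i] = (R[i] - R[i-1]) / fs in seconds; empty for < 2 beats."""
    if len(beats) < 2:
        return np.empty(0)
    r = np.array([b.r_index for b in beats], dtype=float)
    return np.diff(r) / fs
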