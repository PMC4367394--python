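"""Signal conditioning for single-lead ECG and tri-axial acceleration.

Two operations feed the rest of the pipeline:

* second-order Butterworth filtering — a 15 Hz low-pass (muscle noise,
  mains interference) cascaded with a 5 Hz high-pass (baseline drift),
  applied only upstream of QRS detection;
* outlier-robust Z-score normalisation — samples further than
  1.5 original standard deviations from the median are excluded from the
  scale estimate, so motion-artifact spikes do not inflate it.

Filtering is zero-phase (forward-backward) by default so detected R-peak
positions are not delayed relative to reference annotations; a causal mode
is available for streaming emulation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal


class DegenerateSignalError(ValueError):
    """Raised when a signal has no usable variance (e.g. constant input)."""


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled signal.

    Parameters
    ----------
    samples : array of float
        Amplitudes (ECG in mV or normalised units; acceleration in g).
    fs : float
        Sampling rate in Hz, > 0.
    t0 : float
        Start time in seconds.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", arr)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError("signal must be 1-D with at least 2 samples")
        if not np.all(np.isfinite(arr)):
            raise ValueError("signal contains non-finite samples")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    def with_samples(self, samples: np.ndarray) -> "TimeSeries":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass(frozen=True)
class FilterSpec:
    """One Butterworth stage: kind ('lowpass'|'highpass'), cutoff Hz, order."""

    kind: str
    cutoff: float
    order: int = 2

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "highpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.order < 1:
            raise ValueError("order must be >= 1")


# Cascade defaults: 5 Hz high-pass then 15 Hz low-pass, both order 2.
ECG_HIGHPASS = FilterSpec("highpass", 5.0)
ECG_LOWPASS = FilterSpec("lowpass", 15.0)

#: multiples of the original SD beyond which a sample is an outlier
ROBUST_Z_CUTOFF = 1.5


def butterworth_filter(
    x: TimeSeries, spec: FilterSpec, zero_phase: bool = True
) -> TimeSeries:
    """Apply one Butterworth stage, preserving length, rate and time base.

    Zero-phase mode runs the filter forward and backward (squaring the
    magnitude response, cancelling phase); causal mode is a single forward
    pass.
    """
    if spec.cutoff >= x.fs / 2:
        raise ValueError(
            f"cutoff {spec.cutoff} Hz >= Nyquist ({x.fs / 2} Hz) for fs={x.fs}"
        )
    sos = signal.butter(spec.order, spec.cutoff, btype=spec.kind, fs=x.fs, output="sos")
    if zero_phase:
        y = signal.sosfiltfilt(sos, x.samples)
    else:
        y = signal.sosfilt(sos, x.samples)
    return x.with_samples(y)


def ecg_bandpass(x: TimeSeries, zero_phase: bool = True) -> TimeSeries:
    """5 Hz high-pass then 15 Hz low-pass cascade used before QRS detection.

    The band-passed trace is used for slope thresholding only; morphology
    features read the normalised (unfiltered) amplitude.
    """
    y = butterworth_filter(x, ECG_HIGHPASS, zero_phase=zero_phase)
    return butterworth_filter(y, ECG_LOWPASS, zero_phase=zero_phase)


def robust_zscore_params(samples: np.ndarray) -> tuple[float, float]:
    """Return (center, scale) of the outlier-robust Z-score.

    A sample is an inlier when |s - median| <= 1.5 * sd(all samples)
    (population SD). The center is the inlier mean and the scale the inlier
    population SD.
    """
    s = np.asarray(samples, dtype=float)
    med = np.median(s)
    sd0 = float(np.std(s))
    inliers = s[np.abs(s - med) <= ROBUST_Z_CUTOFF * sd0]
    if inliers.size == 0:  # unreachable for finite input, defensive
        raise DegenerateSignalError("no inlier samples")
    center = float(np.mean(inliers))
    scale = float(np.std(inliers))
    if scale == 0.0:
        raise DegenerateSignalError("constant inlier set: robust scale is zero")
    return center, scale


def robust_zscore(x: TimeSeries) -> TimeSeries:
    """Normalise a whole recording with the outlier-robust Z-score.

    Applied per recording (per axis for acceleration), never per segment,
    so motion artifacts in one segment cannot rescale its neighbours.
    """
    center, scale = robust_zscore_params(x.samples)
    return x.with_samples((x.samples - center) / scale)
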