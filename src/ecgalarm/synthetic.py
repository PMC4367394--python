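"""Synthetic coupled ECG + tri-axial acceleration sessions with ground truth.

Emulates a body-sensor-network recording protocol: a subject performs a
routine of ~20-s activity bouts alternating static postures (sitting,
lying, standing) and dynamic activities (walking, jogging, arm movement).
The generator produces

* a single-lead ECG at 100 Hz — beats as sums of Gaussian lobes
  (P/Q/R/S/T); PVC-like abnormal beats are premature (RR x 0.6), widened
  (x 2), taller (x 1.8), lack a P wave and are followed by a compensatory
  pause;
* tri-axial acceleration at the same rate — static bouts are a constant
  gravity projection plus sensor noise, dynamic bouts add a 1-3 Hz
  oscillation of 0.3-0.8 g, and every bout boundary carries a 1.5-s
  high-amplitude motion spike;
* ground truth: the beat schedule with types, per-5-s-segment quality
  labels (low iff the segment overlaps an injected noise burst) and
  activity labels (raw static/non-static and refined
  static/transition/dynamic, from the bout schedule).

Every random quantity flows from named child streams (beat schedule, ECG
noise, acceleration noise, subject-level perturbation) of the master seed,
so sub-streams are independently reproducible and the whole recording is
bit-reproducible given the seed.

This is a test-bench model, not physiology: waveform shapes, artifact
spectra and the PVC parameterisation are chosen so that the documented
feature sets separate the classes by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .preprocess import TimeSeries
from .rules import DYNAMIC, HIGH, LOW, NON_STATIC, STATIC, TRANSITION

#: (name, kind, duration s) — a 120-s routine of alternating bouts
DEFAULT_SCHEDULE = (
    ("sitting", STATIC, 20.0),
    ("walking", DYNAMIC, 20.0),
    ("standing", STATIC, 20.0),
    ("jogging", DYNAMIC, 20.0),
    ("lying", STATIC, 20.0),
    ("arm_movement", DYNAMIC, 20.0),
)

SEGMENT_S = 5.0
#: half-width of the motion-artifact window straddling a bout boundary
TRANSITION_HALF_S = 0.75


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic session."""

    fs: float = 100.0
    activity_schedule: tuple = DEFAULT_SCHEDULE
    base_hr: float = 75.0          # bpm
    hr_jitter: float = 0.03        # fractional RR noise
    pvc_rate: float = 0.0          # abnormal-beat probability
    inject_pvc_at: float | None = None  # force one PVC near this time (s)
    noise_bursts: tuple = ()       # (start s, duration s, sigma) triples
    transition_artifact: float = 0.4   # ECG artifact amplitude (norm. units)
    accel_spike_g: float = 1.0     # acceleration transition spike (g)
    noise_floor: float = 0.01      # ever-present ECG white noise SD
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.activity_schedule:
            raise ValueError("activity schedule is empty")
        for name, kind, dur in self.activity_schedule:
            if dur <= 0:
                raise ValueError(f"bout {name!r} has non-positive duration")
            if kind not in (STATIC, DYNAMIC):
                raise ValueError(f"bout kind must be static|dynamic, got {kind!r}")
        if not 0 <= self.pvc_rate <= 1:
            raise ValueError("pvc_rate must be in [0, 1]")
        for start, dur, sigma in self.noise_bursts:
            if dur <= 0 or sigma < 0:
                raise ValueError("noise bursts need positive duration, sigma >= 0")
        if self.total_s < 10.0:
            raise ValueError("schedule must cover at least 10 s")

    @property
    def total_s(self) -> float:
        return float(sum(d for _, _, d in self.activity_schedule))

    def bout_boundaries(self) -> np.ndarray:
        """Interior bout-change times in seconds."""
        edges = np.cumsum([d for _, _, d in self.activity_schedule])
        return edges[:-1]


@dataclass(frozen=True)
class GroundTruth:
    """Labels recomputable from the ScenarioSpec alone."""

    beat_times: np.ndarray          # seconds, strictly increasing
    beat_types: tuple               # 'normal' | 'pvc'
    segment_quality: tuple          # 'high' | 'low'
    segment_activity_raw: tuple     # 'static' | 'non-static'
    segment_activity_refined: tuple  # 'static' | 'transition' | 'dynamic'
    bout_names: tuple


def _streams(seed: int) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    names = ("beat-schedule", "ecg-noise", "accel-noise", "subject")
    return {n: np.random.default_rng(c) for n, c in zip(names, ss.spawn(len(names)))}


def _bout_kind_at(spec: ScenarioSpec, t: float) -> str:
    edge = 0.0
    for _, kind, dur in spec.activity_schedule:
        edge += dur
        if t < edge:
            return kind
    return spec.activity_schedule[-1][1]


def segment_truth(spec: ScenarioSpec) -> tuple[tuple, tuple, tuple]:
    """Quality, raw-activity and refined-activity labels per 5-s segment."""
    n_seg = int(spec.total_s // SEGMENT_S)
    boundaries = spec.bout_boundaries()
    quality, raw, refined = [], [], []
    for k in range(n_seg):
        lo, hi = k * SEGMENT_S, (k + 1) * SEGMENT_S
        is_low = any(lo < s + d and s < hi
                     for s, d, _sigma in spec.noise_bursts)
        quality.append(LOW if is_low else HIGH)
        on_boundary = any(lo < b + TRANSITION_HALF_S and b - TRANSITION_HALF_S < hi
                          for b in boundaries)
        if on_boundary:
            raw.append(NON_STATIC)
            refined.append(TRANSITION)
        else:
            kind = _bout_kind_at(spec, (lo + hi) / 2)
            raw.append(STATIC if kind == STATIC else NON_STATIC)
            refined.append(STATIC if kind == STATIC else DYNAMIC)
    return tuple(quality), tuple(raw), tuple(refined)


def _beat_schedule(spec: ScenarioSpec,
                   rng: np.random.Generator) -> tuple[np.ndarray, tuple]:
    """Beat times and types; a PVC is premature and followed by a pause."""
    base_rr = 60.0 / spec.base_hr
    times, types = [], []
    t = 0.4
    compensatory = False
    injected = spec.inject_pvc_at is None
    while True:
        rr = base_rr * (1.0 + spec.hr_jitter * rng.standard_normal())
        is_pvc = rng.random() < spec.pvc_rate
        if not injected and times and times[-1] + rr >= spec.inject_pvc_at:
            is_pvc = True
            injected = True
        if is_pvc:
            rr *= 0.6
        elif compensatory:
            rr *= 1.4
        rr = float(np.clip(rr, 0.3, 2.0))
        if times:
            t = times[-1] + rr
        if t > spec.total_s - 0.4:
            break
        times.append(t)
        types.append("pvc" if is_pvc else "normal")
        compensatory = is_pvc
    return np.asarray(times), tuple(types)


def _add_lobe(sig: np.ndarray, fs: float, t_c: float, amp: float,
              sigma_s: float) -> None:
    """Add a Gaussian lobe in place over a +-4 sigma support."""
    n = sig.size
    lo = max(0, int((t_c - 4 * sigma_s) * fs))
    hi = min(n, int((t_c + 4 * sigma_s) * fs) + 1)
    if lo >= hi:
        return
    t = np.arange(lo, hi) / fs
    sig[lo:hi] += amp * np.exp(-0.5 * ((t - t_c) / sigma_s) ** 2)


def generate_ecg(spec: ScenarioSpec) -> tuple[TimeSeries, GroundTruth]:
    """One synthetic single-lead ECG recording with its ground truth."""
    streams = _streams(spec.seed)
    beat_times, beat_types = _beat_schedule(spec, streams["beat-schedule"])
    fs = spec.fs
    n = int(round(spec.total_s * fs))
    sig = np.zeros(n)

    for tb, kind in zip(beat_times, beat_types):
        if kind == "pvc":
            amp, wq = 1.8, 0.036
            _add_lobe(sig, fs, tb - 0.07, -0.25, 0.024)   # Q
            _add_lobe(sig, fs, tb, amp, wq)               # R
            _add_lobe(sig, fs, tb + 0.07, -0.30, 0.024)   # S
            _add_lobe(sig, fs, tb + 0.32, -0.40, 0.06)    # discordant T
        else:
            _add_lobe(sig, fs, tb - 0.18, 0.15, 0.025)    # P
            _add_lobe(sig, fs, tb - 0.035, -0.12, 0.012)  # Q
            _add_lobe(sig, fs, tb, 1.0, 0.018)            # R
            _add_lobe(sig, fs, tb + 0.035, -0.15, 0.012)  # S
            _add_lobe(sig, fs, tb + 0.25, 0.35, 0.05)     # T

    rng = streams["ecg-noise"]
    t = np.arange(n) / fs
    phase = rng.uniform(0, 2 * np.pi)
    sig += 0.08 * np.sin(2 * np.pi * 0.25 * t + phase)    # baseline wander
    sig += spec.noise_floor * rng.standard_normal(n)

    for start, dur, sigma in spec.noise_bursts:
        lo = max(0, int(start * fs))
        hi = min(n, int((start + dur) * fs))
        sig[lo:hi] += sigma * rng.standard_normal(max(0, hi - lo))

    for b in spec.bout_boundaries():
        lo = max(0, int((b - TRANSITION_HALF_S) * fs))
        hi = min(n, int((b + TRANSITION_HALF_S) * fs))
        env = np.hanning(hi - lo)
        sig[lo:hi] += spec.transition_artifact * env * rng.standard_normal(hi - lo)

    quality, raw, refined = segment_truth(spec)
    truth = GroundTruth(
        beat_times=beat_times, beat_types=beat_types,
        segment_quality=quality, segment_activity_raw=raw,
        segment_activity_refined=refined,
        bout_names=tuple(name for name, _, _ in spec.activity_schedule),
    )
    return TimeSeries(sig, fs), truth


def generate_accel(spec: ScenarioSpec) -> tuple[tuple, GroundTruth]:
    """Tri-axial acceleration time-aligned with :func:`generate_ecg`."""
    rng = _streams(spec.seed)["accel-noise"]
    fs = spec.fs
    n = int(round(spec.total_s * fs))
    t = np.arange(n) / fs
    axes = np.zeros((3, n))

    # per-bout baselines: gravity orientation + optional oscillation
    edge = 0.0
    for name, kind, dur in spec.activity_schedule:
        lo, hi = int(edge * fs), min(n, int((edge + dur) * fs))
        g_dir = rng.standard_normal(3)
        g_dir /= np.linalg.norm(g_dir)
        for a in range(3):
            axes[a, lo:hi] = g_dir[a]
        if kind == DYNAMIC:
            f = rng.uniform(1.0, 3.0)
            amp = rng.uniform(0.3, 0.8)
            weights = rng.dirichlet(np.ones(3))
            for a in range(3):
                phase = rng.uniform(0, 2 * np.pi)
                axes[a, lo:hi] += (amp * np.sqrt(weights[a])
                                   * np.sin(2 * np.pi * f * t[lo:hi] + phase))
        edge += dur

    axes += 0.02 * rng.standard_normal((3, n))  # sensor noise

    for b in spec.bout_boundaries():
        lo = max(0, int((b - TRANSITION_HALF_S) * fs))
        hi = min(n, int((b + TRANSITION_HALF_S) * fs))
        env = np.hanning(hi - lo)
        for a in range(3):
            axes[a, lo:hi] += spec.accel_spike_g * env * rng.standard_normal(hi - lo)

    quality, raw, refined = segment_truth(spec)
    # ECG ground truth holds the beat schedule; replicate it so either
    # generator's truth object is complete on its own
    beat_times, beat_types = _beat_schedule(spec, _streams(spec.seed)["beat-schedule"])
    truth = GroundTruth(
        beat_times=beat_times, beat_types=beat_types,
        segment_quality=quality, segment_activity_raw=raw,
        segment_activity_refined=refined,
        bout_names=tuple(name for name, _, _ in spec.activity_schedule),
    )
    return tuple(TimeSeries(axes[a], fs) for a in range(3)), truth


@dataclass(frozen=True)
class Recording:
    """One synthetic session: raw signals plus ground truth."""

    spec: ScenarioSpec
    ecg: TimeSeries
    accel: tuple  # (ax, ay, az)
    truth: GroundTruth
    subject_id: int = 0


def generate_recording(spec: ScenarioSpec, subject_id: int = 0) -> Recording:
    ecg, truth = generate_ecg(spec)
    accel, _ = generate_accel(spec)
    return Recording(spec=spec, ecg=ecg, accel=accel, truth=truth,
                     subject_id=subject_id)


def _perturbed_spec(template: ScenarioSpec, rng: np.random.Generator,
                    subject_seed: int) -> ScenarioSpec:
    """Subject-level variation: heart rate, artifact scale, noise bursts."""
    base_hr = float(np.clip(rng.normal(template.base_hr, 6.0), 62.0, 92.0))
    artifact = template.transition_artifact * rng.uniform(0.8, 1.2)
    # low-quality episodes: roughly one 4-s burst per minute of recording
    n_bursts = rng.poisson(template.total_s / 60.0)
    bursts = []
    for _ in range(n_bursts):
        start = rng.uniform(0.0, max(1.0, template.total_s - 6.0))
        dur = rng.uniform(3.0, 6.0)
        sigma = rng.uniform(1.5, 3.0)
        bursts.append((float(start), float(dur), float(sigma)))
    return replace(
        template, base_hr=base_hr, transition_artifact=artifact,
        noise_bursts=tuple(bursts), seed=subject_seed,
    )


def perturbed_recording(template: ScenarioSpec | None = None, seed: int = 0,
                        inject_pvc_at: float | None = None,
                        subject_id: int = 0) -> Recording:
    """One subject-varied session drawn from the cohort distribution.

    Useful for held-out test subjects whose noise and heart-rate
    characteristics match the training cohort's; optionally forces a single
    PVC near ``inject_pvc_at`` seconds.
    """
    template = template or ScenarioSpec()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    spec = _perturbed_spec(template, rng, int(rng.integers(2 ** 31)))
    if inject_pvc_at is not None:
        spec = replace(spec, inject_pvc_at=inject_pvc_at)
    return generate_recording(spec, subject_id=subject_id)


def generate_cohort(n_subjects: int, template: ScenarioSpec | None = None,
                    seed: int = 0) -> list[Recording]:
    """A cohort of subject-varied sessions for leave-one-subject-out runs."""
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    template = template or ScenarioSpec()
    master = np.random.SeedSequence(seed)
    recs = []
    for sid, child in enumerate(master.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        subject_seed = int(rng.integers(2 ** 31))
        spec = _perturbed_spec(template, rng, subject_seed)
        recs.append(generate_recording(spec, subject_id=sid))
    return recs
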