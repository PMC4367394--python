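"""Readers and writers: CSV sessions, YAML configs, optional WFDB records.

CSV is the canonical session format (plain text, UTF-8, '.' decimal):

* ``ecg.csv`` — header ``time,value``, time in seconds;
* ``accel.csv`` — header ``time,x,y,z``, acceleration in g;
* ``beats.csv`` — header ``onset_index,r_index,label``;
* ``truth_beats.csv`` / ``truth_segments.csv`` — generator ground truth.

WFDB (MIT-BIH-style record + annotation) reading is optional: the ``wfdb``
package is imported lazily, so the package installs and tests without it.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import PACED_RECORDS
from .pipeline import PipelineConfig
from .preprocess import TimeSeries
from .qrs import BeatAnnotation
from .synthetic import GroundTruth, Recording, ScenarioSpec


class ExcludedRecordError(ValueError):
    """A paced MIT-BIH record was requested without the override flag."""


def write_timeseries(path, x: TimeSeries) -> None:
    pd.DataFrame({"time": x.times(), "value": x.samples}).to_csv(path, index=False)


def read_timeseries(path) -> TimeSeries:
    df = pd.read_csv(path)
    t = df["time"].to_numpy()
    fs = 1.0 / np.median(np.diff(t))
    return TimeSeries(df["value"].to_numpy(), fs=float(round(fs, 6)), t0=float(t[0]))


def write_accel(path, ax: TimeSeries, ay: TimeSeries, az: TimeSeries) -> None:
    pd.DataFrame({
        "time": ax.times(), "x": ax.samples, "y": ay.samples, "z": az.samples,
    }).to_csv(path, index=False)


def read_accel(path) -> tuple[TimeSeries, TimeSeries, TimeSeries]:
    df = pd.read_csv(path)
    t = df["time"].to_numpy()
    fs = float(round(1.0 / np.median(np.diff(t)), 6))
    t0 = float(t[0])
    return tuple(TimeSeries(df[c].to_numpy(), fs=fs, t0=t0) for c in "xyz")


def write_beats(path, beats: list[BeatAnnotation]) -> None:
    pd.DataFrame({
        "onset_index": [b.onset_index for b in beats],
        "r_index": [b.r_index for b in beats],
        "label": [b.label or "" for b in beats],
    }).to_csv(path, index=False)


def read_beats(path) -> list[BeatAnnotation]:
    df = pd.read_csv(path, keep_default_na=False)
    return [
        BeatAnnotation(int(r.onset_index), int(r.r_index),
                       label=(str(r.label) or None))
        for r in df.itertuples()
    ]


def save_config(path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh))


def write_session(directory, rec: Recording) -> Path:
    """Write one synthetic session: signals, ground truth, scenario spec."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_timeseries(d / "ecg.csv", rec.ecg)
    write_accel(d / "accel.csv", *rec.accel)
    pd.DataFrame({
        "time": rec.truth.beat_times, "type": list(rec.truth.beat_types),
    }).to_csv(d / "truth_beats.csv", index=False)
    pd.DataFrame({
        "index": range(len(rec.truth.segment_quality)),
        "quality": list(rec.truth.segment_quality),
        "activity_raw": list(rec.truth.segment_activity_raw),
        "activity_refined": list(rec.truth.segment_activity_refined),
    }).to_csv(d / "truth_segments.csv", index=False)
    spec = dataclasses.asdict(rec.spec)
    spec["activity_schedule"] = [list(b) for b in rec.spec.activity_schedule]
    spec["noise_bursts"] = [list(b) for b in rec.spec.noise_bursts]
    with open(d / "spec.yaml", "w") as fh:
        yaml.safe_dump(spec, fh, sort_keys=True)
    return d


def read_session(directory) -> Recording:
    d = Path(directory)
    with open(d / "spec.yaml") as fh:
        raw = yaml.safe_load(fh)
    raw["activity_schedule"] = tuple(tuple(b) for b in raw["activity_schedule"])
    raw["noise_bursts"] = tuple(tuple(b) for b in raw["noise_bursts"])
    spec = ScenarioSpec(**raw)
    ecg = read_timeseries(d / "ecg.csv")
    accel = read_accel(d / "accel.csv")
    tb = pd.read_csv(d / "truth_beats.csv")
    ts = pd.read_csv(d / "truth_segments.csv")
    truth = GroundTruth(
        beat_times=tb["time"].to_numpy(),
        beat_types=tuple(tb["type"]),
        segment_quality=tuple(ts["quality"]),
        segment_activity_raw=tuple(ts["activity_raw"]),
        segment_activity_refined=tuple(ts["activity_refined"]),
        bout_names=tuple(name for name, _, _ in spec.activity_schedule),
    )
    return Recording(spec=spec, ecg=ecg, accel=accel, truth=truth)


def write_report(path, report: dict) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_wfdb_record(path, channel: int = 0, allow_paced: bool = False
                     ) -> tuple[TimeSeries, list[BeatAnnotation]]:
    """Read an MIT-BIH-style record + annotation pair via the wfdb package.

    Paced records (102, 104, 107, 217) are rejected unless ``allow_paced``
    is set. Requires the optional ``wfdb`` dependency.
    """
    record_name = Path(path).name
    if record_name in PACED_RECORDS and not allow_paced:
        raise ExcludedRecordError(
            f"record {record_name} is paced and excluded by default; "
            "pass allow_paced=True to override")
    try:
        import wfdb  # noqa: PLC0415 -- optional dependency
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise ImportError(
            "reading WFDB records requires the optional 'wfdb' package "
            "(pip install ecgalarm[wfdb])") from exc
    rec = wfdb.rdrecord(str(path), channels=[channel])
    ann = wfdb.rdann(str(path), "atr")
    x = TimeSeries(rec.p_signal[:, 0], fs=float(rec.fs))
    beats = [
        BeatAnnotation(onset_index=int(s), r_index=int(s), source="reference",
                       label=sym)
        for s, sym in zip(ann.sample, ann.symbol)
    ]
    return x, beats
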