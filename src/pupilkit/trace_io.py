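"""Pupil-trace and reading-record interchange formats.

The acquisition device's native file format is proprietary, so this package
defines its own plain long-format CSV dialects and reads/writes them
losslessly:

* **Trace CSV** -- one row per sample, header
  ``subject_id,visit,eye,condition,repeat,lux,sampling_rate_hz,stimulus_onset_s,
  stimulus_duration_s,t_s,diameter_mm,device_valid``. UTF-8, ``.`` decimal
  separator, ``device_valid`` in {0, 1}, an empty ``diameter_mm`` field means
  the pupil was not tracked for that sample.
* **Reading CSV** -- one row per estimated minimal pupil size, header
  ``subject_id,visit,eye,condition,method,pupil_mm,n_repeats_used,quality_flags``.

A trace covers one 13 s examination: 3 s of darkness followed by a 10 s light
stimulus, under either mesopic (4 lux) or photopic (300 lux) illumination,
repeated up to five times per session. Missing diameters (lost pupil
tracking) and ``device_valid = 0`` are distinct states: both are discarded by
the reading algorithm but are accounted for separately.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterator, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import TraceFormatError, TraceIntegrityError, DataError

__all__ = [
    "PupilSample",
    "PupilTrace",
    "ReadingRecord",
    "read_traces",
    "write_traces",
    "read_readings",
    "write_readings",
    "CONDITION_LUX",
    "VISITS",
    "EYES",
    "CONDITIONS",
    "METHODS",
]

logger = logging.getLogger(__name__)

VISITS = ("screening", "baseline")
EYES = ("right", "left")
CONDITIONS = ("mesopic", "photopic")
METHODS = ("human", "automated")

#: Protocol illuminance for each light condition (lux).
CONDITION_LUX = {"mesopic": 4.0, "photopic": 300.0}

#: Plausibility band for a minimal pupil size reading (mm).
PLAUSIBLE_PUPIL_MM = (2.0, 9.0)

TRACE_COLUMNS = [
    "subject_id",
    "visit",
    "eye",
    "condition",
    "repeat",
    "lux",
    "sampling_rate_hz",
    "stimulus_onset_s",
    "stimulus_duration_s",
    "t_s",
    "diameter_mm",
    "device_valid",
]

READING_COLUMNS = [
    "subject_id",
    "visit",
    "eye",
    "condition",
    "method",
    "pupil_mm",
    "n_repeats_used",
    "quality_flags",
]


class PupilSample(NamedTuple):
    """One sample of a pupil-diameter time series."""

    t: float
    diameter: Optional[float]  # mm; None when the pupil was not tracked
    device_valid: bool


@dataclass
class PupilTrace:
    """One eye's continuous diameter time series for one 13 s examination.

    ``diameter`` uses NaN for missing samples. Timestamps are seconds from
    recording start; the light stimulus turns on at ``stimulus_onset``
    (protocol value 3.0 s) and lasts ``stimulus_duration`` (10.0 s).
    """

    subject_id: str
    visit: str
    eye: str
    condition: str
    repeat_index: int
    lux: float
    sampling_rate: float
    stimulus_onset: float
    stimulus_duration: float
    t: np.ndarray
    diameter: np.ndarray
    device_valid: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.diameter = np.asarray(self.diameter, dtype=float)
        self.device_valid = np.asarray(self.device_valid, dtype=bool)

    @property
    def key(self) -> tuple:
        return (self.subject_id, self.visit, self.eye, self.condition, self.repeat_index)

    @property
    def session_key(self) -> tuple:
        return (self.subject_id, self.visit, self.eye, self.condition)

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    def samples(self) -> Iterator[PupilSample]:
        for ti, di, vi in zip(self.t, self.diameter, self.device_valid):
            yield PupilSample(float(ti), None if math.isnan(di) else float(di), bool(vi))

    def validate(self) -> None:
        """Raise :class:`TraceIntegrityError` on any data-model violation."""
        problems = []
        if self.t.size == 0:
            problems.append("trace has no samples")
        else:
            if not np.all(np.diff(self.t) > 0):
                problems.append("timestamps are not strictly increasing")
            present = np.isfinite(self.diameter)
            if present.any():
                d = self.diameter[present]
                if not np.all(np.isfinite(d) & (d > 0)):
                    problems.append("present diameters must be finite and positive")
            span_end = self.stimulus_onset + self.stimulus_duration
            # the last sample may fall one sampling interval short of span_end
            slack = 1.5 / self.sampling_rate if self.sampling_rate > 0 else 0.1
            if self.t[0] > 1e-9 or self.t[-1] < span_end - slack:
                problems.append(
                    f"samples must span [0, {span_end:g}) s, got "
                    f"[{self.t[0]:g}, {self.t[-1]:g}]"
                )
        if self.condition not in CONDITIONS:
            problems.append(f"unknown condition {self.condition!r}")
        elif not math.isclose(self.lux, CONDITION_LUX[self.condition]):
            problems.append(
                f"condition {self.condition!r} requires lux="
                f"{CONDITION_LUX[self.condition]:g}, got {self.lux:g}"
            )
        if self.visit not in VISITS:
            problems.append(f"unknown visit {self.visit!r}")
        if self.eye not in EYES:
            problems.append(f"unknown eye {self.eye!r}")
        if not 1 <= int(self.repeat_index) <= 5:
            problems.append(f"repeat_index must be in 1..5, got {self.repeat_index}")
        if self.sampling_rate <= 0:
            problems.append("sampling_rate must be positive")
        if problems:
            raise TraceIntegrityError(
                f"trace {self.key}: " + "; ".join(problems)
            )


@dataclass
class ReadingRecord:
    """A single minimal-pupil-size reading for one subject/visit/eye/condition.

    ``pupil_mm`` is None when the session fell below the quality threshold;
    in that case ``n_repeats_used`` must be 0. Those records are kept on disk
    so that downstream pairwise analyses can count excluded subjects.
    """

    subject_id: str
    visit: str
    eye: str
    condition: str
    method: str
    pupil_mm: Optional[float]
    n_repeats_used: int
    quality_flags: str = ""

    @property
    def key(self) -> tuple:
        return (self.subject_id, self.visit, self.eye, self.condition, self.method)

    def validate(self) -> None:
        problems = []
        lo, hi = PLAUSIBLE_PUPIL_MM
        if self.pupil_mm is not None and not lo <= self.pupil_mm <= hi:
            problems.append(
                f"pupil_mm={self.pupil_mm:g} outside plausibility band [{lo:g}, {hi:g}]"
            )
        if (self.n_repeats_used == 0) != (self.pupil_mm is None):
            problems.append(
                "n_repeats_used must be 0 exactly when pupil_mm is missing"
            )
        if self.method not in METHODS:
            problems.append(f"unknown method {self.method!r}")
        if self.visit not in VISITS:
            problems.append(f"unknown visit {self.visit!r}")
        if self.condition not in CONDITIONS:
            problems.append(f"unknown condition {self.condition!r}")
        if self.eye not in EYES:
            problems.append(f"unknown eye {self.eye!r}")
        if not 0 <= int(self.n_repeats_used) <= 5:
            problems.append("n_repeats_used must be in 0..5")
        if problems:
            raise TraceIntegrityError(f"reading {self.key}: " + "; ".join(problems))


def _trace_frame(trace: PupilTrace) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": trace.subject_id,
            "visit": trace.visit,
            "eye": trace.eye,
            "condition": trace.condition,
            "repeat": int(trace.repeat_index),
            "lux": trace.lux,
            "sampling_rate_hz": trace.sampling_rate,
            "stimulus_onset_s": trace.stimulus_onset,
            "stimulus_duration_s": trace.stimulus_duration,
            "t_s": trace.t,
            "diameter_mm": trace.diameter,
            "device_valid": trace.device_valid.astype(int),
        }
    )


def write_traces(traces: Sequence[PupilTrace], path) -> None:
    """Write traces in the trace CSV dialect (header-only file when empty).

    Missing diameters are serialized as empty fields, never as sentinel
    numbers; floats use shortest-repr formatting so the round trip through
    :func:`read_traces` is bit-identical.
    """
    frames = [_trace_frame(tr) for tr in traces]
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=TRACE_COLUMNS)
    # shortest-repr float serialization keeps the round trip bit-identical
    for col in ("lux", "sampling_rate_hz", "stimulus_onset_s",
                "stimulus_duration_s", "t_s", "diameter_mm"):
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    df.to_csv(path, index=False)


def read_traces(path, strict: bool = True) -> list[PupilTrace]:
    """Read a trace CSV into one :class:`PupilTrace` per sample group.

    Groups are keyed by (subject, visit, eye, condition, repeat); samples are
    returned sorted by ``t_s``. In strict mode any invariant violation
    (non-monotone timestamps, condition/lux mismatch, ...) raises
    :class:`TraceIntegrityError` identifying the group; in lenient mode the
    offending group is logged and skipped.
    """
    try:
        df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    except (OSError, ValueError, pd.errors.ParserError) as exc:
        raise TraceFormatError(f"cannot parse trace file {path}: {exc}") from exc
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(
            f"trace file {path} is missing required column(s): {', '.join(missing)}"
        )
    traces: list[PupilTrace] = []
    key_cols = ["subject_id", "visit", "eye", "condition", "repeat"]
    for key, grp in df.groupby(key_cols, sort=True):
        try:
            trace = _trace_from_group(key, grp, strict=strict)
            trace.validate()
        except DataError as exc:
            if strict:
                raise
            logger.warning("skipping trace group %s: %s", key, exc)
            continue
        traces.append(trace)
    return traces


def _trace_from_group(key: tuple, grp: pd.DataFrame, strict: bool) -> PupilTrace:
    subject_id, visit, eye, condition, repeat = key
    meta = {}
    for col in ("lux", "sampling_rate_hz", "stimulus_onset_s", "stimulus_duration_s"):
        vals = grp[col].unique()
        if len(vals) != 1:
            raise TraceIntegrityError(
                f"trace {key}: column {col} is not constant within the group"
            )
        meta[col] = float(vals[0])
    t = grp["t_s"].to_numpy(dtype=float)
    if not np.all(np.diff(t) > 0):
        if strict:
            raise TraceIntegrityError(f"trace {key}: non-monotone timestamps")
        order = np.argsort(t, kind="mergesort")
        grp = grp.iloc[order]
        t = t[order]
    dv = grp["device_valid"].to_numpy()
    if not np.isin(dv, (0, 1)).all():
        raise TraceFormatError(f"trace {key}: device_valid must be 0 or 1")
    return PupilTrace(
        subject_id=str(subject_id),
        visit=str(visit),
        eye=str(eye),
        condition=str(condition),
        repeat_index=int(repeat),
        lux=meta["lux"],
        sampling_rate=meta["sampling_rate_hz"],
        stimulus_onset=meta["stimulus_onset_s"],
        stimulus_duration=meta["stimulus_duration_s"],
        t=t,
        diameter=grp["diameter_mm"].to_numpy(dtype=float),
        device_valid=dv.astype(bool),
    )


def write_readings(records: Sequence[ReadingRecord], path) -> None:
    """Write reading records in the reading CSV dialect."""
    rows = []
    for rec in records:
        rows.append(
            {
                "subject_id": rec.subject_id,
                "visit": rec.visit,
                "eye": rec.eye,
                "condition": rec.condition,
                "method": rec.method,
                "pupil_mm": np.nan if rec.pupil_mm is None else rec.pupil_mm,
                "n_repeats_used": int(rec.n_repeats_used),
                "quality_flags": rec.quality_flags,
            }
        )
    df = pd.DataFrame(rows, columns=READING_COLUMNS)
    df.to_csv(path, index=False)


def read_readings(path, strict: bool = True) -> list[ReadingRecord]:
    """Read a reading CSV; duplicate keys always raise, bounds only in strict mode.

    Records with a missing ``pupil_mm`` (quality-threshold failures) survive
    the round trip and become the excluded-subject cases downstream.
    """
    try:
        df = pd.read_csv(
            path,
            dtype={"subject_id": str, "quality_flags": str},
            float_precision="round_trip",
        )
    except (OSError, ValueError, pd.errors.ParserError) as exc:
        raise TraceFormatError(f"cannot parse reading file {path}: {exc}") from exc
    missing = [c for c in READING_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(
            f"reading file {path} is missing required column(s): {', '.join(missing)}"
        )
    key_cols = ["subject_id", "visit", "eye", "condition", "method"]
    dup_mask = df.duplicated(subset=key_cols, keep=False)
    if dup_mask.any():
        dups = df.loc[dup_mask, key_cols].drop_duplicates().itertuples(index=False)
        raise TraceIntegrityError(
            "duplicate reading keys: " + "; ".join(str(tuple(d)) for d in dups)
        )
    records = []
    for row in df.itertuples(index=False):
        pupil = None if pd.isna(row.pupil_mm) else float(row.pupil_mm)
        rec = ReadingRecord(
            subject_id=str(row.subject_id),
            visit=str(row.visit),
            eye=str(row.eye),
            condition=str(row.condition),
            method=str(row.method),
            pupil_mm=pupil,
            n_repeats_used=int(row.n_repeats_used),
            quality_flags="" if pd.isna(row.quality_flags) else str(row.quality_flags),
        )
        if strict:
            rec.validate()
        records.append(rec)
    return records
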