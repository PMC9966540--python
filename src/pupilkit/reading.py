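"""Automated reading of minimal pupil size from light-reflex traces.

The automated reading condenses up to five repeated 13 s examinations into a
single minimal-pupil-size estimate per subject, visit, eye and condition:

1. A Hampel-style filter over a rolling 1.4 s window removes samples whose
   deviation from the local median exceeds 1.5 mm or 3 times the MAD-based
   scale estimate (samples are removed, never replaced).
2. Device-invalid samples, missing samples, diameters outside [2, 9] mm and
   samples more than 0.5 mm away from the previous retained point (a step
   that would imply a constriction velocity of roughly 15 mm/s) are also
   discarded.
3. The median and 10th percentile of the retained diameters are computed in
   the light-interval window 2-4 s after stimulus onset, together with a
   quality score q (retained / total samples in the window) and a weight
   w = q * exp(-2 * d), where d = |median - p10|.
4. Repeats with q > 0.5 contribute their 10th percentiles to a robust
   weighted mean, p_bar = sum(w_i * p10_i) / sum(w_i). If no repeat
   qualifies, the session is flagged below the quality threshold and no
   value is produced.

An emulated human-assisted reading (the whole-stimulus minimum of a lightly
sanity-filtered trace) is provided for method-comparison studies; the GUI
procedure it stands in for picks a single data point, so it sees late
("latent") constrictions and pupillary escape that the 2-4 s window excludes.

All operations are pure functions of (trace, config).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigError, DataError
from .trace_io import PupilTrace, ReadingRecord

__all__ = [
    "FilterConfig",
    "WindowEstimate",
    "MinPupilEstimate",
    "hampel_filter",
    "validity_filter",
    "apply_filters",
    "window_estimate",
    "session_estimate",
    "human_minimum",
    "read_session",
]

logger = logging.getLogger(__name__)

#: Consistency factor making the MAD an unbiased scale estimate under normality.
MAD_SCALE = 1.4826


@dataclass(frozen=True)
class FilterConfig:
    """Tunable parameters of the automated reading algorithm.

    Defaults are the algorithm's reference configuration: a 1.4 s Hampel
    window with threshold min(1.5 mm, 3 * MAD scale), the [2, 9] mm
    plausibility band, a 0.5 mm maximum step between consecutive retained
    points, the 2-4 s post-onset analysis window, the strict q > 0.5 quality
    threshold, and weight decay w = q * exp(-2 * d).
    """

    hampel_window: float = 1.4  # s
    hampel_t: float = 3.0  # multiplier on the MAD-based scale
    hampel_abs: float = 1.5  # mm, absolute deviation cap
    min_diameter: float = 2.0  # mm
    max_diameter: float = 9.0  # mm
    max_step: float = 0.5  # mm between consecutive retained points
    window_start_offset: float = 2.0  # s after stimulus onset
    window_end_offset: float = 4.0  # s after stimulus onset
    quality_threshold: float = 0.5  # strict inequality: q must exceed this
    weight_decay: float = 2.0  # w = q * exp(-weight_decay * d)
    step_anchor: str = "retained"  # "retained" or "raw" previous point
    hampel_center: str = "centered"  # "centered" or "trailing" window

    def __post_init__(self) -> None:
        positive = (
            "hampel_window",
            "hampel_t",
            "hampel_abs",
            "min_diameter",
            "max_diameter",
            "max_step",
            "weight_decay",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ConfigError(f"FilterConfig.{name} must be positive")
        if not self.window_start_offset < self.window_end_offset:
            raise ConfigError(
                "FilterConfig.window_start_offset must be below window_end_offset"
            )
        if not 0 <= self.quality_threshold <= 1:
            raise ConfigError("FilterConfig.quality_threshold must lie in [0, 1]")
        if self.min_diameter >= self.max_diameter:
            raise ConfigError("FilterConfig.min_diameter must be below max_diameter")
        if self.step_anchor not in ("retained", "raw"):
            raise ConfigError("FilterConfig.step_anchor must be 'retained' or 'raw'")
        if self.hampel_center not in ("centered", "trailing"):
            raise ConfigError(
                "FilterConfig.hampel_center must be 'centered' or 'trailing'"
            )


@dataclass(frozen=True)
class WindowEstimate:
    """Per-repeat statistics of the 2-4 s post-onset analysis window."""

    p_median: float  # mm, 50th percentile of retained diameters (NaN if none)
    p10: float  # mm, 10th percentile of retained diameters (NaN if none)
    q: float  # quality score: n_retained / n_total
    d: float  # mm, |p_median - p10|
    w: float  # weight q * exp(-weight_decay * d)
    n_total: int  # samples falling in the window by timestamp
    n_retained: int  # samples surviving all filters


@dataclass(frozen=True)
class MinPupilEstimate:
    """Quality-weighted robust mean of the per-repeat 10th percentiles."""

    p_bar: Optional[float]  # mm; None when no repeat passed the threshold
    contributing: Tuple[Tuple[int, WindowEstimate], ...]
    excluded: Tuple[Tuple[int, str], ...]
    status: str  # "ok" or "below_quality_threshold"


def hampel_filter(trace: PupilTrace, cfg: FilterConfig = FilterConfig()) -> np.ndarray:
    """Rolling-median outlier mask over present-diameter samples.

    For each sample with a present diameter, the median ``m`` and the
    MAD-based scale ``S = 1.4826 * median(|x_j - m|)`` are computed over the
    1.4 s window of present-diameter samples (centered by default, truncated
    at the trace edges). The sample is dropped when |x - m| exceeds the
    1.5 mm absolute cap or ``hampel_t * S``; with S = 0 (a constant window)
    only the absolute rule applies. Missing-diameter samples are ignored for
    the window statistics and marked not retained.

    Returns a boolean retention mask aligned with ``trace.t``.
    """
    d = trace.diameter
    if d.size == 0:
        raise DataError(f"trace {trace.key}: empty trace")
    present = np.isfinite(d)
    if not present.any():
        raise DataError(f"trace {trace.key}: no present diameters")
    x = d[present]
    tt = trace.t[present]
    if cfg.hampel_center == "centered":
        half = cfg.hampel_window / 2.0
        lo = np.searchsorted(tt, tt - half, side="left")
        hi = np.searchsorted(tt, tt + half, side="right")
    else:  # trailing
        lo = np.searchsorted(tt, tt - cfg.hampel_window, side="left")
        hi = np.arange(1, tt.size + 1)
    keep = np.empty(x.size, dtype=bool)
    for i in range(x.size):
        win = x[lo[i] : hi[i]]
        if win.size <= 1:
            keep[i] = True  # a lone sample never deviates from its own median
            continue
        m = np.median(win)
        dev = abs(x[i] - m)
        scale = MAD_SCALE * np.median(np.abs(win - m))
        keep[i] = not (
            dev > cfg.hampel_abs or (scale > 0 and dev > cfg.hampel_t * scale)
        )
    mask = np.zeros(d.size, dtype=bool)
    mask[np.flatnonzero(present)] = keep
    return mask


def validity_filter(
    trace: PupilTrace, mask: np.ndarray, cfg: FilterConfig = FilterConfig()
) -> np.ndarray:
    """Device-validity, range and maximum-step rules on top of a Hampel mask.

    Removes device-invalid samples, missing diameters, diameters outside
    [min_diameter, max_diameter], and samples whose diameter differs by more
    than ``max_step`` from the anchor point. With the default
    ``step_anchor="retained"`` the anchor is the most recent retained sample,
    so a single spike does not cascade into removals of the recovered signal;
    ``step_anchor="raw"`` compares against the previous present-diameter
    sample regardless of retention. May retain zero samples.
    """
    d = trace.diameter
    present = np.isfinite(d)
    vals = np.where(present, d, 0.0)
    keep = (
        np.asarray(mask, dtype=bool)
        & present
        & trace.device_valid
        & (vals >= cfg.min_diameter)
        & (vals <= cfg.max_diameter)
    )
    if cfg.step_anchor == "retained":
        last: Optional[float] = None
        for i in np.flatnonzero(keep):
            if last is not None and abs(d[i] - last) > cfg.max_step:
                keep[i] = False
            else:
                last = float(d[i])
    else:
        prev: Optional[float] = None
        for i in np.flatnonzero(present):
            if keep[i] and prev is not None and abs(d[i] - prev) > cfg.max_step:
                keep[i] = False
            prev = float(d[i])
    return keep


def apply_filters(
    trace: PupilTrace, cfg: FilterConfig = FilterConfig()
) -> np.ndarray:
    """Hampel filter followed by the validity/range/step rules."""
    return validity_filter(trace, hampel_filter(trace, cfg), cfg)


def window_estimate(
    trace: PupilTrace, mask: np.ndarray, cfg: FilterConfig = FilterConfig()
) -> WindowEstimate:
    """Median/10th-percentile summary of the half-open analysis window.

    The window is [onset + window_start_offset, onset + window_end_offset).
    ``n_total`` counts every sample in the window by timestamp (retained or
    not, including device-invalid and missing ones), so q is the fraction of
    window samples surviving all filters. Percentiles use the
    linear-interpolation definition. An empty retained set yields q = 0,
    missing percentiles, and zero weight.
    """
    t0 = trace.stimulus_onset + cfg.window_start_offset
    t1 = trace.stimulus_onset + cfg.window_end_offset
    in_window = (trace.t >= t0) & (trace.t < t1)
    n_total = int(in_window.sum())
    retained = in_window & np.asarray(mask, dtype=bool)
    n_retained = int(retained.sum())
    if n_retained == 0:
        return WindowEstimate(
            p_median=math.nan,
            p10=math.nan,
            q=0.0,
            d=math.nan,
            w=0.0,
            n_total=n_total,
            n_retained=0,
        )
    vals = trace.diameter[retained]
    p_median, p10 = np.percentile(vals, [50.0, 10.0])
    q = n_retained / n_total
    d = abs(float(p_median) - float(p10))
    w = q * math.exp(-cfg.weight_decay * d)
    return WindowEstimate(
        p_median=float(p_median),
        p10=float(p10),
        q=q,
        d=d,
        w=w,
        n_total=n_total,
        n_retained=n_retained,
    )


def session_estimate(
    repeats: Mapping[int, WindowEstimate], cfg: FilterConfig = FilterConfig()
) -> MinPupilEstimate:
    """Robust weighted mean of the per-repeat 10th percentiles.

    Only repeats with q strictly above ``quality_threshold`` contribute;
    the rest are listed in ``excluded`` with a reason. If none qualify the
    status is ``below_quality_threshold`` and ``p_bar`` is None (never 0 or
    NaN, so the failure cannot silently propagate into downstream
    statistics).
    """
    if not repeats:
        raise DataError("session_estimate requires at least one repeat")
    contributing = []
    excluded = []
    for idx in sorted(repeats):
        est = repeats[idx]
        if est.q > cfg.quality_threshold:
            contributing.append((idx, est))
        else:
            excluded.append(
                (idx, f"q={est.q:.3f} not above threshold {cfg.quality_threshold:g}")
            )
    if not contributing:
        return MinPupilEstimate(
            p_bar=None,
            contributing=(),
            excluded=tuple(excluded),
            status="below_quality_threshold",
        )
    w_sum = sum(est.w for _, est in contributing)
    p_bar = sum(est.w * est.p10 for _, est in contributing) / w_sum
    return MinPupilEstimate(
        p_bar=float(p_bar),
        contributing=tuple(contributing),
        excluded=tuple(excluded),
        status="ok",
    )


def human_minimum(
    trace: PupilTrace, cfg: FilterConfig = FilterConfig()
) -> float:
    """Emulated human-assisted reading: the whole-stimulus minimum.

    Returns the minimum present diameter over the full light interval
    [onset, onset + duration) after removing device-invalid samples and
    diameters outside the [2, 9] mm plausibility band (a blink-spike guard),
    but WITHOUT the Hampel or windowing steps -- emulating a reader marking
    a single data point in the acquisition GUI. Returns NaN when no sample
    is eligible.
    """
    t0 = trace.stimulus_onset
    t1 = trace.stimulus_onset + trace.stimulus_duration
    present = np.isfinite(trace.diameter)
    vals = np.where(present, trace.diameter, np.inf)
    eligible = (
        (trace.t >= t0)
        & (trace.t < t1)
        & present
        & trace.device_valid
        & (vals >= cfg.min_diameter)
        & (vals <= cfg.max_diameter)
    )
    if not eligible.any():
        return math.nan
    return float(trace.diameter[eligible].min())


def read_session(
    traces: Sequence[PupilTrace], cfg: FilterConfig = FilterConfig()
) -> Tuple[ReadingRecord, ReadingRecord]:
    """Produce the (automated, human) reading pair for one session.

    ``traces`` are the 1-5 repeats of one subject-visit-eye-condition. The
    automated record applies the full filter/window/weighting chain; the
    human record averages the per-repeat whole-stimulus minima (the device
    protocol averages five measurements).
    """
    if not 1 <= len(traces) <= 5:
        raise DataError(f"read_session expects 1-5 repeats, got {len(traces)}")
    session_keys = {tr.session_key for tr in traces}
    if len(session_keys) != 1:
        raise DataError(f"read_session got mixed sessions: {sorted(session_keys)}")
    repeat_idx = [tr.repeat_index for tr in traces]
    if len(set(repeat_idx)) != len(repeat_idx):
        raise DataError(f"read_session got duplicate repeat indices: {repeat_idx}")
    subject_id, visit, eye, condition = traces[0].session_key

    estimates = {
        tr.repeat_index: window_estimate(tr, apply_filters(tr, cfg), cfg)
        for tr in traces
    }
    est = session_estimate(estimates, cfg)
    q_summary = ",".join(
        f"{idx}:q={estimates[idx].q:.2f}" for idx in sorted(estimates)
    )
    flags = f"automated; {q_summary}"
    if est.excluded:
        flags += "; excluded=" + ",".join(str(idx) for idx, _ in est.excluded)
    if est.status != "ok":
        flags += "; below_quality_threshold"
    automated = ReadingRecord(
        subject_id=subject_id,
        visit=visit,
        eye=eye,
        condition=condition,
        method="automated",
        pupil_mm=est.p_bar,
        n_repeats_used=len(est.contributing),
        quality_flags=flags,
    )

    minima = {tr.repeat_index: human_minimum(tr, cfg) for tr in traces}
    usable = [m for m in minima.values() if not math.isnan(m)]
    human = ReadingRecord(
        subject_id=subject_id,
        visit=visit,
        eye=eye,
        condition=condition,
        method="human",
        pupil_mm=float(np.mean(usable)) if usable else None,
        n_repeats_used=len(usable),
        quality_flags="emulated human-assisted reading (whole-stimulus minimum)",
    )
    logger.debug(
        "session %s: automated=%s human=%s", traces[0].session_key,
        automated.pupil_mm, human.pupil_mm,
    )
    return automated, human
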