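"""Synthetic pupillary-light-reflex traces, sessions and two-visit cohorts.

The generator emulates the examination protocol the reading algorithm was
built for: 3 s of darkness followed by a 10 s binocular light stimulus at
4 lux (mesopic) or 300 lux (photopic), sampled at 30 Hz, with five repeats
per condition accepted only when their minima span at most a 1.0 mm
tolerability range.

A single trace is a piecewise deterministic trajectory plus colored noise
and blink artifacts:

* flat dark-adapted baseline until stimulus onset + latency;
* smoothstep phasic constriction reaching ``phasic_min`` exactly at
  onset + ``time_to_min``;
* a plateau of ``escape_delay`` seconds, then exponential pupillary escape
  toward ``phasic_min + escape_amplitude`` (escape is larger at lower light
  levels);
* optionally a late "latent" constriction - a Gaussian-shaped dip reaching
  ``depth_mm`` at ``time_s`` - emulating near-fixation/cognitive
  re-constriction that only a whole-stimulus reading registers;
* AR(1) measurement noise and blink artifacts: runs of missing/invalid
  samples flanked by short sub-2 mm spikes, exercising both the
  device-validity and the range filters downstream.

Cohort defaults reproduce the statistical structure of the study the
package targets: 43 subjects, mesopic sizes 4.12 (SD 0.70) mm and photopic
sizes 2.73 (SD 0.29) mm, between-visit difference SDs 0.454 mm (mesopic)
and 0.122 mm (photopic) - i.e. agreement coefficients of about 0.89 and
0.24 mm - and a multiplicative automated-vs-human reading bias of 1.023
under mesopic conditions, driven mechanistically by in-window pupillary
escape. Everything is deterministic given (params, seed). Ground truth is
returned separately from the traces and is never read by the reading
pipeline, so parameter-recovery tests stay honest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .errors import ParameterError
from .trace_io import CONDITION_LUX, PupilTrace
from .agreement import PairedMeasurements

__all__ = [
    "TraceParams",
    "CohortParams",
    "CohortData",
    "simulate_trace",
    "simulate_session",
    "simulate_cohort",
    "simulate_method_pairs",
    "simulate_visit_pairs",
    "preset_trace",
    "TRACE_PRESETS",
]

#: Protocol constants: darkness before stimulus, stimulus length, sampling.
PROTOCOL_ONSET_S = 3.0
PROTOCOL_DURATION_S = 10.0
PROTOCOL_RATE_HZ = 30.0


@dataclass(frozen=True)
class TraceParams:
    """Parameters of one simulated trace (all sizes in mm, times in s)."""

    baseline: float = 7.2  # dark-adapted diameter
    latency: float = 0.25  # onset-to-constriction delay
    phasic_min: float = 4.0  # trough of the initial constriction
    time_to_min: float = 1.2  # onset-to-trough time
    escape_delay: float = 0.0  # plateau before escape starts
    escape_amplitude: float = 0.1  # re-dilation from trough to sustained level
    escape_tau: float = 0.3  # escape time constant
    latent_constriction: Optional[Tuple[float, float]] = None  # (time_s, depth_mm)
    latent_width: float = 0.25  # Gaussian sigma of the latent dip
    noise_sd: float = 0.01  # marginal SD of the AR(1) measurement noise
    noise_tau: float = 0.1  # noise correlation time
    blink_rate: float = 0.1  # blink events per second
    blink_duration: float = 0.15  # seconds of lost tracking per blink
    seed: int = 0

    def validate(self) -> None:
        if not 2.0 < self.phasic_min < self.baseline <= 9.0:
            raise ParameterError(
                f"require 2 < phasic_min ({self.phasic_min:g}) < baseline "
                f"({self.baseline:g}) <= 9"
            )
        if self.latency < 0 or self.time_to_min <= self.latency:
            raise ParameterError("require 0 <= latency < time_to_min")
        if self.escape_amplitude < 0:
            raise ParameterError("escape_amplitude must be non-negative")
        if self.escape_tau <= 0 or self.latent_width <= 0:
            raise ParameterError("escape_tau and latent_width must be positive")
        for name in ("escape_delay", "noise_sd", "noise_tau", "blink_rate", "blink_duration"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.latent_constriction is not None:
            tc, depth = self.latent_constriction
            if not 2.0 <= depth:
                raise ParameterError(
                    f"latent constriction depth {depth:g} mm would leave the "
                    "[2, 9] mm plausibility band"
                )
            if tc <= 0:
                raise ParameterError("latent constriction time must be positive")


def _trajectory(p: TraceParams, t: np.ndarray, onset: float) -> np.ndarray:
    """Deterministic (noise- and blink-free) pupil trajectory."""
    t0 = onset + p.latency
    t1 = onset + p.time_to_min
    t2 = t1 + p.escape_delay
    s = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
    smooth = s * s * (3.0 - 2.0 * s)  # cubic smoothstep: C1 at both ends
    v = p.baseline + (p.phasic_min - p.baseline) * smooth
    esc = t >= t2
    v[esc] = p.phasic_min + p.escape_amplitude * (
        1.0 - np.exp(-(t[esc] - t2) / p.escape_tau)
    )
    if p.latent_constriction is not None:
        tc, depth = p.latent_constriction
        base_at_center = float(
            _trajectory(replace(p, latent_constriction=None), np.array([tc]), onset)[0]
        )
        amp = base_at_center - depth
        if amp < 0:
            raise ParameterError(
                f"latent constriction depth {depth:g} mm lies above the "
                f"trajectory ({base_at_center:g} mm) at t={tc:g} s"
            )
        v = v - amp * np.exp(-0.5 * ((t - tc) / p.latent_width) ** 2)
    return v


def _colored_noise(
    rng: np.random.Generator, n: int, sd: float, tau: float, dt: float
) -> np.ndarray:
    """Stationary AR(1) noise with marginal SD ``sd`` and correlation time ``tau``."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    if tau <= 0:
        return rng.normal(0.0, sd, n)
    a = math.exp(-dt / tau)
    e = rng.normal(0.0, 1.0, n)
    x = lfilter([1.0], [1.0, -a], e)
    return sd * math.sqrt(1.0 - a * a) * x


def simulate_trace(
    params: TraceParams,
    condition: str = "mesopic",
    subject_id: str = "sim",
    visit: str = "screening",
    eye: str = "right",
    repeat_index: int = 1,
    stimulus_onset: float = PROTOCOL_ONSET_S,
    stimulus_duration: float = PROTOCOL_DURATION_S,
    sampling_rate: float = PROTOCOL_RATE_HZ,
) -> PupilTrace:
    """Simulate one 13 s examination trace; deterministic given the seed.

    Blink artifacts replace a run of samples with missing/invalid values and
    place a sub-2 mm spike on each flank, so the downstream validity and
    range filters are both exercised. Raises :class:`ParameterError` when
    the deterministic trajectory leaves the (0, 10) mm device range.
    """
    params.validate()
    n = int(round((stimulus_onset + stimulus_duration) * sampling_rate))
    t = np.arange(n) / sampling_rate
    traj = _trajectory(params, t, stimulus_onset)
    if traj.min() <= 0 or traj.max() >= 10:
        raise ParameterError(
            f"trajectory leaves (0, 10) mm: range [{traj.min():g}, {traj.max():g}]"
        )
    rng = np.random.default_rng(params.seed)
    diameter = traj + _colored_noise(
        rng, n, params.noise_sd, params.noise_tau, 1.0 / sampling_rate
    )
    device_valid = np.ones(n, dtype=bool)
    if params.blink_rate > 0 and params.blink_duration > 0:
        n_blinks = rng.poisson(params.blink_rate * t[-1])
        for _ in range(n_blinks):
            tb = rng.uniform(0.0, t[-1])
            core = (t >= tb) & (t < tb + params.blink_duration)
            idx = np.flatnonzero(core)
            if idx.size == 0:
                continue
            diameter[idx] = np.nan
            device_valid[idx] = False
            for j in (idx[0] - 1, idx[-1] + 1):  # sub-2 mm eyelid spikes
                if 0 <= j < n:
                    diameter[j] = rng.uniform(1.0, 1.9)
    return PupilTrace(
        subject_id=subject_id,
        visit=visit,
        eye=eye,
        condition=condition,
        repeat_index=repeat_index,
        lux=CONDITION_LUX[condition],
        sampling_rate=sampling_rate,
        stimulus_onset=stimulus_onset,
        stimulus_duration=stimulus_duration,
        t=t,
        diameter=diameter,
        device_valid=device_valid,
    )


def simulate_session(
    true_min: float,
    template: TraceParams,
    condition: str = "mesopic",
    subject_id: str = "sim",
    visit: str = "screening",
    eye: str = "right",
    k: int = 5,
    repeat_sd: float = 0.1,
    tolerability_range: float = 1.0,
    retry_cap: int = 100,
    escape_fraction: Optional[float] = None,
    latent_prob: float = 0.0,
    latent_depth_offset: float = 0.12,
    rng: Optional[np.random.Generator] = None,
) -> list[PupilTrace]:
    """Simulate the ``k`` repeats of one session around a subject-level minimum.

    Per-repeat phasic minima are drawn as Normal(true_min, repeat_sd) and the
    whole set is redrawn (up to ``retry_cap`` times) until its spread fits
    inside the device's tolerability range, emulating the acceptance rule.
    When ``escape_fraction`` is given, each repeat's escape amplitude is
    ``escape_fraction * phasic_min`` (a multiplicative in-window escape);
    otherwise the template amplitude is used unchanged. With probability
    ``latent_prob`` a repeat receives a latent constriction dipping
    ``latent_depth_offset`` mm below its phasic minimum late in the stimulus.
    """
    if rng is None:
        rng = np.random.default_rng(template.seed)
    if k < 1:
        raise ParameterError("k must be at least 1")
    for _ in range(retry_cap):
        minima = rng.normal(true_min, repeat_sd, k)
        spread_ok = minima.max() - minima.min() <= tolerability_range
        bounds_ok = minima.min() > 2.0 and minima.max() < template.baseline
        if spread_ok and bounds_ok:
            break
    else:
        raise ParameterError(
            f"could not draw {k} repeats within tolerability range "
            f"{tolerability_range:g} mm after {retry_cap} attempts "
            f"(true_min={true_min:g}, repeat_sd={repeat_sd:g})"
        )
    traces = []
    for i, m in enumerate(minima, start=1):
        latent = None
        if latent_prob > 0 and rng.random() < latent_prob:
            depth = float(m) - latent_depth_offset
            if depth > 2.0:
                latent = (float(rng.uniform(9.5, 11.5)), depth)
        amp = (
            escape_fraction * float(m)
            if escape_fraction is not None
            else template.escape_amplitude
        )
        p = replace(
            template,
            phasic_min=float(m),
            escape_amplitude=amp,
            latent_constriction=latent,
            seed=int(rng.integers(2**31)),
        )
        traces.append(
            simulate_trace(
                p,
                condition=condition,
                subject_id=subject_id,
                visit=visit,
                eye=eye,
                repeat_index=i,
            )
        )
    return traces


def _cond_dict(mesopic: float, photopic: float) -> Dict[str, float]:
    return {"mesopic": mesopic, "photopic": photopic}


@dataclass(frozen=True)
class CohortParams:
    """Statistical structure of a simulated two-visit cohort.

    Defaults encode the targeted study conditions: subject-level true
    minimal pupil sizes per condition, between-visit drift of the true
    size, within-session repeat variability constrained by the 1.0 mm
    tolerability range, and the multiplicative automated-vs-human bias
    realized as in-window pupillary escape (mesopic only; the photopic
    method difference emerges from the minimum-vs-percentile mechanism
    alone).
    """

    n_subjects: int = 43
    mean_size: Dict[str, float] = field(default_factory=lambda: _cond_dict(4.12, 2.73))
    sd_size: Dict[str, float] = field(default_factory=lambda: _cond_dict(0.70, 0.29))
    between_visit_sd: Dict[str, float] = field(
        default_factory=lambda: _cond_dict(0.454, 0.122)
    )
    method_bias: Dict[str, float] = field(
        default_factory=lambda: _cond_dict(1.023, 1.0)
    )
    repeat_sd: Dict[str, float] = field(default_factory=lambda: _cond_dict(0.12, 0.05))
    latent_prob: Dict[str, float] = field(default_factory=lambda: _cond_dict(0.05, 0.0))
    latent_depth_offset: float = 0.12  # mm below the repeat's phasic minimum
    tolerability_range: float = 1.0  # mm, device acceptance rule
    retry_cap: int = 100
    eye_asymmetry_sd: float = 0.05  # mm, left-vs-right true-size offset
    noise_sd: float = 0.01
    blink_rate: float = 0.1
    conditions: Tuple[str, ...] = ("mesopic", "photopic")
    visits: Tuple[str, ...] = ("screening", "baseline")
    eyes: Tuple[str, ...] = ("right", "left")
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 3:
            raise ParameterError("n_subjects must be at least 3")
        for name in ("sd_size", "between_visit_sd", "repeat_sd"):
            for cond, val in getattr(self, name).items():
                if val < 0:
                    raise ParameterError(f"{name}[{cond}] must be non-negative")
        for cond in self.conditions:
            if cond not in CONDITION_LUX:
                raise ParameterError(f"unknown condition {cond!r}")
            if self.method_bias[cond] <= 0:
                raise ParameterError("method_bias factors must be positive")
        if self.tolerability_range <= 0:
            raise ParameterError("tolerability_range must be positive")


@dataclass
class CohortData:
    """Simulated traces plus the latent ground truth (kept separate)."""

    traces: list
    truth: pd.DataFrame


def _session_template(size: float, cp: CohortParams, seed: int) -> TraceParams:
    # trough at onset + 1.2 s with a fast escape puts the 5-7 s reading
    # window on the sustained plateau
    return TraceParams(
        baseline=min(size + 3.0, 8.8),
        latency=0.25,
        phasic_min=size,
        time_to_min=1.2,
        escape_delay=0.0,
        escape_amplitude=0.0,
        escape_tau=0.3,
        noise_sd=cp.noise_sd,
        noise_tau=0.1,
        blink_rate=cp.blink_rate,
        blink_duration=0.15,
        seed=seed,
    )


def _draw_size(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    for _ in range(1000):
        s = rng.normal(mean, sd)
        if lo < s < hi:
            return float(s)
    raise ParameterError(
        f"could not draw a plausible size from N({mean:g}, {sd:g}) in ({lo:g}, {hi:g})"
    )


def simulate_cohort(cp: CohortParams = CohortParams()) -> CohortData:
    """Simulate a full two-visit cohort and its ground-truth table.

    For each subject and condition a true minimal pupil size is drawn; each
    visit's size is that truth plus an independent
    Normal(0, between_visit_sd / sqrt(2)) perturbation, so the visit-to-visit
    difference has SD ``between_visit_sd`` while differences stay
    uncorrelated with averages (an asymmetric "visit 2 = visit 1 + drift"
    model would correlate them by construction). Sessions of five repeats
    are generated for every visit, eye and condition. The ground truth
    records all latent subject-level variables; the reading pipeline never
    sees it.
    """
    cp.validate()
    root = np.random.SeedSequence(cp.seed)
    subject_seqs = root.spawn(cp.n_subjects)
    traces = []
    truth_rows = []
    for si, seq in enumerate(subject_seqs):
        rng = np.random.default_rng(seq)
        sid = f"S{si + 1:02d}"
        for cond in cp.conditions:
            mean, sd = cp.mean_size[cond], cp.sd_size[cond]
            truth = _draw_size(rng, mean, sd, 2.4, 5.6)
            visit_sd = cp.between_visit_sd[cond] / math.sqrt(2.0)
            sizes = {
                visit: float(np.clip(truth + rng.normal(0.0, visit_sd), 2.3, 5.7))
                for visit in cp.visits
            }
            for visit in cp.visits:
                for eye in cp.eyes:
                    eye_size = sizes[visit]
                    if eye != "right":
                        eye_size = float(
                            np.clip(
                                eye_size + rng.normal(0.0, cp.eye_asymmetry_sd),
                                2.3,
                                5.7,
                            )
                        )
                    template = _session_template(eye_size, cp, seed=0)
                    traces.extend(
                        simulate_session(
                            eye_size,
                            template,
                            condition=cond,
                            subject_id=sid,
                            visit=visit,
                            eye=eye,
                            k=5,
                            repeat_sd=cp.repeat_sd[cond],
                            tolerability_range=cp.tolerability_range,
                            retry_cap=cp.retry_cap,
                            escape_fraction=cp.method_bias[cond] - 1.0,
                            latent_prob=cp.latent_prob[cond],
                            latent_depth_offset=cp.latent_depth_offset,
                            rng=rng,
                        )
                    )
                    if eye == "right":
                        truth_rows.append(
                            {
                                "subject_id": sid,
                                "condition": cond,
                                "visit": visit,
                                "true_min_mm": eye_size,
                                "method_bias": cp.method_bias[cond],
                                "expected_automated_mm": eye_size
                                * cp.method_bias[cond],
                            }
                        )
    return CohortData(traces=traces, truth=pd.DataFrame(truth_rows))


def simulate_method_pairs(
    n: int = 43,
    ratio: float = 1.023,
    subject_mean: float = 4.12,
    subject_sd: float = 0.70,
    ratio_sd: float = 0.006,
    seed: int = 0,
    labels: Tuple[str, str] = ("automated", "human"),
) -> PairedMeasurements:
    """Paired readings with a multiplicative method bias.

    ``b`` are subject-level sizes; ``a = b * Normal(ratio, ratio_sd)``, i.e.
    measurement error scales with pupil size, which is the structure the
    ratio-scale (log-equivalent) agreement analysis assumes. Used for
    parameter-recovery and power checks of the ratio machinery.
    """
    rng = np.random.default_rng(seed)
    b = np.array([_draw_size(rng, subject_mean, subject_sd, 2.2, 8.5) for _ in range(n)])
    r = rng.normal(ratio, ratio_sd, n)
    return PairedMeasurements(
        label_a=labels[0],
        label_b=labels[1],
        subjects=tuple(f"S{i + 1:02d}" for i in range(n)),
        a=b * r,
        b=b,
    )


def simulate_visit_pairs(
    n: int = 43,
    subject_mean: float = 4.12,
    subject_sd: float = 0.70,
    diff_sd: float = 0.454,
    seed: int = 0,
    labels: Tuple[str, str] = ("screening", "baseline"),
) -> PairedMeasurements:
    """Paired readings from two visits with a given difference SD (zero bias)."""
    rng = np.random.default_rng(seed)
    a = np.array([_draw_size(rng, subject_mean, subject_sd, 2.2, 8.5) for _ in range(n)])
    b = a + rng.normal(0.0, diff_sd, n)
    return PairedMeasurements(
        label_a=labels[0],
        label_b=labels[1],
        subjects=tuple(f"S{i + 1:02d}" for i in range(n)),
        a=a,
        b=np.clip(b, 2.0, 9.0),
    )


def _figure1_params(seed: int = 0) -> TraceParams:
    # qualitative template of the first worked example: constriction from
    # 7.5 to 3.4 mm by 5.5 s, escape toward ~5 mm, no latent event
    return TraceParams(
        baseline=7.5,
        latency=0.3,
        phasic_min=3.4,
        time_to_min=2.5,
        escape_delay=0.0,
        escape_amplitude=1.6,
        escape_tau=1.0,
        latent_constriction=None,
        noise_sd=0.03,
        noise_tau=0.1,
        blink_rate=0.1,
        seed=seed,
    )


def _figure2_params(seed: int = 0) -> TraceParams:
    # plateau at 4.7 mm inside the 5-7 s reading window, escape from 5.5 s,
    # latent constriction to 4.1 mm centered at 10.5 s; noise-free so the
    # reading-method divergence is exact
    return TraceParams(
        baseline=7.7,
        latency=0.3,
        phasic_min=4.7,
        time_to_min=1.7,
        escape_delay=0.8,
        escape_amplitude=0.9,
        escape_tau=0.5,
        latent_constriction=(10.5, 4.1),
        latent_width=0.25,
        noise_sd=0.0,
        blink_rate=0.0,
        seed=seed,
    )


#: Named single-trace presets (both represent mesopic examinations).
TRACE_PRESETS = {
    "figure1": _figure1_params,
    "figure2": _figure2_params,
}


def preset_trace(name: str, seed: int = 0) -> PupilTrace:
    """Simulate one of the named single-trace presets (mesopic condition)."""
    if name not in TRACE_PRESETS:
        raise ParameterError(
            f"unknown trace preset {name!r}; choose from {sorted(TRACE_PRESETS)}"
        )
    return simulate_trace(TRACE_PRESETS[name](seed=seed), condition="mesopic")
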