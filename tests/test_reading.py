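"""Unit and property tests for the automated reading algorithm."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pupilkit import (
    ConfigError,
    DataError,
    FilterConfig,
    WindowEstimate,
    apply_filters,
    hampel_filter,
    human_minimum,
    preset_trace,
    read_session,
    session_estimate,
    simulate_trace,
    validity_filter,
    window_estimate,
)
from pupilkit.synthetic import TraceParams

from conftest import make_trace, full_length

CFG = FilterConfig()


def flat(value=5.0, n=None):
    return np.full(full_length() if n is None else n, float(value))


class TestHampelFilter:
    def test_constant_trace_fully_retained(self):
        mask = hampel_filter(make_trace(flat(5.0)), CFG)
        assert mask.all()

    def test_absolute_cap_removes_large_spike(self):
        d = flat(5.0)
        d[200] = 7.2  # deviation 2.2 mm > the 1.5 mm cap
        mask = hampel_filter(make_trace(d), CFG)
        assert not mask[200]
        assert mask.sum() == d.size - 1

    def test_mad_rule_removes_moderate_spike_in_tight_window(self):
        # flat segment with small random jitter: the MAD-based scale is
        # small, so a 0.8 mm deviation is removed via 3*S even though
        # 0.8 < 1.5 (the absolute cap alone would keep it)
        rng = np.random.default_rng(6)
        d = 5.0 + rng.uniform(-0.05, 0.05, full_length())
        d[150] = 5.8
        trace = make_trace(d)
        # independent brute-force check of the window statistics at index 150
        in_win = np.abs(trace.t - trace.t[150]) <= CFG.hampel_window / 2
        win = d[in_win]
        m = np.median(win)
        s = 1.4826 * np.median(np.abs(win - m))
        assert 3 * s < abs(d[150] - m) < CFG.hampel_abs
        mask = hampel_filter(trace, CFG)
        assert not mask[150]

    def test_zero_mad_window_uses_absolute_rule_only(self):
        # constant window: S = 0, so only the 1.5 mm cap applies
        d = flat(5.0)
        d[100] = 6.0  # 1.0 mm deviation: below the cap, kept despite S = 0
        mask = hampel_filter(make_trace(d), CFG)
        assert mask[100]

    def test_missing_samples_not_retained_but_ignored_in_windows(self):
        d = flat(5.0)
        d[50:55] = np.nan
        mask = hampel_filter(make_trace(d), CFG)
        assert not mask[50:55].any()
        assert mask.sum() == d.size - 5

    def test_empty_trace_errors(self):
        with pytest.raises(DataError):
            hampel_filter(make_trace(np.full(full_length(), np.nan)), CFG)

    def test_trailing_window_config(self):
        d = flat(5.0)
        d[200] = 7.2
        cfg = FilterConfig(hampel_center="trailing")
        mask = hampel_filter(make_trace(d), cfg)
        assert not mask[200]


class TestValidityFilter:
    def _masked(self, d, cfg=CFG, valid=None):
        trace = make_trace(d, valid=valid)
        return validity_filter(trace, hampel_filter(trace, cfg), cfg)

    def test_small_diameter_removed(self):
        d = flat(2.5)
        d[30] = 1.9
        assert not self._masked(d)[30]

    def test_device_invalid_removed(self):
        d = flat(5.0)
        valid = np.ones(d.size, bool)
        valid[40] = False
        trace = make_trace(d, valid=valid)
        mask = validity_filter(trace, hampel_filter(trace, CFG), CFG)
        assert not mask[40]
        assert mask.sum() == d.size - 1

    def test_step_rule_removes_fast_jump(self):
        d = flat(5.0)
        d[60] = 5.6  # 0.6 mm step from the 5.0 anchor
        mask = self._masked(d)
        assert not mask[60]

    def test_step_rule_anchors_on_last_retained_point(self):
        # 5.0, 5.8, 5.2: the spike is removed; 5.2 is kept because its step
        # is measured against the last RETAINED point (5.0), not the spike
        d = flat(5.0)
        d[60], d[61] = 5.8, 5.2
        mask = self._masked(d)
        assert not mask[60]
        assert mask[61]

    def test_step_rule_raw_anchor_config(self):
        # with the raw-anchor alternative, 5.2 is compared against the raw
        # previous point 5.8 (step 0.6) and removed as well
        d = flat(5.0)
        d[60], d[61] = 5.8, 5.2
        cfg = FilterConfig(step_anchor="raw")
        mask = self._masked(d, cfg=cfg)
        assert not mask[60]
        assert not mask[61]

    def test_may_retain_zero_samples(self):
        d = flat(1.5)  # everything below the 2 mm floor
        trace = make_trace(d)
        mask = validity_filter(trace, hampel_filter(trace, CFG), CFG)
        assert not mask.any()


class TestWindowEstimate:
    def test_constant_window(self):
        trace = make_trace(flat(4.0))
        est = window_estimate(trace, np.ones(trace.n_samples, bool), CFG)
        assert est.n_total == 60  # 2 s at 30 Hz
        assert est.p_median == est.p10 == 4.0
        assert est.d == 0.0 and est.q == 1.0 and est.w == 1.0

    def test_half_retained_q_fails_strict_threshold(self):
        trace = make_trace(flat(4.0))
        mask = np.ones(trace.n_samples, bool)
        in_win = (trace.t >= 5.0) & (trace.t < 7.0)
        idx = np.flatnonzero(in_win)
        mask[idx[: idx.size // 2]] = False
        est = window_estimate(trace, mask, CFG)
        assert est.q == 0.5
        result = session_estimate({1: est}, CFG)
        assert result.status == "below_quality_threshold"
        assert result.p_bar is None

    def test_weight_decay_factor(self):
        # p_median 4.2, p10 4.0 -> d = 0.2, w = q * e^(-0.4)
        trace = make_trace(flat(4.0))
        in_win = (trace.t >= 5.0) & (trace.t < 7.0)
        idx = np.flatnonzero(in_win)
        vals = np.linspace(4.0, 4.25, idx.size)
        trace.diameter[idx] = vals
        est = window_estimate(trace, np.ones(trace.n_samples, bool), CFG)
        expected_d = abs(np.percentile(vals, 50) - np.percentile(vals, 10))
        assert est.d == pytest.approx(expected_d, abs=1e-12)
        assert est.w == pytest.approx(est.q * math.exp(-2.0 * est.d), abs=1e-12)
        # the worked factor: d = 0.2 exactly gives w = q * 0.6703
        assert math.exp(-2.0 * 0.2) == pytest.approx(0.670320, abs=1e-6)

    def test_empty_retained_set(self):
        trace = make_trace(flat(4.0))
        est = window_estimate(trace, np.zeros(trace.n_samples, bool), CFG)
        assert est.q == 0.0 and est.w == 0.0 and est.n_retained == 0
        assert math.isnan(est.p10) and math.isnan(est.p_median)

    @given(
        st.lists(st.floats(min_value=2.0, max_value=9.0), min_size=1, max_size=50)
    )
    @settings(max_examples=200, deadline=None)
    def test_percentile_oracle(self, values):
        """np.percentile path agrees with a hand-rolled sort-and-interpolate."""
        arr = np.array(values)
        for frac in (0.10, 0.50):
            expect = _interpolated_percentile(sorted(values), frac)
            got = np.percentile(arr, 100 * frac)
            assert got == pytest.approx(expect, abs=1e-12)


def _interpolated_percentile(ordered, frac):
    # independent linear-interpolation definition over order statistics
    pos = frac * (len(ordered) - 1)
    lo = int(math.floor(pos))
    hi = int(math.ceil(pos))
    return ordered[lo] + (pos - lo) * (ordered[hi] - ordered[lo])


def _we(p10, p_median, q, cfg=CFG):
    d = abs(p_median - p10)
    return WindowEstimate(
        p_median=p_median, p10=p10, q=q, d=d,
        w=q * math.exp(-cfg.weight_decay * d), n_total=60,
        n_retained=int(round(q * 60)),
    )


class TestSessionEstimate:
    def test_identical_repeats(self):
        reps = {i: _we(3.0, 3.0, 1.0) for i in range(1, 6)}
        est = session_estimate(reps, CFG)
        assert est.p_bar == pytest.approx(3.0)
        assert len(est.contributing) == 5 and est.status == "ok"

    def test_all_below_threshold(self):
        reps = {i: _we(3.0, 3.0, 0.4) for i in range(1, 6)}
        est = session_estimate(reps, CFG)
        assert est.status == "below_quality_threshold"
        assert est.p_bar is None and len(est.excluded) == 5

    def test_hand_computed_weighted_mean(self):
        # (p10 = 3.0, w = 1.0) and (p10 = 4.0, w = 0.5) -> (3 + 2) / 1.5
        e1 = WindowEstimate(3.0, 3.0, 1.0, 0.0, 1.0, 60, 60)
        e2 = WindowEstimate(4.0, 4.0, 0.6, 0.0, 0.5, 60, 36)
        est = session_estimate({1: e1, 2: e2}, CFG)
        assert est.p_bar == pytest.approx(10.0 / 3.0, abs=1e-12)

    def test_empty_errors(self):
        with pytest.raises(DataError):
            session_estimate({}, CFG)

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=2.0, max_value=9.0),  # p10
                st.floats(min_value=0.0, max_value=1.0),  # extra spread
                st.floats(min_value=0.51, max_value=1.0),  # q above threshold
            ),
            min_size=1,
            max_size=5,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_weighted_mean_bounded_by_contributing_p10(self, reps):
        ests = {
            i + 1: _we(p10, p10 + spread, q) for i, (p10, spread, q) in enumerate(reps)
        }
        est = session_estimate(ests, CFG)
        p10s = [e.p10 for _, e in est.contributing]
        assert min(p10s) - 1e-12 <= est.p_bar <= max(p10s) + 1e-12


class TestWeightMonotonicity:
    def test_weight_decreases_with_spread_at_fixed_quality(self):
        spreads = np.linspace(0.0, 2.0, 21)
        ws = [_we(4.0, 4.0 + s, 0.8).w for s in spreads]
        assert ws[0] == pytest.approx(0.8)  # w = q exactly at d = 0
        assert all(a > b for a, b in zip(ws, ws[1:]))


class TestHumanMinimum:
    def test_monotone_constriction_reaches_trough(self):
        p = TraceParams(
            baseline=7.0, phasic_min=3.4, escape_amplitude=0.0,
            noise_sd=0.0, blink_rate=0.0,
        )
        trace = simulate_trace(p)
        assert human_minimum(trace) == pytest.approx(3.4, abs=1e-12)

    def test_blink_spike_ignored(self):
        d = flat(4.0)
        d[200] = 1.2  # sub-2 mm eyelid spike
        assert human_minimum(make_trace(d)) == pytest.approx(4.0)

    def test_latent_constriction_seen_only_by_human_reading(self):
        trace = preset_trace("figure2")
        mask = apply_filters(trace, CFG)
        est = session_estimate({1: window_estimate(trace, mask, CFG)}, CFG)
        assert est.p_bar == pytest.approx(4.7, abs=1e-9)
        assert human_minimum(trace) == pytest.approx(4.1, abs=1e-9)

    def test_no_eligible_samples_yields_nan(self):
        trace = make_trace(flat(4.0), valid=np.zeros(full_length(), bool))
        assert math.isnan(human_minimum(trace))


class TestReadSession:
    def _session(self, phasic=3.0, escape=0.0, n=5, seed=0):
        traces = []
        for rep in range(1, n + 1):
            p = TraceParams(
                baseline=6.5, phasic_min=phasic, escape_amplitude=escape,
                escape_tau=0.3, time_to_min=1.2, noise_sd=0.0, blink_rate=0.0,
                seed=seed + rep,
            )
            traces.append(simulate_trace(p, repeat_index=rep, subject_id="X"))
        return traces

    def test_flat_session_automated_equals_human(self):
        automated, human = read_session(self._session(phasic=3.0), CFG)
        assert automated.pupil_mm == pytest.approx(3.0, abs=1e-9)
        assert human.pupil_mm == pytest.approx(3.0, abs=1e-9)
        assert automated.n_repeats_used == 5

    def test_escape_biases_automated_above_human(self):
        automated, human = read_session(self._session(phasic=3.0, escape=1.0), CFG)
        assert automated.pupil_mm > human.pupil_mm

    def test_escape_sensitivity_is_monotone(self):
        gaps = []
        for escape in (0.0, 0.3, 0.6, 1.0):
            automated, human = read_session(
                self._session(phasic=3.0, escape=escape), CFG
            )
            gaps.append(automated.pupil_mm - human.pupil_mm)
        assert all(b >= a - 1e-12 for a, b in zip(gaps, gaps[1:]))

    def test_deterministic(self):
        traces = self._session()
        assert read_session(traces, CFG) == read_session(traces, CFG)

    def test_mixed_sessions_rejected(self):
        traces = self._session(n=2)
        traces[1].visit = "baseline"
        with pytest.raises(DataError):
            read_session(traces, CFG)


def test_invalid_filter_config_rejected():
    with pytest.raises(ConfigError):
        FilterConfig(window_start_offset=4.0, window_end_offset=2.0)
    with pytest.raises(ConfigError):
        FilterConfig(quality_threshold=1.5)


@given(
    baseline=st.floats(min_value=6.0, max_value=8.8),
    drop=st.floats(min_value=2.0, max_value=3.5),
    time_to_min=st.floats(min_value=1.0, max_value=2.5),
    escape=st.floats(min_value=0.0, max_value=1.5),
    escape_tau=st.floats(min_value=0.3, max_value=1.0),
)
@settings(max_examples=30, deadline=None)
def test_filters_transparent_on_clean_traces(
    baseline, drop, time_to_min, escape, escape_tau
):
    """Zero-noise, artifact-free traces pass the full filter chain untouched."""
    p = TraceParams(
        baseline=baseline,
        phasic_min=baseline - drop,
        time_to_min=time_to_min,
        escape_amplitude=escape,
        escape_tau=escape_tau,
        noise_sd=0.0,
        blink_rate=0.0,
    )
    trace = simulate_trace(p)
    assert apply_filters(trace, CFG).all()
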