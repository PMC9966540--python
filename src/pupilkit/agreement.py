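"""Bland-Altman agreement analysis with exact confidence-interval formulas.

Agreement between two sets of paired measurements (two visits, or two
reading methods) is summarised the Bland-Altman way: per-subject values
v_i = a_i - b_i (difference scale) or v_i = a_i / b_i (ratio scale) are
plotted against the averages (a_i + b_i)/2; the bias is mean(v), the limits
of agreement (LOA) are bias +/- 1.96 * SD(v), and 1.96 * SD(v) is the
agreement coefficient (over time) or inter-method repeatability coefficient
(between methods).

Because bias and LOA are sample estimates, 95% confidence intervals are
attached using SE(bias) = sqrt(SD^2 / n), SE(LOA) = sqrt(3 * SD^2 / n), and
the two-sided t quantile with n - 1 degrees of freedom:
estimate +/- t_{0.975, n-1} * SE.

Proportional bias (differences growing with the magnitude of the
measurement) is screened with Pearson's correlation of values against
averages; when significant, the analysis is repeated on the ratio scale,
which is equivalent to a log transformation because
log(a/b) = log(a) - log(b).

Outliers beyond ``sd_multiplier`` (default 3) standard deviations of the
all-data bias are removed in a single pass and the analysis rerun; both
results are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import DataError

__all__ = [
    "PairedMeasurements",
    "AgreementResult",
    "BlandAltmanResult",
    "PairReport",
    "QQData",
    "SummaryCI",
    "bland_altman",
    "proportional_bias",
    "analyze_pair",
    "qq_data",
    "log_ratio_equivalence_check",
    "loa_ci_from_summary",
]

#: Normal quantile used inside the LOA definition itself (not for CIs).
LOA_Z = 1.96


@dataclass(frozen=True)
class PairedMeasurements:
    """Per-subject paired readings for one comparison.

    ``a`` and ``b`` are the two measurement sets (e.g. automated vs human, or
    screening vs baseline); pairs with a missing member must be excluded
    upstream (they are the reduced-N cases in pairwise-complete analyses).
    """

    label_a: str
    label_b: str
    subjects: Tuple[str, ...]
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", np.asarray(self.a, dtype=float))
        object.__setattr__(self, "b", np.asarray(self.b, dtype=float))
        if len(self.subjects) != self.a.size or self.a.size != self.b.size:
            raise DataError("PairedMeasurements: subjects, a, b must align")
        if len(set(self.subjects)) != len(self.subjects):
            raise DataError("PairedMeasurements: subject ids must be unique")
        if not (np.isfinite(self.a).all() and np.isfinite(self.b).all()):
            raise DataError("PairedMeasurements: all paired values must be finite")

    @property
    def n(self) -> int:
        return self.a.size

    def subset(self, keep: np.ndarray) -> "PairedMeasurements":
        keep = np.asarray(keep, dtype=bool)
        return PairedMeasurements(
            label_a=self.label_a,
            label_b=self.label_b,
            subjects=tuple(s for s, k in zip(self.subjects, keep) if k),
            a=self.a[keep],
            b=self.b[keep],
        )

    def swapped(self) -> "PairedMeasurements":
        return PairedMeasurements(
            label_a=self.label_b,
            label_b=self.label_a,
            subjects=self.subjects,
            a=self.b.copy(),
            b=self.a.copy(),
        )


@dataclass(frozen=True)
class AgreementResult:
    """Full Bland-Altman output for one set of pairs on one scale."""

    scale: str  # "difference" or "ratio"
    label_a: str
    label_b: str
    n: int
    bias: float  # mean of per-subject values
    sd: float  # sample SD (n-1 denominator) of per-subject values
    loa_lower: float  # bias - 1.96 * sd
    loa_upper: float  # bias + 1.96 * sd
    coefficient: float  # 1.96 * sd (agreement / repeatability coefficient)
    se_bias: float  # sqrt(sd^2 / n)
    se_loa: float  # sqrt(3 * sd^2 / n)
    t_crit: float  # two-sided 97.5th t quantile, n - 1 df
    ci_bias: Tuple[float, float]
    ci_loa_lower: Tuple[float, float]
    ci_loa_upper: Tuple[float, float]
    pearson_r: float  # correlation of values vs averages (NaN if undefined)
    pearson_p: float
    outliers_excluded: Tuple[str, ...] = ()
    degenerate: bool = False  # zero-variance values or undefined correlation

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "label_a": self.label_a,
            "label_b": self.label_b,
            "n": self.n,
            "bias": self.bias,
            "sd": self.sd,
            "loa_lower": self.loa_lower,
            "loa_upper": self.loa_upper,
            "coefficient": self.coefficient,
            "se_bias": self.se_bias,
            "se_loa": self.se_loa,
            "t_crit": self.t_crit,
            "ci_bias": list(self.ci_bias),
            "ci_loa_lower": list(self.ci_loa_lower),
            "ci_loa_upper": list(self.ci_loa_upper),
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "outliers_excluded": list(self.outliers_excluded),
            "degenerate": self.degenerate,
        }


@dataclass(frozen=True)
class BlandAltmanResult:
    """All-data result plus (optionally) the single-pass outlier-excluded rerun."""

    all: AgreementResult
    outliers_excluded: Optional[AgreementResult]

    @property
    def final(self) -> AgreementResult:
        return self.outliers_excluded if self.outliers_excluded is not None else self.all


@dataclass(frozen=True)
class PairReport:
    """Difference-scale analysis plus the ratio fallback when triggered."""

    difference: BlandAltmanResult
    ratio: Optional[BlandAltmanResult]
    ratio_triggered: bool
    headline_scale: str  # "ratio" when the ratio analysis was triggered
    alpha: float
    notes: Tuple[str, ...] = ()


@dataclass(frozen=True)
class QQData:
    """Normal quantile-quantile plot data (no automatic accept/reject)."""

    theoretical: np.ndarray  # standard-normal quantiles at (i - 0.5) / n
    sample: np.ndarray  # order statistics standardized by sample mean / sd
    degenerate: bool  # constant input: standardization undefined


@dataclass(frozen=True)
class SummaryCI:
    """Bias/LOA confidence intervals recomputed from printed summaries."""

    bias: float
    coefficient: float
    n: int
    sd: float
    se_bias: float
    se_loa: float
    t_crit: float
    loa_lower: float
    loa_upper: float
    ci_bias: Tuple[float, float]
    ci_loa_lower: Tuple[float, float]
    ci_loa_upper: Tuple[float, float]


def _interval_arithmetic(
    bias: float, sd: float, n: int, conf: float
) -> Tuple[float, float, float, float, float, Tuple[float, float], Tuple[float, float], Tuple[float, float]]:
    """Shared closed forms: LOA, SEs, t quantile, and all three CIs."""
    loa_lower = bias - LOA_Z * sd
    loa_upper = bias + LOA_Z * sd
    se_bias = math.sqrt(sd * sd / n)
    se_loa = math.sqrt(3.0 * sd * sd / n)
    t_crit = float(stats.t.ppf(0.5 + conf / 2.0, n - 1))
    ci_bias = (bias - t_crit * se_bias, bias + t_crit * se_bias)
    ci_lo = (loa_lower - t_crit * se_loa, loa_lower + t_crit * se_loa)
    ci_up = (loa_upper - t_crit * se_loa, loa_upper + t_crit * se_loa)
    return loa_lower, loa_upper, se_bias, se_loa, t_crit, ci_bias, ci_lo, ci_up


def _near_constant(x: np.ndarray) -> bool:
    # guards against correlations computed on pure floating-point jitter
    return float(np.std(x)) <= 1e-13 * max(1.0, float(np.abs(np.mean(x))))


def _pearson(values: np.ndarray, averages: np.ndarray) -> Tuple[float, float]:
    if _near_constant(values) or _near_constant(averages):
        return math.nan, math.nan
    res = stats.pearsonr(values, averages)
    return float(res.statistic), float(res.pvalue)


def _values(pm: PairedMeasurements, scale: str) -> Tuple[np.ndarray, np.ndarray]:
    if scale == "difference":
        v = pm.a - pm.b
    elif scale == "ratio":
        if np.any(pm.a <= 0) or np.any(pm.b <= 0):
            raise DataError("ratio scale requires strictly positive measurements")
        v = pm.a / pm.b
    else:
        raise DataError(f"unknown scale {scale!r}")
    return v, (pm.a + pm.b) / 2.0


def _one_pass(
    pm: PairedMeasurements,
    scale: str,
    conf: float,
    outliers: Tuple[str, ...] = (),
) -> AgreementResult:
    v, avg = _values(pm, scale)
    n = pm.n
    bias = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    loa_lower, loa_upper, se_bias, se_loa, t_crit, ci_bias, ci_lo, ci_up = (
        _interval_arithmetic(bias, sd, n, conf)
    )
    r, p = _pearson(v, avg)
    return AgreementResult(
        scale=scale,
        label_a=pm.label_a,
        label_b=pm.label_b,
        n=n,
        bias=bias,
        sd=sd,
        loa_lower=loa_lower,
        loa_upper=loa_upper,
        coefficient=LOA_Z * sd,
        se_bias=se_bias,
        se_loa=se_loa,
        t_crit=t_crit,
        ci_bias=ci_bias,
        ci_loa_lower=ci_lo,
        ci_loa_upper=ci_up,
        pearson_r=r,
        pearson_p=p,
        outliers_excluded=outliers,
        degenerate=(sd == 0.0) or math.isnan(r),
    )


def bland_altman(
    pm: PairedMeasurements,
    scale: str = "difference",
    exclude_outliers: bool = True,
    sd_multiplier: float = 3.0,
    conf: float = 0.95,
) -> BlandAltmanResult:
    """Bland-Altman analysis with an optional single-pass outlier exclusion.

    The outlier pass removes subjects with |v - bias| > sd_multiplier * SD,
    where bias and SD come from the all-data analysis (no iteration), then
    recomputes everything on the remainder; both results are returned.
    Requires n >= 3; a zero SD yields a degenerate result with zero-width
    LOA and CIs, flagged via ``degenerate``.
    """
    if pm.n < 3:
        raise DataError(f"bland_altman requires n >= 3 pairs, got {pm.n}")
    all_result = _one_pass(pm, scale, conf)
    excluded_result = None
    if exclude_outliers:
        v, _ = _values(pm, scale)
        if all_result.sd > 0:
            keep = np.abs(v - all_result.bias) <= sd_multiplier * all_result.sd
        else:
            keep = np.ones(pm.n, dtype=bool)
        dropped = tuple(s for s, k in zip(pm.subjects, keep) if not k)
        if dropped:
            reduced = pm.subset(keep)
            if reduced.n < 3:
                raise DataError(
                    "outlier exclusion left fewer than 3 pairs "
                    f"(dropped {list(dropped)})"
                )
            excluded_result = _one_pass(reduced, scale, conf, outliers=dropped)
        else:
            excluded_result = _one_pass(pm, scale, conf)
    return BlandAltmanResult(all=all_result, outliers_excluded=excluded_result)


def proportional_bias(
    pm: PairedMeasurements, scale: str = "difference"
) -> Tuple[float, float]:
    """Pearson correlation of per-subject values against averages.

    The two-sided p-value comes from the t distribution with n - 2 degrees
    of freedom. Returns (NaN, NaN) when either vector has zero variance.
    """
    if pm.n < 3:
        raise DataError(f"proportional_bias requires n >= 3 pairs, got {pm.n}")
    v, avg = _values(pm, scale)
    return _pearson(v, avg)


def analyze_pair(
    pm: PairedMeasurements,
    alpha: float = 0.05,
    sd_multiplier: float = 3.0,
    conf: float = 0.95,
) -> PairReport:
    """Difference-scale analysis plus the ratio fallback when warranted.

    The ratio analysis (bias and LOA of per-subject ratios, screened again
    for proportional bias against averages) is triggered when the
    difference-scale correlation of the outlier-excluded analysis is
    significant at ``alpha``. An undefined correlation (degenerate data) is
    treated as non-significant and flagged in ``notes``.
    """
    notes: list[str] = []
    diff = bland_altman(
        pm, scale="difference", exclude_outliers=True,
        sd_multiplier=sd_multiplier, conf=conf,
    )
    trigger_p = diff.final.pearson_p
    if math.isnan(trigger_p):
        notes.append(
            "difference-vs-average correlation undefined (degenerate data); "
            "treated as non-significant"
        )
        triggered = False
    else:
        triggered = trigger_p < alpha
    ratio = None
    if triggered:
        ratio = bland_altman(
            pm, scale="ratio", exclude_outliers=True,
            sd_multiplier=sd_multiplier, conf=conf,
        )
    return PairReport(
        difference=diff,
        ratio=ratio,
        ratio_triggered=triggered,
        headline_scale="ratio" if triggered else "difference",
        alpha=alpha,
        notes=tuple(notes),
    )


def qq_data(values: Sequence[float]) -> QQData:
    """Normal Q-Q plot data: order statistics vs standard-normal quantiles.

    Theoretical quantiles are taken at probabilities (i - 0.5)/n; sample
    order statistics are standardized by the sample mean and SD. Constant
    input is flagged degenerate (standardized values reported as zero).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise DataError(f"qq_data requires n >= 3 values, got {x.size}")
    n = x.size
    theoretical = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    ordered = np.sort(x)
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        return QQData(
            theoretical=theoretical,
            sample=np.zeros(n),
            degenerate=True,
        )
    standardized = (ordered - float(np.mean(x))) / sd
    return QQData(theoretical=theoretical, sample=standardized, degenerate=False)


def log_ratio_equivalence_check(
    pm: PairedMeasurements, tol: float = 1e-12
) -> bool:
    """Self-test of the ratio machinery: log(a/b) == log(a) - log(b).

    Verifies the algebraic identity per subject to ``tol``; it is the reason
    the ratio-scale analysis is equivalent to a log-transformed difference
    analysis. Raises on non-positive measurements.
    """
    if np.any(pm.a <= 0) or np.any(pm.b <= 0):
        raise DataError("log_ratio_equivalence_check requires positive values")
    lhs = np.log(pm.a / pm.b)
    rhs = np.log(pm.a) - np.log(pm.b)
    return bool(np.all(np.abs(lhs - rhs) <= tol))


def loa_ci_from_summary(
    bias: float, coefficient: float, n: int, conf: float = 0.95
) -> SummaryCI:
    """Recompute bias/LOA confidence intervals from reported summaries.

    Given a printed bias, agreement/repeatability coefficient (1.96 * SD)
    and sample size, recovers SD = coefficient / 1.96 and applies the same
    SE and t-quantile arithmetic as the full analysis. Useful for checking
    published agreement tables without the raw data.
    """
    if n < 2:
        raise DataError("loa_ci_from_summary requires n >= 2")
    sd = coefficient / LOA_Z
    loa_lower, loa_upper, se_bias, se_loa, t_crit, ci_bias, ci_lo, ci_up = (
        _interval_arithmetic(bias, sd, n, conf)
    )
    return SummaryCI(
        bias=bias,
        coefficient=coefficient,
        n=n,
        sd=sd,
        se_bias=se_bias,
        se_loa=se_loa,
        t_crit=t_crit,
        loa_lower=loa_lower,
        loa_upper=loa_upper,
        ci_bias=ci_bias,
        ci_loa_lower=ci_lo,
        ci_loa_upper=ci_up,
    )
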