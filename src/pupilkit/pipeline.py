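"""End-to-end orchestration: traces -> readings -> agreement report bundle.

``run_pipeline`` turns a collection of traces into

1. a descriptive table of mean (SD) pupil size per condition, visit and
   reading method;
2. difference-scale agreement tables with "all" and "outliers excluded"
   rows for the four standard comparisons (screening vs baseline on human
   and on automated readings; automated vs human at each visit);
3. ratio-scale tables whenever the difference-vs-average correlation is
   significant;
4. Bland-Altman and Q-Q plot-data CSVs;
5. a machine-readable JSON report carrying unrounded values, the package
   version, a config hash and the seed. Rounding (2 decimals on the mm
   scale, 3 on the ratio scale) is applied only at render time.

Analysis defaults to the right eye. Comparisons with fewer than three
complete pairs are skipped with a logged reason.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .agreement import (
    AgreementResult,
    BlandAltmanResult,
    PairReport,
    PairedMeasurements,
    analyze_pair,
    qq_data,
)
from .errors import ConfigError
from .reading import FilterConfig, read_session
from .trace_io import PupilTrace, ReadingRecord

__all__ = ["RunConfig", "ReportBundle", "compute_readings", "build_pair", "run_pipeline"]

logger = logging.getLogger(__name__)

#: The four standard comparisons: (kind, fixed level, a-label, b-label).
COMPARISONS = {
    "visits_human": {"kind": "visits", "method": "human", "a": "screening", "b": "baseline"},
    "visits_automated": {"kind": "visits", "method": "automated", "a": "screening", "b": "baseline"},
    "methods_screening": {"kind": "methods", "visit": "screening", "a": "automated", "b": "human"},
    "methods_baseline": {"kind": "methods", "visit": "baseline", "a": "automated", "b": "human"},
}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full pipeline run."""

    eye: str = "right"
    conditions: Tuple[str, ...] = ("mesopic", "photopic")
    comparisons: Tuple[str, ...] = (
        "visits_human",
        "visits_automated",
        "methods_screening",
        "methods_baseline",
    )
    alpha: float = 0.05
    outlier_sd: float = 3.0
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    seed: int = 0
    mm_decimals: int = 2
    ratio_decimals: int = 3

    def __post_init__(self) -> None:
        unknown = sorted(set(self.comparisons) - set(COMPARISONS))
        if unknown:
            raise ConfigError(f"unknown comparison(s): {', '.join(unknown)}")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.outlier_sd <= 0:
            raise ConfigError("outlier_sd must be positive")


@dataclass
class ReportBundle:
    """Everything one pipeline run produces."""

    records: list  # ReadingRecord
    report: dict  # unrounded machine-readable report
    descriptives: pd.DataFrame
    agreement_tables: Dict[str, pd.DataFrame]  # rounded render per scale
    plot_data: Dict[str, pd.DataFrame]  # Bland-Altman points and Q-Q pairs


def compute_readings(
    traces: Sequence[PupilTrace],
    cfg: FilterConfig = FilterConfig(),
    eye: str = "right",
) -> list[ReadingRecord]:
    """Run the automated and emulated-human readings on every session.

    ``eye`` may be "right", "left" or "both".
    """
    eyes = ("right", "left") if eye == "both" else (eye,)
    sessions: Dict[tuple, list] = {}
    for tr in traces:
        if tr.eye not in eyes:
            continue
        sessions.setdefault(tr.session_key, []).append(tr)
    records: list[ReadingRecord] = []
    for key in sorted(sessions):
        automated, human = read_session(sessions[key], cfg)
        records.extend((automated, human))
    logger.info("computed %d readings from %d sessions", len(records), len(sessions))
    return records


def _records_frame(records: Sequence[ReadingRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "visit": [r.visit for r in records],
            "eye": [r.eye for r in records],
            "condition": [r.condition for r in records],
            "method": [r.method for r in records],
            "pupil_mm": [math.nan if r.pupil_mm is None else r.pupil_mm for r in records],
            "n_repeats_used": [r.n_repeats_used for r in records],
        }
    )


def descriptive_table(records: Sequence[ReadingRecord]) -> pd.DataFrame:
    """Mean (SD) pupil size per condition, visit, and reading method."""
    df = _records_frame(records)
    rows = []
    for (cond, visit, method), grp in df.groupby(["condition", "visit", "method"]):
        vals = grp["pupil_mm"].dropna()
        rows.append(
            {
                "condition": cond,
                "visit": visit,
                "method": method,
                "n": int(vals.size),
                "mean_mm": float(vals.mean()) if vals.size else math.nan,
                "sd_mm": float(vals.std(ddof=1)) if vals.size > 1 else math.nan,
            }
        )
    return pd.DataFrame(rows)


def build_pair(
    records: Sequence[ReadingRecord],
    comparison: str,
    condition: str,
    eye: str = "right",
) -> Optional[PairedMeasurements]:
    """Assemble pairwise-complete measurements for one comparison/condition.

    Subjects with a missing reading on either side (quality-threshold
    failures) are dropped pairwise, so each comparison keeps its own N.
    Returns None when no subject has both members.
    """
    spec = COMPARISONS.get(comparison)
    if spec is None:
        raise ConfigError(f"unknown comparison {comparison!r}")
    df = _records_frame(records)
    df = df[(df["condition"] == condition) & (df["eye"] == eye)]
    if spec["kind"] == "visits":
        df = df[df["method"] == spec["method"]]
        side_col = "visit"
    else:
        df = df[df["visit"] == spec["visit"]]
        side_col = "method"
    a_df = df[df[side_col] == spec["a"]].set_index("subject_id")["pupil_mm"]
    b_df = df[df[side_col] == spec["b"]].set_index("subject_id")["pupil_mm"]
    joined = pd.DataFrame({"a": a_df, "b": b_df}).dropna()
    if joined.empty:
        return None
    joined = joined.sort_index()
    return PairedMeasurements(
        label_a=spec["a"],
        label_b=spec["b"],
        subjects=tuple(joined.index),
        a=joined["a"].to_numpy(),
        b=joined["b"].to_numpy(),
    )


def _round_sig(x: float, decimals: int) -> float:
    return float(f"{x:.{decimals}f}") if np.isfinite(x) else x


def _result_row(res: AgreementResult, decimals: int, subset: str) -> dict:
    return {
        "subset": subset,
        "n": res.n,
        "bias": _round_sig(res.bias, decimals),
        "bias_ci_low": _round_sig(res.ci_bias[0], decimals),
        "bias_ci_high": _round_sig(res.ci_bias[1], decimals),
        "loa_lower": _round_sig(res.loa_lower, decimals),
        "loa_lower_ci_low": _round_sig(res.ci_loa_lower[0], decimals),
        "loa_lower_ci_high": _round_sig(res.ci_loa_lower[1], decimals),
        "loa_upper": _round_sig(res.loa_upper, decimals),
        "loa_upper_ci_low": _round_sig(res.ci_loa_upper[0], decimals),
        "loa_upper_ci_high": _round_sig(res.ci_loa_upper[1], decimals),
        "coefficient": _round_sig(res.coefficient, decimals),
        "pearson_r": _round_sig(res.pearson_r, 2),
        "pearson_p": res.pearson_p,
    }


def _ba_result_dict(ba: BlandAltmanResult) -> dict:
    return {
        "all": ba.all.to_dict(),
        "outliers_excluded": (
            ba.outliers_excluded.to_dict() if ba.outliers_excluded is not None else None
        ),
    }


def _pair_report_dict(rep: PairReport) -> dict:
    return {
        "difference": _ba_result_dict(rep.difference),
        "ratio": _ba_result_dict(rep.ratio) if rep.ratio is not None else None,
        "ratio_triggered": rep.ratio_triggered,
        "headline_scale": rep.headline_scale,
        "alpha": rep.alpha,
        "notes": list(rep.notes),
    }


def _config_dict(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    d["conditions"] = list(cfg.conditions)
    d["comparisons"] = list(cfg.comparisons)
    return d


def run_pipeline(
    traces: Sequence[PupilTrace],
    cfg: RunConfig = RunConfig(),
    outdir=None,
) -> ReportBundle:
    """Run readings and all configured agreement analyses; optionally write files.

    Two runs with identical traces and config produce byte-identical JSON
    reports (no timestamps are embedded).
    """
    records = compute_readings(traces, cfg.filter_config, eye=cfg.eye)
    descriptives = descriptive_table(records)

    config_dict = _config_dict(cfg)
    config_json = json.dumps(config_dict, sort_keys=True)
    report = {
        "version": __version__,
        "seed": cfg.seed,
        "config": config_dict,
        "config_hash": hashlib.sha256(config_json.encode()).hexdigest(),
        "descriptives": descriptives.to_dict(orient="records"),
        "comparisons": {},
        "skipped": {},
    }
    diff_rows = []
    ratio_rows = []
    plot_data: Dict[str, pd.DataFrame] = {}
    for comparison in cfg.comparisons:
        for condition in cfg.conditions:
            name = f"{comparison}:{condition}"
            pm = build_pair(records, comparison, condition, eye=cfg.eye)
            if pm is None or pm.n < 3:
                reason = (
                    "fewer than 3 complete pairs"
                    if pm is not None
                    else "no complete pairs"
                )
                logger.warning("skipping comparison %s: %s", name, reason)
                report["skipped"][name] = reason
                continue
            rep = analyze_pair(pm, alpha=cfg.alpha, sd_multiplier=cfg.outlier_sd)
            report["comparisons"][name] = _pair_report_dict(rep)

            for subset, res in (
                ("all", rep.difference.all),
                ("outliers_excluded", rep.difference.outliers_excluded),
            ):
                if res is None:
                    continue
                row = {"comparison": comparison, "condition": condition}
                row.update(_result_row(res, cfg.mm_decimals, subset))
                diff_rows.append(row)
            if rep.ratio is not None:
                for subset, res in (
                    ("all", rep.ratio.all),
                    ("outliers_excluded", rep.ratio.outliers_excluded),
                ):
                    if res is None:
                        continue
                    row = {"comparison": comparison, "condition": condition}
                    row.update(_result_row(res, cfg.ratio_decimals, subset))
                    ratio_rows.append(row)

            v = pm.a - pm.b
            plot_data[f"ba_{name}"] = pd.DataFrame(
                {
                    "subject_id": pm.subjects,
                    "average_mm": (pm.a + pm.b) / 2.0,
                    "difference_mm": v,
                    "ratio": pm.a / pm.b,
                }
            )
            qq = qq_data(v)
            plot_data[f"qq_{name}"] = pd.DataFrame(
                {
                    "theoretical_quantile": qq.theoretical,
                    "standardized_difference": qq.sample,
                }
            )

    agreement_tables = {
        "difference": pd.DataFrame(diff_rows),
        "ratio": pd.DataFrame(ratio_rows),
    }
    bundle = ReportBundle(
        records=records,
        report=report,
        descriptives=descriptives,
        agreement_tables=agreement_tables,
        plot_data=plot_data,
    )
    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _write_bundle(bundle: ReportBundle, outdir: Path) -> None:
    from .trace_io import write_readings

    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(bundle.report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    write_readings(bundle.records, outdir / "readings.csv")
    bundle.descriptives.to_csv(outdir / "descriptives.csv", index=False)
    for scale, table in bundle.agreement_tables.items():
        table.to_csv(outdir / f"agreement_{scale}.csv", index=False)
    for name, df in bundle.plot_data.items():
        safe = name.replace(":", "_")
        df.to_csv(outdir / f"{safe}.csv", index=False)
    logger.info("wrote report bundle to %s", outdir)
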