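"""Summary statistics, criteria sweeps, and cross-method cohort trends.

The summary layout mirrors the table a QA physicist reads off a
comparison run: total evaluable points, points over the critical value
(gamma >= 1, |MDdiff| >= (1/2) deltaD0) with their ratio, then the mean,
mean-absolute, and maximum-absolute metric values as supplementary
evidence. MDdiff means are signed — the sign says which distribution is
hotter.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .dose_model import (
    METRIC_GAMMA,
    METRIC_MDDIFF,
    Criteria,
    DoseGrid,
    MetricMap,
    ValidationError,
    resample_to_reference,
)
from .gamma import GammaOptions, gamma_map, gamma_pass_mask
from .mddiff import mddiff_map, mddiff_pass_mask
from .synthetic import CohortCase

__all__ = [
    "SummaryStats",
    "summarize_metric",
    "compare_pair",
    "criteria_sweep",
    "cohort_trend",
    "write_report",
    "read_report",
    "format_report_table",
]

logger = logging.getLogger("mddiff")


@dataclass(frozen=True)
class SummaryStats:
    """One summary row for one metric on one QA case.

    ``mean`` is signed for MDdiff (cGy) and the plain average for gamma;
    ``mean_abs`` averages |values|; ``max_abs`` is the maximum absolute
    value. Invariants: mean_abs >= |mean| and max_abs >= mean_abs.
    """

    metric_name: str
    total_points: int
    failing_points: int
    failing_ratio: float
    mean: float
    mean_abs: float
    max_abs: float


def summarize_metric(
    metric_map: MetricMap,
    criteria: Criteria,
    signed_rule: bool = False,
) -> SummaryStats:
    """Summarize a gamma or MDdiff map over its valid points."""
    if metric_map.n_valid == 0:
        raise ValidationError("metric map has no valid points to summarize")
    vals = metric_map.valid_values
    if metric_map.metric_name == METRIC_GAMMA:
        result = gamma_pass_mask(metric_map)
    elif metric_map.metric_name == METRIC_MDDIFF:
        result = mddiff_pass_mask(metric_map, criteria, signed_rule=signed_rule)
    else:
        raise TypeError(
            f"no pass rule defined for metric '{metric_map.metric_name}'"
        )
    return SummaryStats(
        metric_name=metric_map.metric_name,
        total_points=metric_map.n_valid,
        failing_points=result.failing_count,
        failing_ratio=result.failing_ratio,
        mean=float(vals.mean()),
        mean_abs=float(np.abs(vals).mean()),
        max_abs=float(np.abs(vals).max()),
    )


def compare_pair(
    evaluated: DoseGrid,
    reference: DoseGrid,
    criteria: Criteria,
    gamma_options: GammaOptions | None = None,
    signed_rule: bool = False,
    methods: tuple[str, ...] = (METRIC_GAMMA, METRIC_MDDIFF),
) -> dict[str, SummaryStats]:
    """Run the full comparison workflow on one reference/evaluated pair.

    The evaluated grid is resampled onto the reference geometry for
    MDdiff; gamma searches the evaluated grid in its native geometry.
    """
    logger.info(
        "compare: criteria deltaD0=%.4g cGy, DTA0=%.4g mm, prescribed=%.4g cGy",
        criteria.dose_diff_criterion,
        criteria.dta_criterion,
        criteria.prescribed_dose,
    )
    logger.info(
        "compare: reference %sx%s @ %s mm, evaluated %sx%s @ %s mm",
        *reference.shape, reference.spacing, *evaluated.shape, evaluated.spacing,
    )
    out: dict[str, SummaryStats] = {}
    if METRIC_GAMMA in methods:
        gmap = gamma_map(evaluated, reference, criteria, gamma_options)
        logger.info(
            "gamma: %d of %d reference points excluded (search disc clipped)",
            gmap.values.size - gmap.n_valid, gmap.values.size,
        )
        out[METRIC_GAMMA] = summarize_metric(gmap, criteria)
    if METRIC_MDDIFF in methods:
        resampled, valid = resample_to_reference(evaluated, reference)
        logger.info(
            "mddiff: %d of %d reference points outside evaluated extent",
            valid.size - int(valid.sum()), valid.size,
        )
        mmap = mddiff_map(resampled, reference, criteria, valid_mask=valid)
        out[METRIC_MDDIFF] = summarize_metric(mmap, criteria, signed_rule=signed_rule)
    return out


def criteria_sweep(
    evaluated: DoseGrid,
    reference: DoseGrid,
    criteria_list: list[Criteria],
    which: str,
    gamma_options: GammaOptions | None = None,
    signed_rule: bool = False,
) -> pd.DataFrame:
    """Failing counts of both methods as one criterion is swept.

    ``which`` is ``"dd"`` (sweep deltaD0, DTA0 fixed) or ``"dta"`` (sweep
    DTA0, deltaD0 fixed). The swept values must be strictly ascending and
    the other criterion held fixed. Enlarging either tolerance can only
    remove failures, so both counts are non-increasing along the sweep.
    """
    if which not in ("dd", "dta"):
        raise ValidationError(f"which: expected 'dd' or 'dta', got {which!r}")
    if len(criteria_list) < 1:
        raise ValidationError("criteria_list: empty")
    swept = [
        c.dose_diff_criterion if which == "dd" else c.dta_criterion
        for c in criteria_list
    ]
    fixed = [
        c.dta_criterion if which == "dd" else c.dose_diff_criterion
        for c in criteria_list
    ]
    if any(b <= a for a, b in zip(swept, swept[1:])):
        raise ValidationError(
            f"criteria_list: swept {which} values must be strictly ascending, got {swept}"
        )
    if any(abs(f - fixed[0]) > 1e-12 for f in fixed):
        raise ValidationError("criteria_list: the non-swept criterion must stay fixed")

    resampled, valid = resample_to_reference(evaluated, reference)
    rows = []
    for crit, value in zip(criteria_list, swept):
        gmap = gamma_map(evaluated, reference, crit, gamma_options)
        g = gamma_pass_mask(gmap)
        mmap = mddiff_map(resampled, reference, crit, valid_mask=valid)
        m = mddiff_pass_mask(mmap, crit, signed_rule=signed_rule)
        rows.append(
            {
                "criterion": value,
                "gamma_failing": g.failing_count,
                "mddiff_failing": m.failing_count,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["which"] = which
    return df


def cohort_trend(
    cases: list[CohortCase] | list[tuple[DoseGrid, DoseGrid]],
    criteria: Criteria,
    gamma_options: GammaOptions | None = None,
    signed_rule: bool = False,
) -> tuple[pd.DataFrame, float | None]:
    """Per-case failing ratios of both methods plus their rank agreement.

    Accepts :class:`CohortCase` objects or bare (reference, evaluated)
    tuples. Returns a DataFrame with one row per case (gamma_ratio,
    mddiff_ratio) and the Spearman rank correlation between the two ratio
    vectors (average ranks on ties); ``None`` when the correlation is
    undefined (e.g. a constant ratio vector).
    """
    if len(cases) < 2:
        raise ValidationError(f"cohort_trend needs at least 2 cases, got {len(cases)}")
    rows = []
    for k, case in enumerate(cases):
        if isinstance(case, CohortCase):
            case_id, ref, ev, severity = case.case_id, case.reference, case.evaluated, case.severity
        else:
            ref, ev = case
            case_id, severity = f"case{k}", float("nan")
        stats = compare_pair(ev, ref, criteria, gamma_options, signed_rule=signed_rule)
        rows.append(
            {
                "case_id": case_id,
                "severity": severity,
                "gamma_ratio": stats[METRIC_GAMMA].failing_ratio,
                "mddiff_ratio": stats[METRIC_MDDIFF].failing_ratio,
            }
        )
    df = pd.DataFrame(rows)
    with warnings.catch_warnings():
        # constant ratio vectors (e.g. all-perfect cohort): undefined -> None
        warnings.simplefilter("ignore")
        rho = spearmanr(df["gamma_ratio"], df["mddiff_ratio"]).statistic
    return df, (None if np.isnan(rho) else float(rho))


# ---------------------------------------------------------------------------
# report serialization

_ROW_LABELS = {
    METRIC_GAMMA: [
        ("gamma >= 1", "failing_points"),
        ("(ratio)", "failing_ratio"),
        ("gamma_avg", "mean"),
        ("gamma_max", "max_abs"),
    ],
    METRIC_MDDIFF: [
        ("|MDdiff| >= (1/2)dD0", "failing_points"),
        ("(ratio)", "failing_ratio"),
        ("MDdiff_avg (cGy)", "mean"),
        ("MDdiff_|avg| (cGy)", "mean_abs"),
        ("MDdiff_max (cGy)", "max_abs"),
    ],
}


def _stats_to_json(s: SummaryStats) -> dict:
    if s.metric_name == METRIC_GAMMA:
        return {
            "total": s.total_points,
            "failing": s.failing_points,
            "ratio": s.failing_ratio,
            "avg": s.mean,
            "max": s.max_abs,
        }
    return {
        "total": s.total_points,
        "failing": s.failing_points,
        "ratio": s.failing_ratio,
        "avg": s.mean,
        "avg_abs": s.mean_abs,
        "max_abs": s.max_abs,
    }


def write_report(
    stats: dict[str, SummaryStats],
    path: str | Path,
    criteria: Criteria,
    case_id: str = "case",
) -> str:
    """Write a machine-readable JSON report; return the human-readable table.

    Schema: ``{case_id, criteria: {dd_cGy, dta_mm, prescribed_cGy},
    gamma: {total, failing, ratio, avg, max},
    mddiff: {total, failing, ratio, avg, avg_abs, max_abs}}``.
    """
    payload = {
        "case_id": case_id,
        "criteria": {
            "dd_cGy": criteria.dose_diff_criterion,
            "dta_mm": criteria.dta_criterion,
            "prescribed_cGy": criteria.prescribed_dose,
        },
    }
    for name, s in stats.items():
        payload[name] = _stats_to_json(s)
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return format_report_table(stats, case_id=case_id)


def format_report_table(stats: dict[str, SummaryStats], case_id: str = "case") -> str:
    """Plain-text summary table, one row per statistic."""
    lines = [f"Patient-specific QA summary: {case_id}"]
    totals = {s.total_points for s in stats.values()}
    if len(totals) == 1:
        lines.append(f"{'Total # of Data Points':28s} {totals.pop()}")
    for name, s in stats.items():
        if len(totals) > 1:
            lines.append(f"{'Total # of Data Points (' + name + ')':28s} {s.total_points}")
        for label, field in _ROW_LABELS.get(name, []):
            v = getattr(s, field)
            if field == "failing_ratio":
                lines.append(f"{label:28s} {100.0 * v:.2f}%")
            elif field == "failing_points":
                lines.append(f"{label:28s} {v}")
            else:
                lines.append(f"{label:28s} {v:.2f}")
    return "\n".join(lines)


def read_report(path: str | Path) -> tuple[str, Criteria, dict[str, SummaryStats]]:
    """Re-parse a JSON report written by :func:`write_report`."""
    payload = json.loads(Path(path).read_text())
    crit = Criteria(
        payload["criteria"]["dd_cGy"],
        payload["criteria"]["dta_mm"],
        payload["criteria"]["prescribed_cGy"],
    )
    stats = {}
    for name in (METRIC_GAMMA, METRIC_MDDIFF):
        if name not in payload:
            continue
        d = payload[name]
        stats[name] = SummaryStats(
            metric_name=name,
            total_points=d["total"],
            failing_points=d["failing"],
            failing_ratio=d["ratio"],
            mean=d["avg"],
            mean_abs=d.get("avg_abs", d["avg"]),
            max_abs=d.get("max_abs", d.get("max")),
        )
    return payload["case_id"], crit, stats
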