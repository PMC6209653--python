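"""Sensitivity and publication-bias diagnostics.

Leave-one-out sensitivity re-runs the full pooling (including fixed/random
re-selection) k times, omitting one study each time.  Publication bias is
quantified with Egger's regression of the standardized effect on precision;
funnel coordinates are exported for visual inspection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy import stats

from . import meta_engine
from .data_model_io import StudyRecord
from .genetic_models import model_table
from .meta_engine import EffectEstimate, PooledResult

__all__ = [
    "STABILITY_TOLERANCE_DEFAULT",
    "LooEntry",
    "SensitivityReport",
    "EggerResult",
    "leave_one_out",
    "funnel_data",
    "egger_test",
]

#: Default bound on the relative change in pooled OR for a "stable" call.
STABILITY_TOLERANCE_DEFAULT = 0.20


@dataclass(frozen=True)
class LooEntry:
    left_out_study_id: str
    pooled_or: float
    ci_low: float
    ci_high: float
    p: float


@dataclass(frozen=True)
class SensitivityReport:
    variant_id: str
    group: str
    baseline_or: float
    loo_entries: list[LooEntry]
    or_range: tuple[float, float]
    stable: bool
    stability_tolerance: float


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    intercept_se: float
    t_statistic: float
    p: float
    k: int


def _pool_tables(tables, study_ids, *, variant_id, group, genetic_model) -> PooledResult:
    return meta_engine.pool(
        tables,
        variant_id=variant_id,
        group=group,
        genetic_model=genetic_model,
        study_ids=study_ids,
    )


def leave_one_out(
    records: Sequence[StudyRecord],
    *,
    variant_id: str,
    group: str = "overall",
    genetic_model: str = "allele",
    stability_tolerance: float = STABILITY_TOLERANCE_DEFAULT,
) -> SensitivityReport:
    """Delete each study in turn and re-pool, re-selecting fixed vs random.

    ``stable`` is true iff every leave-one-out pooled OR keeps the baseline's
    side of 1 and changes by at most ``stability_tolerance`` relative to the
    baseline OR.
    """
    if len(records) < 2:
        raise ValueError("sensitivity undefined: need at least two studies")
    tables = [model_table(genetic_model, r.case_counts, r.control_counts) for r in records]
    ids = [r.study_id for r in records]
    baseline = _pool_tables(
        tables, ids, variant_id=variant_id, group=group, genetic_model=genetic_model
    )
    entries: list[LooEntry] = []
    for i in range(len(records)):
        sub_tables = tables[:i] + tables[i + 1 :]
        sub_ids = ids[:i] + ids[i + 1 :]
        result = _pool_tables(
            sub_tables, sub_ids, variant_id=variant_id, group=group, genetic_model=genetic_model
        )
        entries.append(
            LooEntry(
                left_out_study_id=ids[i],
                pooled_or=result.pooled_or,
                ci_low=result.ci_low,
                ci_high=result.ci_high,
                p=result.p,
            )
        )
    ors = [e.pooled_or for e in entries]
    or_range = (min(ors), max(ors))
    base = baseline.pooled_or
    same_side = all((or_ - 1.0) * (base - 1.0) >= 0.0 for or_ in ors)
    within = all(abs(or_ - base) / base <= stability_tolerance for or_ in ors)
    return SensitivityReport(
        variant_id=variant_id,
        group=group,
        baseline_or=base,
        loo_entries=entries,
        or_range=or_range,
        stable=same_side and within,
        stability_tolerance=stability_tolerance,
    )


def funnel_data(effects: Sequence[EffectEstimate]) -> list[tuple[str, float, float]]:
    """Plot-ready ``(study_id, log_or, se)`` triples, ordered by se ascending."""
    return [
        (e.study_id, e.log_or, e.se)
        for e in sorted(effects, key=lambda e: e.se)
    ]


def egger_test(effects: Sequence[EffectEstimate]) -> EggerResult:
    """Egger's regression test for funnel-plot asymmetry.

    Ordinary least squares of the standardized effect (log OR / se) on
    precision (1 / se); the intercept's two-sided t test (k - 2 df) is the
    asymmetry test.
    """
    k = len(effects)
    if k < 3:
        raise ValueError("Egger's test requires at least three studies")
    x = [1.0 / e.se for e in effects]
    y = [e.log_or / e.se for e in effects]
    n = float(k)
    x_bar = sum(x) / n
    y_bar = sum(y) / n
    sxx = sum((xi - x_bar) ** 2 for xi in x)
    if sxx == 0:
        # constant precision: the slope is unidentifiable.  A funnel of
        # exactly equal effects is perfectly symmetric; anything else is
        # genuinely undefined.
        if all(yi == y[0] for yi in y):
            return EggerResult(intercept=0.0, intercept_se=0.0, t_statistic=0.0, p=1.0, k=k)
        raise ValueError("Egger's test undefined: all studies share one precision")
    sxy = sum((xi - x_bar) * (yi - y_bar) for xi, yi in zip(x, y))
    slope = sxy / sxx
    intercept = y_bar - slope * x_bar
    residuals = [yi - (intercept + slope * xi) for xi, yi in zip(x, y)]
    df = k - 2
    sigma2 = sum(r * r for r in residuals) / df
    intercept_se = math.sqrt(sigma2 * (1.0 / n + x_bar * x_bar / sxx))
    if intercept_se == 0.0:
        # perfectly collinear inputs; a zero intercept is exactly symmetric
        t_statistic = 0.0 if intercept == 0.0 else math.inf
    else:
        t_statistic = intercept / intercept_se
    p = 2.0 * float(stats.t.sf(abs(t_statistic), df=df)) if math.isfinite(t_statistic) else 0.0
    return EggerResult(
        intercept=intercept,
        intercept_se=intercept_se,
        t_statistic=t_statistic,
        p=min(1.0, p),
        k=k,
    )
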