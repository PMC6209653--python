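"""Full analysis orchestration.

Stages: eligibility filtering (>= 4 studies per variant by default),
grouped allele-model meta-analysis (overall / by ethnicity / by country),
two-tier significance classification, dominant/recessive decomposition of
the top-tier variants into heterozygote/homozygote contribution calls, and
counts-weighted pooled allele-frequency summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from . import meta_engine
from .data_model_io import ReportRow, StudyRecord, VariantDataset
from .genetic_models import model_table
from .meta_engine import PooledResult, PoolingError

logger = logging.getLogger(__name__)

__all__ = [
    "TIER1_DEFAULT",
    "TIER2_DEFAULT",
    "MIN_STUDIES_DEFAULT",
    "SUBGROUP_MIN_STUDIES_DEFAULT",
    "ClassificationResult",
    "AFSummary",
    "eligible_variants",
    "run_group_meta",
    "classify",
    "decompose_contributions",
    "pooled_af",
    "bonferroni",
    "run_pipeline",
    "PipelineReport",
]

TIER1_DEFAULT = 0.05
TIER2_DEFAULT = 1e-5
MIN_STUDIES_DEFAULT = 4
SUBGROUP_MIN_STUDIES_DEFAULT = 2

TIER_MOST = "most_recommended"
TIER_RECOMMENDED = "recommended"
TIER_NOT = "not_recommended"

GROUP_OVERALL = "overall"
GROUPINGS = ("overall", "by_ethnicity", "by_country")


@dataclass(frozen=True)
class ClassificationResult:
    """Screening tier, effect direction and contribution call for one variant x group."""

    variant_id: str
    group: str
    tier: str
    direction: str
    contribution: str = "not_assessed"

    def __post_init__(self) -> None:
        if self.tier not in (TIER_MOST, TIER_RECOMMENDED, TIER_NOT):
            raise ValueError(f"unknown tier {self.tier!r}")
        if self.contribution != "not_assessed" and self.tier != TIER_MOST:
            raise ValueError("contribution calls apply to most_recommended variants only")


@dataclass(frozen=True)
class AFSummary:
    """Counts-weighted pooled risk-allele frequencies for one variant x group."""

    variant_id: str
    group: str
    af_cases: float
    af_controls: float
    af_population: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("af_cases", "af_controls"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


def eligible_variants(
    datasets: Iterable[VariantDataset], min_studies: int = MIN_STUDIES_DEFAULT
) -> list[str]:
    """Variants with at least ``min_studies`` accepted studies, sorted by rsID."""
    return sorted(d.variant_id for d in datasets if d.k >= min_studies)


def _group_records(
    records: Sequence[StudyRecord], grouping: str
) -> list[tuple[str, list[StudyRecord]]]:
    if grouping == "overall":
        return [(GROUP_OVERALL, list(records))]
    if grouping == "by_ethnicity":
        key = lambda r: r.ethnicity
        prefix = ""
    elif grouping == "by_country":
        key = lambda r: f"country:{r.country}"
        prefix = "country:"
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    del prefix
    groups: dict[str, list[StudyRecord]] = {}
    for record in records:
        groups.setdefault(key(record), []).append(record)
    return sorted(groups.items())


def _pool_records(
    records: Sequence[StudyRecord],
    *,
    variant_id: str,
    group: str,
    genetic_model: str,
) -> PooledResult:
    tables = [model_table(genetic_model, r.case_counts, r.control_counts) for r in records]
    return meta_engine.pool(
        tables,
        variant_id=variant_id,
        group=group,
        genetic_model=genetic_model,
        study_ids=[r.study_id for r in records],
    )


def run_group_meta(
    datasets: Sequence[VariantDataset],
    grouping: str = "overall",
    genetic_model: str = "allele",
    *,
    subgroup_min_studies: int = SUBGROUP_MIN_STUDIES_DEFAULT,
) -> list[PooledResult]:
    """Pooled results per variant per group under one genetic model.

    Groups with fewer than ``subgroup_min_studies`` studies are omitted and
    logged (the overall group is never subject to this bound — eligibility
    is the caller's responsibility there).
    """
    results: list[PooledResult] = []
    for dataset in datasets:
        for group, records in _group_records(dataset.analysis_records, grouping):
            if group != GROUP_OVERALL and len(records) < subgroup_min_studies:
                logger.info(
                    "omitting %s / %s: %d studies < subgroup minimum %d",
                    dataset.variant_id, group, len(records), subgroup_min_studies,
                )
                continue
            if not records:
                continue
            try:
                results.append(
                    _pool_records(
                        records,
                        variant_id=dataset.variant_id,
                        group=group,
                        genetic_model=genetic_model,
                    )
                )
            except PoolingError as exc:
                logger.warning(
                    "skipping %s / %s (%s): %s", dataset.variant_id, group, genetic_model, exc
                )
    return results


def classify(
    result: PooledResult,
    tier1: float = TIER1_DEFAULT,
    tier2: float = TIER2_DEFAULT,
    contribution: str = "not_assessed",
) -> ClassificationResult:
    """Two-tier classification with strict thresholds.

    p < tier2 -> most_recommended; tier2 <= p < tier1 -> recommended;
    otherwise not_recommended.  Direction is read off the pooled OR only
    for classified variants.
    """
    if result.p < tier2:
        tier = TIER_MOST
    elif result.p < tier1:
        tier = TIER_RECOMMENDED
    else:
        tier = TIER_NOT
    if tier == TIER_NOT or result.pooled_or == 1.0:
        direction = "none"
    elif result.pooled_or > 1.0:
        direction = "risk"
    else:
        direction = "protective"
    if tier != TIER_MOST:
        contribution = "not_assessed"
    return ClassificationResult(
        variant_id=result.variant_id,
        group=result.group,
        tier=tier,
        direction=direction,
        contribution=contribution,
    )


def decompose_contributions(
    records: Sequence[StudyRecord],
    *,
    variant_id: str,
    group: str = GROUP_OVERALL,
    tier2: float = TIER2_DEFAULT,
) -> tuple[str, PooledResult, PooledResult]:
    """Attribute a top-tier signal to heterozygotes and/or homozygotes.

    Runs dominant and recessive pooled analyses on the same studies;
    dominant-only significance (p < tier2) implicates heterozygotes,
    recessive-only implicates homozygotes.  Returns
    ``(contribution, dominant_result, recessive_result)``.
    """
    dominant = _pool_records(
        records, variant_id=variant_id, group=group, genetic_model="dominant"
    )
    recessive = _pool_records(
        records, variant_id=variant_id, group=group, genetic_model="recessive"
    )
    dom_sig = dominant.p < tier2
    rec_sig = recessive.p < tier2
    if dom_sig and rec_sig:
        contribution = "both"
    elif dom_sig:
        contribution = "heterozygote"
    elif rec_sig:
        contribution = "homozygote"
    else:
        contribution = "neither"
    return contribution, dominant, recessive


def pooled_af(
    records: Sequence[StudyRecord], *, variant_id: str, group: str = GROUP_OVERALL
) -> AFSummary:
    """Counts-weighted pooled risk-allele frequencies across studies."""
    if not records:
        raise ValueError("pooled AF requires at least one record")
    case_risk = sum(r.case_counts.risk_alleles for r in records)
    case_total = sum(2 * r.case_counts.total for r in records)
    ctrl_risk = sum(r.control_counts.risk_alleles for r in records)
    ctrl_total = sum(2 * r.control_counts.total for r in records)
    af_population = next((r.af_gnomad for r in records if r.af_gnomad is not None), None)
    return AFSummary(
        variant_id=variant_id,
        group=group,
        af_cases=case_risk / case_total,
        af_controls=ctrl_risk / ctrl_total,
        af_population=af_population,
    )


def bonferroni(p: float, n_tests: int) -> float:
    """Bonferroni-adjusted p (utility only; not wired into classification)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return min(1.0, p * n_tests)


@dataclass
class PipelineReport:
    """Everything the full run produces, ready for the writers."""

    rows: list[ReportRow]
    pooled: list[PooledResult]
    classifications: list[ClassificationResult]
    af_summaries: list[AFSummary]


def _report_row(
    result: PooledResult,
    af: Optional[AFSummary],
    classification: Optional[ClassificationResult],
) -> ReportRow:
    return ReportRow(
        variant_id=result.variant_id,
        group=result.group,
        genetic_model=result.genetic_model,
        method=result.method,
        k=result.k,
        pooled_or=result.pooled_or,
        ci_low=result.ci_low,
        ci_high=result.ci_high,
        z=result.z,
        p=result.p,
        q=result.q,
        df=result.df,
        p_q=result.p_q,
        i_squared=result.i_squared,
        tau_squared=result.tau_squared,
        af_cases=None if af is None else af.af_cases,
        af_controls=None if af is None else af.af_controls,
        af_population=None if af is None else af.af_population,
        tier=None if classification is None else classification.tier,
        direction=None if classification is None else classification.direction,
        contribution=None if classification is None else classification.contribution,
    )


def run_pipeline(
    datasets: Sequence[VariantDataset],
    *,
    groupings: Sequence[str] = ("overall",),
    models: Sequence[str] = ("allele",),
    tier1: float = TIER1_DEFAULT,
    tier2: float = TIER2_DEFAULT,
    min_studies: int = MIN_STUDIES_DEFAULT,
    subgroup_min_studies: int = SUBGROUP_MIN_STUDIES_DEFAULT,
) -> PipelineReport:
    """Run the complete procedure and assemble the result table.

    Classification always derives from the allele model; dominant/recessive
    rows are emitted when requested, and contribution calls are computed for
    every most_recommended variant x group regardless of ``models``.
    """
    if "allele" not in models:
        raise ValueError("the allele model is required for classification")
    eligible = set(eligible_variants(datasets, min_studies=min_studies))
    kept = sorted(
        (d for d in datasets if d.variant_id in eligible), key=lambda d: d.variant_id
    )
    dropped = sorted(d.variant_id for d in datasets if d.variant_id not in eligible)
    if dropped:
        logger.info("variants below the %d-study minimum: %s", min_studies, ", ".join(dropped))

    records_by_key: dict[tuple[str, str], list[StudyRecord]] = {}
    for dataset in kept:
        for grouping in groupings:
            for group, records in _group_records(dataset.analysis_records, grouping):
                records_by_key[(dataset.variant_id, group)] = records

    rows: list[ReportRow] = []
    pooled: list[PooledResult] = []
    classifications: list[ClassificationResult] = []
    af_summaries: list[AFSummary] = []
    extra_rows: list[ReportRow] = []

    for grouping in groupings:
        allele_results = run_group_meta(
            kept, grouping, "allele", subgroup_min_studies=subgroup_min_studies
        )
        for result in allele_results:
            records = records_by_key[(result.variant_id, result.group)]
            af = pooled_af(records, variant_id=result.variant_id, group=result.group)
            classification = classify(result, tier1=tier1, tier2=tier2)
            if classification.tier == TIER_MOST:
                contribution, dominant, recessive = decompose_contributions(
                    records, variant_id=result.variant_id, group=result.group, tier2=tier2
                )
                classification = ClassificationResult(
                    variant_id=classification.variant_id,
                    group=classification.group,
                    tier=classification.tier,
                    direction=classification.direction,
                    contribution=contribution,
                )
                for extra in (dominant, recessive):
                    if extra.genetic_model in models:
                        pooled.append(extra)
                        extra_rows.append(_report_row(extra, af, None))
            elif set(models) - {"allele"}:
                # non-top-tier variants still get the extra model rows when asked
                for model in models:
                    if model == "allele":
                        continue
                    try:
                        extra = _pool_records(
                            records,
                            variant_id=result.variant_id,
                            group=result.group,
                            genetic_model=model,
                        )
                    except PoolingError as exc:
                        logger.warning(
                            "skipping %s / %s (%s): %s",
                            result.variant_id, result.group, model, exc,
                        )
                        continue
                    pooled.append(extra)
                    extra_rows.append(_report_row(extra, af, None))
            pooled.append(result)
            classifications.append(classification)
            af_summaries.append(af)
            rows.append(_report_row(result, af, classification))

    rows.extend(extra_rows)
    return PipelineReport(
        rows=rows,
        pooled=pooled,
        classifications=classifications,
        af_summaries=af_summaries,
    )
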