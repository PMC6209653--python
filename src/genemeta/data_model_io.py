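"""Study-level data model, tabular input reading/validation, result writers.

The input is a UTF-8 TSV with one row per study x variant::

    study_id  author_year  ethnicity  country  nos  variant_id  risk_allele
    other_allele  case_hom_risk  case_het  case_hom_other  ctrl_hom_risk
    ctrl_het  ctrl_hom_other  [superseded_by]  [af_gnomad]

Rows are validated against the :class:`StudyRecord` invariants, harmonized
to one risk allele per variant (flipping genotype triples where a row's
orientation disagrees), and grouped into :class:`VariantDataset` objects.
Records carrying ``superseded_by`` mark overlapping cohorts replaced by a
newer study; they stay in the roster but are excluded from analysis totals.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .genetic_models import GenotypeCounts, InvalidCountsError

logger = logging.getLogger(__name__)

__all__ = [
    "ETHNICITIES",
    "StudyRecord",
    "VariantDataset",
    "ReportRow",
    "SchemaError",
    "ValidationError",
    "read_records",
    "group_by_variant",
    "read_dataset",
    "write_results",
    "read_results",
    "write_forest_csv",
    "write_funnel_csv",
    "p_display",
]

ETHNICITIES = ("European", "East Asian", "Latino", "West Asian", "Mixed")

REQUIRED_COLUMNS = (
    "study_id",
    "author_year",
    "ethnicity",
    "country",
    "nos",
    "variant_id",
    "risk_allele",
    "other_allele",
    "case_hom_risk",
    "case_het",
    "case_hom_other",
    "ctrl_hom_risk",
    "ctrl_het",
    "ctrl_hom_other",
)
OPTIONAL_COLUMNS = ("superseded_by", "af_gnomad")

#: p-values below this floor are displayed as "<0.00001" (raw values untouched).
P_DISPLAY_FLOOR = 1e-5


class SchemaError(ValueError):
    """The input file's header does not match the documented schema."""


class ValidationError(ValueError):
    """One or more rows violate the record invariants."""

    def __init__(self, messages: Sequence[str]):
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))


@dataclass(frozen=True)
class StudyRecord:
    """One study's metadata and genotype counts for one variant."""

    study_id: str
    author_year: str
    ethnicity: str
    country: str
    nos_score: int
    variant_id: str
    risk_allele: str
    other_allele: str
    case_counts: GenotypeCounts
    control_counts: GenotypeCounts
    superseded_by: Optional[str] = None
    af_gnomad: Optional[float] = None
    flipped: bool = False

    def __post_init__(self) -> None:
        if self.ethnicity not in ETHNICITIES:
            raise ValueError(
                f"unknown ethnicity {self.ethnicity!r}; expected one of {ETHNICITIES}"
            )
        if self.risk_allele == self.other_allele:
            raise ValueError("risk and other allele must differ")
        if not (0 <= self.nos_score <= 9):
            raise ValueError("NOS score must lie in 0..9")

    @property
    def superseded(self) -> bool:
        """True when this cohort is replaced by a newer study."""
        return self.superseded_by is not None

    @property
    def n_cases(self) -> int:
        return self.case_counts.total

    @property
    def n_controls(self) -> int:
        return self.control_counts.total


@dataclass
class VariantDataset:
    """All study records for one variant, harmonized to one risk allele."""

    variant_id: str
    risk_allele: str
    other_allele: str
    records: list[StudyRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for record in self.records:
            if record.variant_id != self.variant_id:
                raise ValueError("all records must share the dataset's variant_id")
            if record.study_id in seen:
                raise ValueError(
                    f"duplicate study_id {record.study_id!r} for variant {self.variant_id}"
                )
            seen.add(record.study_id)

    @property
    def analysis_records(self) -> list[StudyRecord]:
        """Records entering pooled analyses (superseded cohorts removed)."""
        return [r for r in self.records if not r.superseded]

    @property
    def k(self) -> int:
        return len(self.analysis_records)


def _parse_int(value: str, what: str) -> int:
    try:
        as_float = float(value)
    except (TypeError, ValueError):
        raise ValueError(f"{what} is not a number: {value!r}") from None
    if not as_float.is_integer():
        raise ValueError(f"{what} must be an integer, got {value!r}")
    return int(as_float)


def _row_to_record(row: pd.Series) -> StudyRecord:
    case_counts = GenotypeCounts(
        _parse_int(row["case_hom_risk"], "case_hom_risk"),
        _parse_int(row["case_het"], "case_het"),
        _parse_int(row["case_hom_other"], "case_hom_other"),
    )
    control_counts = GenotypeCounts(
        _parse_int(row["ctrl_hom_risk"], "ctrl_hom_risk"),
        _parse_int(row["ctrl_het"], "ctrl_het"),
        _parse_int(row["ctrl_hom_other"], "ctrl_hom_other"),
    )
    superseded_by = row.get("superseded_by")
    if superseded_by is not None and (superseded_by == "" or pd.isna(superseded_by)):
        superseded_by = None
    af_gnomad = row.get("af_gnomad")
    if af_gnomad is not None and (af_gnomad == "" or pd.isna(af_gnomad)):
        af_gnomad = None
    elif af_gnomad is not None:
        af_gnomad = float(af_gnomad)
    return StudyRecord(
        study_id=str(row["study_id"]),
        author_year=str(row["author_year"]),
        ethnicity=str(row["ethnicity"]),
        country=str(row["country"]),
        nos_score=_parse_int(row["nos"], "nos"),
        variant_id=str(row["variant_id"]),
        risk_allele=str(row["risk_allele"]),
        other_allele=str(row["other_allele"]),
        case_counts=case_counts,
        control_counts=control_counts,
        superseded_by=superseded_by,
        af_gnomad=af_gnomad,
    )


def read_records(
    path: str | Path, *, strict: bool = True
) -> tuple[list[StudyRecord], list[tuple[int, str]]]:
    """Read and validate study records from a TSV file.

    Returns ``(records, rejected)`` where ``rejected`` holds
    ``(1-based data row number, message)`` pairs.  With ``strict`` (the
    default) any rejected row raises :class:`ValidationError` instead.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    records: list[StudyRecord] = []
    rejected: list[tuple[int, str]] = []
    for index, row in frame.iterrows():
        row_number = int(index) + 1
        try:
            records.append(_row_to_record(row))
        except (ValueError, InvalidCountsError) as exc:
            rejected.append((row_number, f"row {row_number}: {exc}"))
    if rejected and strict:
        raise ValidationError([msg for _, msg in rejected])
    for _, msg in rejected:
        logger.warning("rejected %s", msg)
    if not records:
        logger.warning("no valid study records in %s", path)
    return records, rejected


def group_by_variant(records: Iterable[StudyRecord]) -> list[VariantDataset]:
    """Partition records by variant and harmonize risk-allele orientation.

    The first record seen for a variant fixes the dataset's risk allele;
    later rows with the opposite orientation have their genotype triples
    flipped and are marked ``flipped``.
    """
    grouped: dict[str, list[StudyRecord]] = {}
    orientation: dict[str, tuple[str, str]] = {}
    for record in records:
        vid = record.variant_id
        if vid not in orientation:
            orientation[vid] = (record.risk_allele, record.other_allele)
            grouped[vid] = []
        risk, other = orientation[vid]
        if (record.risk_allele, record.other_allele) == (risk, other):
            grouped[vid].append(record)
        elif (record.risk_allele, record.other_allele) == (other, risk):
            logger.info(
                "flipping allele orientation for study %s at %s", record.study_id, vid
            )
            grouped[vid].append(
                replace(
                    record,
                    risk_allele=risk,
                    other_allele=other,
                    case_counts=record.case_counts.flipped(),
                    control_counts=record.control_counts.flipped(),
                    af_gnomad=None if record.af_gnomad is None else 1.0 - record.af_gnomad,
                    flipped=True,
                )
            )
        else:
            raise ValidationError(
                [
                    f"study {record.study_id}: alleles "
                    f"{record.risk_allele}/{record.other_allele} do not match "
                    f"{risk}/{other} for {vid}"
                ]
            )
    return [
        VariantDataset(
            variant_id=vid,
            risk_allele=orientation[vid][0],
            other_allele=orientation[vid][1],
            records=recs,
        )
        for vid, recs in grouped.items()
    ]


def read_dataset(path: str | Path, format: str = "tsv", *, strict: bool = True) -> list[VariantDataset]:
    """Read, validate and group the input file into per-variant datasets."""
    if format != "tsv":
        raise ValueError(f"unsupported input format {format!r}")
    records, _ = read_records(path, strict=strict)
    return group_by_variant(records)


def write_records_tsv(records: Sequence[StudyRecord], path: str | Path) -> None:
    """Write study records in the standard input TSV schema."""
    rows = []
    for r in records:
        rows.append(
            {
                "study_id": r.study_id,
                "author_year": r.author_year,
                "ethnicity": r.ethnicity,
                "country": r.country,
                "nos": r.nos_score,
                "variant_id": r.variant_id,
                "risk_allele": r.risk_allele,
                "other_allele": r.other_allele,
                "case_hom_risk": r.case_counts.hom_risk,
                "case_het": r.case_counts.het,
                "case_hom_other": r.case_counts.hom_other,
                "ctrl_hom_risk": r.control_counts.hom_risk,
                "ctrl_het": r.control_counts.het,
                "ctrl_hom_other": r.control_counts.hom_other,
                "superseded_by": r.superseded_by or "",
                "af_gnomad": "" if r.af_gnomad is None else r.af_gnomad,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Result output
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReportRow:
    """One output row: variant x group x genetic model.

    Mirrors the pooled-estimate table layout (OR with CI bounds, raw p,
    heterogeneity block, pooled allele frequencies) plus the screening tier
    and heterozygote/homozygote contribution call where assessed.
    """

    variant_id: str
    group: str
    genetic_model: str
    method: str
    k: int
    pooled_or: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    q: float
    df: int
    p_q: float
    i_squared: float
    tau_squared: float
    af_cases: Optional[float] = None
    af_controls: Optional[float] = None
    af_population: Optional[float] = None
    tier: Optional[str] = None
    direction: Optional[str] = None
    contribution: Optional[str] = None


RESULT_COLUMNS = [f.name for f in ReportRow.__dataclass_fields__.values()]
_FLOAT_FIELDS = {
    "pooled_or", "ci_low", "ci_high", "z", "p", "q", "p_q", "i_squared",
    "tau_squared", "af_cases", "af_controls", "af_population",
}
_INT_FIELDS = {"k", "df"}
_OPTIONAL_FIELDS = {"af_cases", "af_controls", "af_population", "tier", "direction", "contribution"}


def p_display(p: float, floor: float = P_DISPLAY_FLOOR) -> str:
    """Presentation form of a p-value: "<0.00001" below the floor, else the raw value."""
    if p < floor:
        return f"<{floor:.5f}".rstrip("0") if floor != 1e-5 else "<0.00001"
    return repr(float(p))


def _rows_to_frame(rows: Sequence[ReportRow]) -> pd.DataFrame:
    data = [asdict(r) for r in rows]
    frame = pd.DataFrame(data, columns=RESULT_COLUMNS)
    frame.insert(RESULT_COLUMNS.index("p") + 1, "p_display", [p_display(r.p) for r in rows])
    return frame


def write_results(rows: Sequence[ReportRow], path: str | Path, format: str = "tsv") -> None:
    """Write result rows as TSV or JSON at full numeric precision."""
    if not rows:
        raise ValueError("result set is empty")
    path = Path(path)
    if format == "tsv":
        frame = _rows_to_frame(rows)
        # str(float) is the shortest round-trip repr, so read_results restores
        # every value exactly.
        frame.to_csv(path, sep="\t", index=False, na_rep="")
    elif format == "json":
        payload = []
        for row in rows:
            entry = asdict(row)
            entry["p_display"] = p_display(row.p)
            payload.append(entry)
        path.write_text(json.dumps(payload, indent=2))
    else:
        raise ValueError(f"unsupported result format {format!r}")


def _entry_to_row(entry: dict) -> ReportRow:
    entry = dict(entry)
    entry.pop("p_display", None)
    for name in _INT_FIELDS:
        entry[name] = int(entry[name])
    for name in _FLOAT_FIELDS:
        value = entry.get(name)
        if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
            entry[name] = None if name in _OPTIONAL_FIELDS else float("nan")
        else:
            entry[name] = float(value)
    for name in ("tier", "direction", "contribution"):
        value = entry.get(name)
        if value is None or value == "" or (isinstance(value, float) and math.isnan(value)):
            entry[name] = None
    return ReportRow(**entry)


def read_results(path: str | Path, format: str = "tsv") -> list[ReportRow]:
    """Read back a results file written by :func:`write_results`."""
    path = Path(path)
    if format == "tsv":
        frame = pd.read_csv(path, sep="\t")
        return [_entry_to_row(rec) for rec in frame.to_dict(orient="records")]
    if format == "json":
        return [_entry_to_row(entry) for entry in json.loads(path.read_text())]
    raise ValueError(f"unsupported result format {format!r}")


def write_forest_csv(entries: Sequence[dict], path: str | Path) -> None:
    """Plot-ready per-study forest data (OR, CI bounds, weight)."""
    frame = pd.DataFrame(
        entries,
        columns=["variant_id", "group", "study_id", "or_value", "ci_low", "ci_high", "weight"],
    )
    frame.to_csv(path, index=False)


def write_funnel_csv(points: Sequence[tuple[str, float, float]], path: str | Path) -> None:
    """Funnel coordinates (study_id, log_or, se), one row per study."""
    frame = pd.DataFrame(points, columns=["study_id", "log_or", "se"])
    frame.to_csv(path, index=False)
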