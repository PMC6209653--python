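"""Genetic-model transforms: genotype counts -> 2x2 exposure tables.

Three classical single-locus models are supported:

* **allele** -- each person contributes two alleles; the table counts risk
  vs other alleles in cases and controls.
* **dominant** -- risk-allele carriers (hom + het) vs non-carriers, persons.
* **recessive** -- risk homozygotes vs everyone else, persons.

Heterozygotes are never split fractionally: under the allele model a
heterozygous person contributes exactly one risk and one other allele.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from scipy import stats

__all__ = [
    "GenotypeCounts",
    "ContingencyTable",
    "allele_table",
    "dominant_table",
    "recessive_table",
    "allele_frequency",
    "hwe_chi_square",
]

ALLELE_UNIT = "alleles"
PERSON_UNIT = "persons"


class InvalidCountsError(ValueError):
    """Raised when genotype counts violate their invariants."""


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one study arm: (hom_risk, het, hom_other), persons."""

    hom_risk: int
    het: int
    hom_other: int

    def __post_init__(self) -> None:
        for name in ("hom_risk", "het", "hom_other"):
            value = getattr(self, name)
            if not isinstance(value, (int,)) or isinstance(value, bool):
                raise InvalidCountsError(f"{name} must be an integer, got {value!r}")
            if value < 0:
                raise InvalidCountsError(f"{name} must be non-negative, got {value}")
        if self.total < 1:
            raise InvalidCountsError("genotype counts must total at least one person")

    @property
    def total(self) -> int:
        return self.hom_risk + self.het + self.hom_other

    @property
    def risk_alleles(self) -> int:
        return 2 * self.hom_risk + self.het

    @property
    def other_alleles(self) -> int:
        return 2 * self.hom_other + self.het

    def flipped(self) -> "GenotypeCounts":
        """Counts with the risk/other allele orientation swapped."""
        return GenotypeCounts(self.hom_other, self.het, self.hom_risk)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 exposure table: cases/controls (rows) x exposed/unexposed (cols).

    ``a``/``b`` are case exposed/unexposed, ``c``/``d`` control
    exposed/unexposed.  ``unit`` records whether cells count alleles
    (allele model) or persons (dominant/recessive).  ``corrected`` marks a
    table whose cells carry a +0.5 continuity correction.
    """

    a: float
    b: float
    c: float
    d: float
    unit: str = PERSON_UNIT
    corrected: bool = False

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.a + self.b <= 0 or self.c + self.d <= 0:
            raise ValueError("both case and control margins must be positive")

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0

    @property
    def total(self) -> float:
        return self.a + self.b + self.c + self.d

    def with_correction(self, delta: float = 0.5) -> "ContingencyTable":
        """Return a copy with ``delta`` added to every cell (continuity correction)."""
        return replace(
            self,
            a=self.a + delta,
            b=self.b + delta,
            c=self.c + delta,
            d=self.d + delta,
            corrected=True,
        )

    def swapped_rows(self) -> "ContingencyTable":
        """Exchange the case and control rows (inverts the odds ratio)."""
        return replace(self, a=self.c, b=self.d, c=self.a, d=self.b)


def allele_table(cases: GenotypeCounts, controls: GenotypeCounts) -> ContingencyTable:
    """Allele-model table: risk vs other allele counts, cases vs controls."""
    return ContingencyTable(
        a=cases.risk_alleles,
        b=cases.other_alleles,
        c=controls.risk_alleles,
        d=controls.other_alleles,
        unit=ALLELE_UNIT,
    )


def dominant_table(cases: GenotypeCounts, controls: GenotypeCounts) -> ContingencyTable:
    """Dominant-model table: risk-allele carriers vs non-carriers, persons."""
    return ContingencyTable(
        a=cases.hom_risk + cases.het,
        b=cases.hom_other,
        c=controls.hom_risk + controls.het,
        d=controls.hom_other,
        unit=PERSON_UNIT,
    )


def recessive_table(cases: GenotypeCounts, controls: GenotypeCounts) -> ContingencyTable:
    """Recessive-model table: risk homozygotes vs all others, persons."""
    return ContingencyTable(
        a=cases.hom_risk,
        b=cases.het + cases.hom_other,
        c=controls.hom_risk,
        d=controls.het + controls.hom_other,
        unit=PERSON_UNIT,
    )


MODEL_TABLES = {
    "allele": allele_table,
    "dominant": dominant_table,
    "recessive": recessive_table,
}


def model_table(model: str, cases: GenotypeCounts, controls: GenotypeCounts) -> ContingencyTable:
    """Dispatch to the table builder for ``model`` (allele/dominant/recessive)."""
    try:
        builder = MODEL_TABLES[model]
    except KeyError:
        raise ValueError(f"unknown genetic model {model!r}") from None
    return builder(cases, controls)


def allele_frequency(counts: GenotypeCounts) -> float:
    """Risk-allele frequency (2*hom_risk + het) / (2*total)."""
    return counts.risk_alleles / (2 * counts.total)


def hwe_chi_square(counts: GenotypeCounts) -> tuple[float, float]:
    """Hardy-Weinberg chi-square goodness-of-fit (1 df) for one arm.

    Offered as a diagnostic only; it is never used as an exclusion filter.
    Returns ``(statistic, p_value)``.  Degenerate arms (frequency 0 or 1)
    return ``(0.0, 1.0)``.
    """
    n = counts.total
    q = allele_frequency(counts)
    if q == 0.0 or q == 1.0:
        return 0.0, 1.0
    expected = (n * q * q, 2 * n * q * (1 - q), n * (1 - q) * (1 - q))
    observed = (counts.hom_risk, counts.het, counts.hom_other)
    statistic = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    return statistic, float(stats.chi2.sf(statistic, df=1))
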