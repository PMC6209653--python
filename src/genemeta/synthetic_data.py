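"""Synthetic multi-study case-control genotype data with known ground truth.

Controls are drawn multinomially from Hardy-Weinberg proportions at a
configurable risk-allele frequency (optionally per ethnicity).  Case
genotype probabilities are the control proportions tilted by genotype odds
(multiplicative: psi^2, psi, 1; dominant: psi, psi, 1; recessive:
psi, 1, 1) and renormalized — a logistic disease model on genotype odds
with no rare-disease approximation.  Optional between-study spread adds
Normal(0, sd) noise to each study's log odds ratio.

Randomness: one master seed; study ``i`` always uses the substream
``default_rng([seed, i])``, so a dataset is reproducible study-by-study
regardless of generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .data_model_io import ETHNICITIES, StudyRecord
from .genetic_models import GenotypeCounts, allele_table
from .meta_engine import pool

__all__ = [
    "SimulationConfig",
    "simulate_study",
    "simulate_dataset",
    "null_calibration",
    "DEFAULT_ETHNICITY_WEIGHTS",
]

INHERITANCE_MODES = ("multiplicative", "dominant", "recessive")

#: Default ethnicity mix, mirroring a 36-study roster with 20 East Asian,
#: 13 European and one study each from the remaining groups.
DEFAULT_ETHNICITY_WEIGHTS: dict[str, float] = {
    "East Asian": 20 / 36,
    "European": 13 / 36,
    "Latino": 1 / 36,
    "Mixed": 1 / 36,
    "West Asian": 1 / 36,
}

_COUNTRY_BY_ETHNICITY = {
    "East Asian": "China",
    "European": "Multi-country",
    "Latino": "Brazil",
    "West Asian": "Iran",
    "Mixed": "America",
}


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters for one simulated variant's study base."""

    variant_id: str = "rs0000001"
    true_or: float = 1.0
    inheritance: str = "multiplicative"
    control_af: Union[float, Mapping[str, float]] = 0.30
    k_studies: int = 10
    n_cases_range: tuple[int, int] = (100, 5000)
    n_controls_range: tuple[int, int] = (100, 5000)
    ethnicity_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ETHNICITY_WEIGHTS)
    )
    between_study_sd: float = 0.0
    seed: int = 0
    risk_allele: str = "A"
    other_allele: str = "G"

    def __post_init__(self) -> None:
        if self.true_or <= 0:
            raise ValueError("true_or must be positive")
        if self.inheritance not in INHERITANCE_MODES:
            raise ValueError(f"unknown inheritance mode {self.inheritance!r}")
        if self.k_studies < 1:
            raise ValueError("k_studies must be >= 1")
        for name in ("n_cases_range", "n_controls_range"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} must be a positive interval")
        if self.between_study_sd < 0:
            raise ValueError("between_study_sd must be non-negative")
        weights = dict(self.ethnicity_weights)
        if abs(sum(weights.values()) - 1.0) > 1e-9:
            raise ValueError("ethnicity_weights must sum to 1")
        for ethnicity in weights:
            if ethnicity not in ETHNICITIES:
                raise ValueError(f"unknown ethnicity {ethnicity!r}")
        if isinstance(self.control_af, Mapping):
            for q in self.control_af.values():
                _check_af(q)
        else:
            _check_af(self.control_af)


def _check_af(q: float) -> None:
    if not (0.0 < q < 1.0):
        raise ValueError(f"control allele frequency must lie strictly in (0, 1), got {q}")


def genotype_odds(psi: float, inheritance: str) -> tuple[float, float, float]:
    """Disease odds multipliers for (hom_risk, het, hom_other) genotypes."""
    if inheritance == "multiplicative":
        return (psi * psi, psi, 1.0)
    if inheritance == "dominant":
        return (psi, psi, 1.0)
    if inheritance == "recessive":
        return (psi, 1.0, 1.0)
    raise ValueError(f"unknown inheritance mode {inheritance!r}")


def case_probabilities(q: float, psi: float, inheritance: str) -> np.ndarray:
    """Case genotype probabilities: HWE control proportions x genotype odds."""
    control = np.array([q * q, 2 * q * (1 - q), (1 - q) * (1 - q)])
    tilted = control * np.array(genotype_odds(psi, inheritance))
    return tilted / tilted.sum()


def study_rng(seed: int, study_index: int) -> np.random.Generator:
    """The per-study substream: counter-keyed on (master seed, study index)."""
    return np.random.default_rng([seed, study_index])


def _draw_sizes(rng: np.random.Generator, config: SimulationConfig) -> tuple[int, int]:
    n_cases = int(rng.integers(config.n_cases_range[0], config.n_cases_range[1] + 1))
    n_controls = int(rng.integers(config.n_controls_range[0], config.n_controls_range[1] + 1))
    return n_cases, n_controls


def _simulate_study_full(
    config: SimulationConfig,
    study_index: int,
    rng: Optional[np.random.Generator] = None,
) -> tuple[StudyRecord, dict]:
    if rng is None:
        rng = study_rng(config.seed, study_index)

    ethnicities = sorted(config.ethnicity_weights)
    weights = np.array([config.ethnicity_weights[e] for e in ethnicities])
    ethnicity = str(rng.choice(ethnicities, p=weights))

    if isinstance(config.control_af, Mapping):
        try:
            q = float(config.control_af[ethnicity])
        except KeyError:
            raise ValueError(f"no control allele frequency configured for {ethnicity!r}") from None
    else:
        q = float(config.control_af)
    _check_af(q)

    n_cases, n_controls = _draw_sizes(rng, config)
    log_psi = math.log(config.true_or)
    if config.between_study_sd > 0:
        log_psi += rng.normal(0.0, config.between_study_sd)
    psi = math.exp(log_psi)

    control_p = np.array([q * q, 2 * q * (1 - q), (1 - q) * (1 - q)])
    case_p = case_probabilities(q, psi, config.inheritance)
    ctrl = rng.multinomial(n_controls, control_p)
    case = rng.multinomial(n_cases, case_p)

    record = StudyRecord(
        study_id=f"sim{study_index:04d}",
        author_year=f"{2000 + study_index % 20}Sim{study_index:04d}",
        ethnicity=ethnicity,
        country=_COUNTRY_BY_ETHNICITY[ethnicity],
        nos_score=7,
        variant_id=config.variant_id,
        risk_allele=config.risk_allele,
        other_allele=config.other_allele,
        case_counts=GenotypeCounts(int(case[0]), int(case[1]), int(case[2])),
        control_counts=GenotypeCounts(int(ctrl[0]), int(ctrl[1]), int(ctrl[2])),
    )
    truth = {
        "study_id": record.study_id,
        "psi": psi,
        "control_af": q,
        "ethnicity": ethnicity,
        "n_cases": n_cases,
        "n_controls": n_controls,
    }
    return record, truth


def simulate_study(
    config: SimulationConfig,
    study_index: int,
    rng: Optional[np.random.Generator] = None,
) -> StudyRecord:
    """Simulate one study; deterministic given (config.seed, study_index)."""
    record, _ = _simulate_study_full(config, study_index, rng)
    return record


def simulate_dataset(config: SimulationConfig) -> tuple[list[StudyRecord], dict]:
    """Simulate the configured number of studies plus a ground-truth manifest."""
    records: list[StudyRecord] = []
    truths: list[dict] = []
    for i in range(config.k_studies):
        record, truth = _simulate_study_full(config, i)
        records.append(record)
        truths.append(truth)
    manifest = {
        "variant_id": config.variant_id,
        "true_or": config.true_or,
        "inheritance": config.inheritance,
        "between_study_sd": config.between_study_sd,
        "seed": config.seed,
        "k_studies": config.k_studies,
        "studies": truths,
    }
    return records, manifest


def null_calibration(
    config: SimulationConfig, replicates: int = 2000, alpha: float = 0.05
) -> float:
    """Fraction of null (psi = 1) replicates with allele-model pooled p < alpha."""
    if config.true_or != 1.0:
        config = replace(config, true_or=1.0)
    rejections = 0
    for rep in range(replicates):
        tables = []
        for i in range(config.k_studies):
            rng = np.random.default_rng([config.seed, rep, i])
            record = simulate_study(config, i, rng=rng)
            tables.append(allele_table(record.case_counts, record.control_counts))
        result = pool(tables, variant_id=config.variant_id)
        if result.p < alpha:
            rejections += 1
    return rejections / replicates
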