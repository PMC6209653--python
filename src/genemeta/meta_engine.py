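"""Per-study effect estimation and fixed/random-effects pooling.

Estimators follow the RevMan conventions for dichotomous outcomes:
Mantel-Haenszel pooling with the Robins-Breslow-Greenland variance for the
fixed-effects model, and DerSimonian-Laird inverse-variance pooling for the
random-effects model.  The fixed/random choice is driven by Cochran's Q and
I-squared: fixed iff p(Q) > 0.1 or I2 <= 50%, random otherwise.

A +0.5 continuity correction is applied to every cell of any table with a
zero cell, per study, both for per-study effects and for the MH sums.
Tables that are non-informative (both exposed cells zero, or both
unexposed cells zero) are excluded rather than corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy import stats

from .genetic_models import ContingencyTable

__all__ = [
    "FIXED_MH",
    "RANDOM_DL",
    "EffectEstimate",
    "HeterogeneityStats",
    "PooledResult",
    "study_effect",
    "is_informative",
    "effects_from_tables",
    "heterogeneity",
    "select_method",
    "wald_p",
    "pool_fixed_mh",
    "pool_random_dl",
    "pool",
]

FIXED_MH = "fixed_MH"
RANDOM_DL = "random_DL"

#: Normal quantile for two-sided 95% intervals (RevMan convention, not t).
Z_95 = 1.959963984540054


class PoolingError(ValueError):
    """Raised when pooling is requested on empty or all-non-informative input."""


@dataclass(frozen=True)
class EffectEstimate:
    """One study's log odds ratio with its Woolf standard error."""

    study_id: str
    log_or: float
    se: float
    corrected: bool = False

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("standard error must be positive")

    @property
    def or_value(self) -> float:
        return math.exp(self.log_or)

    @property
    def weight(self) -> float:
        """Inverse-variance weight 1/se^2."""
        return 1.0 / (self.se * self.se)


@dataclass(frozen=True)
class HeterogeneityStats:
    q: float
    df: int
    p_q: float
    i_squared: float
    tau_squared: float


@dataclass(frozen=True)
class PooledResult:
    """Pooled OR/CI/p plus heterogeneity for one variant x group x model."""

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

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.pooled_or <= self.ci_high):
            raise ValueError("confidence interval must bracket the pooled OR")
        if not (0.0 <= self.i_squared <= 100.0):
            raise ValueError("I2 must lie in [0, 100]")
        if self.tau_squared < 0:
            raise ValueError("tau2 must be non-negative")
        if self.method == FIXED_MH and self.tau_squared != 0.0:
            raise ValueError("fixed-effects results carry tau2 = 0")

    @property
    def log_or(self) -> float:
        return math.log(self.pooled_or)


def is_informative(table: ContingencyTable) -> bool:
    """False when both exposed cells or both unexposed cells are zero."""
    return not ((table.a == 0 and table.c == 0) or (table.b == 0 and table.d == 0))


def _maybe_correct(table: ContingencyTable) -> ContingencyTable:
    return table.with_correction() if table.has_zero_cell else table


def study_effect(
    table: ContingencyTable, study_id: str = "", correction: bool = True
) -> Optional[EffectEstimate]:
    """Woolf log-OR and SE for one study; ``None`` for non-informative tables.

    OR = ad/bc, se = sqrt(1/a + 1/b + 1/c + 1/d).  Zero cells trigger a
    +0.5 correction of all four cells when ``correction`` is enabled.
    """
    if not is_informative(table):
        return None
    if table.has_zero_cell:
        if not correction:
            return None
        table = table.with_correction()
    log_or = math.log(table.a * table.d / (table.b * table.c))
    se = math.sqrt(1 / table.a + 1 / table.b + 1 / table.c + 1 / table.d)
    return EffectEstimate(study_id=study_id, log_or=log_or, se=se, corrected=table.corrected)


def effects_from_tables(
    tables: Sequence[ContingencyTable], study_ids: Optional[Sequence[str]] = None
) -> list[EffectEstimate]:
    """Per-study effects for the informative tables, in input order."""
    if study_ids is None:
        study_ids = [f"study{i}" for i in range(len(tables))]
    effects = []
    for table, sid in zip(tables, study_ids):
        effect = study_effect(table, study_id=sid)
        if effect is not None:
            effects.append(effect)
    return effects


def wald_p(log_or: float, se: float) -> tuple[float, float]:
    """Two-sided Wald test of log OR = 0: returns ``(z, p)``."""
    z = log_or / se
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return z, p


def heterogeneity(effects: Sequence[EffectEstimate]) -> HeterogeneityStats:
    """Cochran's Q, I2 and the DerSimonian-Laird tau2 from IV fixed weights.

    I2 = max(0, (Q - df)/Q) * 100, floored at zero and defined as 0 for a
    single study.  tau2 = max(0, (Q - df)/C) with C = sum(w) - sum(w^2)/sum(w).
    """
    if not effects:
        raise PoolingError("heterogeneity requires at least one effect")
    k = len(effects)
    df = k - 1
    if k == 1:
        return HeterogeneityStats(q=0.0, df=0, p_q=1.0, i_squared=0.0, tau_squared=0.0)
    weights = [e.weight for e in effects]
    w_sum = sum(weights)
    y_bar = sum(w * e.log_or for w, e in zip(weights, effects)) / w_sum
    q = sum(w * (e.log_or - y_bar) ** 2 for w, e in zip(weights, effects))
    p_q = float(stats.chi2.sf(q, df=df))
    i_squared = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    c = w_sum - sum(w * w for w in weights) / w_sum
    tau_squared = max(0.0, (q - df) / c) if c > 0 else 0.0
    return HeterogeneityStats(q=q, df=df, p_q=p_q, i_squared=i_squared, tau_squared=tau_squared)


def select_method(p_q: float, i_squared: float) -> str:
    """Fixed effects iff p(Q) > 0.1 or I2 <= 50%; random effects otherwise."""
    if p_q > 0.1 or i_squared <= 50.0:
        return FIXED_MH
    return RANDOM_DL


def _result(
    *,
    variant_id: str,
    group: str,
    genetic_model: str,
    method: str,
    k: int,
    log_or: float,
    se: float,
    het: HeterogeneityStats,
    tau_squared: float,
) -> PooledResult:
    z, p = wald_p(log_or, se)
    return PooledResult(
        variant_id=variant_id,
        group=group,
        genetic_model=genetic_model,
        method=method,
        k=k,
        pooled_or=math.exp(log_or),
        ci_low=math.exp(log_or - Z_95 * se),
        ci_high=math.exp(log_or + Z_95 * se),
        z=z,
        p=p,
        q=het.q,
        df=het.df,
        p_q=het.p_q,
        i_squared=het.i_squared,
        tau_squared=tau_squared,
    )


def pool_fixed_mh(
    tables: Sequence[ContingencyTable],
    *,
    variant_id: str = "",
    group: str = "overall",
    genetic_model: str = "allele",
    study_ids: Optional[Sequence[str]] = None,
) -> PooledResult:
    """Mantel-Haenszel fixed-effects pooled OR with the RBG variance.

    pooled OR = sum(a_i d_i / n_i) / sum(b_i c_i / n_i); variance of the
    log pooled OR by Robins-Breslow-Greenland.  Per-study zero cells are
    continuity-corrected before entering the sums.
    """
    informative = [t for t in tables if is_informative(t)]
    if not informative:
        raise PoolingError("no informative tables to pool")
    corrected = [_maybe_correct(t) for t in informative]

    r_sum = s_sum = 0.0
    term1 = term2 = term3 = 0.0
    for t in corrected:
        n = t.total
        r_i = t.a * t.d / n
        s_i = t.b * t.c / n
        p_i = (t.a + t.d) / n
        q_i = (t.b + t.c) / n
        r_sum += r_i
        s_sum += s_i
        term1 += p_i * r_i
        term2 += p_i * s_i + q_i * r_i
        term3 += q_i * s_i
    log_or = math.log(r_sum / s_sum)
    var = (
        term1 / (2 * r_sum * r_sum)
        + term2 / (2 * r_sum * s_sum)
        + term3 / (2 * s_sum * s_sum)
    )
    se = math.sqrt(var)

    if study_ids is not None:
        study_ids = [sid for sid, t in zip(study_ids, tables) if is_informative(t)]
    het = heterogeneity(effects_from_tables(informative, study_ids))
    return _result(
        variant_id=variant_id,
        group=group,
        genetic_model=genetic_model,
        method=FIXED_MH,
        k=len(informative),
        log_or=log_or,
        se=se,
        het=het,
        tau_squared=0.0,
    )


def pool_random_dl(
    effects: Sequence[EffectEstimate],
    *,
    variant_id: str = "",
    group: str = "overall",
    genetic_model: str = "allele",
) -> PooledResult:
    """DerSimonian-Laird random-effects pooling of per-study log ORs.

    Weights are re-computed as 1/(se_i^2 + tau2); a single effect pools to
    itself with tau2 = 0.
    """
    if not effects:
        raise PoolingError("no effects to pool")
    het = heterogeneity(effects)
    tau2 = het.tau_squared
    weights = [1.0 / (e.se * e.se + tau2) for e in effects]
    w_sum = sum(weights)
    log_or = sum(w * e.log_or for w, e in zip(weights, effects)) / w_sum
    se = 1.0 / math.sqrt(w_sum)
    return _result(
        variant_id=variant_id,
        group=group,
        genetic_model=genetic_model,
        method=RANDOM_DL,
        k=len(effects),
        log_or=log_or,
        se=se,
        het=het,
        tau_squared=tau2,
    )


def pool(
    tables: Sequence[ContingencyTable],
    *,
    variant_id: str = "",
    group: str = "overall",
    genetic_model: str = "allele",
    study_ids: Optional[Sequence[str]] = None,
    method: Optional[str] = None,
) -> PooledResult:
    """Pool tables, choosing fixed vs random by the Q/I2 rule unless forced."""
    informative = [t for t in tables if is_informative(t)]
    if not informative:
        raise PoolingError("no informative tables to pool")
    ids = None
    if study_ids is not None:
        ids = [sid for sid, t in zip(study_ids, tables) if is_informative(t)]
    effects = effects_from_tables(informative, ids)
    if method is None:
        het = heterogeneity(effects)
        method = select_method(het.p_q, het.i_squared)
    if method == FIXED_MH:
        return pool_fixed_mh(
            informative,
            variant_id=variant_id,
            group=group,
            genetic_model=genetic_model,
            study_ids=ids,
        )
    if method == RANDOM_DL:
        return pool_random_dl(
            effects, variant_id=variant_id, group=group, genetic_model=genetic_model
        )
    raise ValueError(f"unknown pooling method {method!r}")
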