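"""Bundled example data for demonstrations, regression tests and acceptance runs.

Two pieces ship with the package:

* a 36-study case-control roster (author-year label, ethnicity, country,
  arm sizes, quality score) from a published SNCA/Parkinson's-disease
  meta-analysis study base — metadata only, since per-study genotype
  counts were never deposited; :func:`example_roster_records` fills in
  synthetic counts at the published arm sizes;
* the published overall-population allele-model pooled estimates for the
  16 variants analysed there (OR, 95% CI, p, pooled allele frequencies),
  encoded as :class:`~genemeta.meta_engine.PooledResult` objects by
  :func:`published_overall_results`.

Published p-values printed as a floor ("<0.00001") are represented by half
the floor — any stand-in strictly below the floor classifies identically
under the strict-threshold rules.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .data_model_io import StudyRecord, write_records_tsv
from .genetic_models import GenotypeCounts
from .meta_engine import FIXED_MH, PooledResult, wald_p
from .synthetic_data import case_probabilities

__all__ = [
    "EXAMPLE_ROSTER",
    "PUBLISHED_OVERALL_ESTIMATES",
    "ETHNICITY_CONTROL_AF",
    "example_roster_records",
    "write_example_roster_tsv",
    "published_overall_results",
]

# (author_year, ethnicity, country, n_cases, n_controls, nos_score)
EXAMPLE_ROSTER: list[tuple[str, str, str, int, int, int]] = [
    ("2006Mizuta I", "East Asian", "Japan", 882, 938, 7),
    ("2008Mizuta I", "East Asian", "Japan", 1403, 1941, 8),
    ("2010Chang XL", "East Asian", "China", 636, 510, 9),
    ("2010Hu FY", "East Asian", "China", 330, 300, 7),
    ("2010Yu L", "East Asian", "China", 332, 300, 8),
    ("2012Gan R", "East Asian", "China", 189, 189, 6),
    ("2012Hu Y", "East Asian", "China", 110, 136, 7),
    ("2012Li NN", "East Asian", "China", 685, 569, 7),
    ("2012Miyake Y", "East Asian", "Japan", 229, 357, 8),
    ("2012Pan F", "East Asian", "China", 403, 315, 7),
    ("2013Liu B", "East Asian", "China", 116, 95, 6),
    ("2013Liu J", "East Asian", "China", 989, 748, 7),
    ("2013Pan F", "East Asian", "China", 515, 450, 8),
    ("2013Wu-Chou YH", "East Asian", "China", 633, 473, 8),
    ("2014Guo XY", "East Asian", "China", 1011, 721, 7),
    ("2015Chen YP", "East Asian", "China", 1276, 846, 7),
    ("2015Guo JF", "East Asian", "China", 1061, 1066, 8),
    ("2015Wu GP", "East Asian", "China", 120, 100, 6),
    ("2016Fang J", "East Asian", "China", 583, 553, 8),
    ("2017Chen WJ", "East Asian", "China", 210, 251, 7),
    ("2007Goris A", "European", "UK", 659, 2176, 7),
    ("2007Parsian AJ", "European", "America", 521, 215, 8),
    ("2007Ross OA", "European", "Ireland", 186, 186, 9),
    ("2007Winkler S", "European", "Germany", 397, 270, 7),
    ("2008Myhre R", "European", "Norway", 236, 236, 8),
    ("2008Westerlund M", "European", "Sweden", 290, 313, 9),
    ("2009Chung SJ", "European", "America", 1103, 1103, 7),
    ("2009Pankratz N", "European", "America", 445, 335, 7),
    ("2010Mata IF", "European", "America", 685, 673, 8),
    ("2011Elbaz A", "European", "Multi-country", 5302, 4161, 7),
    ("2012Cardo LF", "European", "Spain", 1135, 772, 6),
    ("2012Trotta L", "European", "Italy", 904, 891, 6),
    ("2013Emelyanov A", "European", "Russia", 224, 308, 7),
    ("2017Campêlo CL", "Latino", "Brazil", 104, 98, 7),
    ("2014Lee PC", "Mixed", "America", 533, 700, 8),
    ("2016Shahmohammadibeni N", "West Asian", "Iran", 520, 520, 7),
]

# Published overall-population allele-model summaries, one per variant:
# (variant_id, risk_allele, other_allele, or, ci_low, ci_high, p, p_is_floor,
#  af_cases, af_controls)
PUBLISHED_OVERALL_ESTIMATES: list[tuple] = [
    ("rs181489", "T", "C", 1.28, 1.17, 1.40, 1e-5, True, 0.3486, 0.2974),
    ("rs356165", "G", "A", 1.25, 1.15, 1.37, 1e-5, True, 0.5117, 0.4631),
    ("rs356186", "A", "G", 0.77, 0.70, 0.86, 1e-5, True, 0.1629, 0.2008),
    ("rs356219", "G", "A", 1.30, 1.23, 1.38, 1e-5, True, 0.4723, 0.4038),
    ("rs356220", "T", "C", 1.23, 1.14, 1.33, 1e-5, True, 0.4865, 0.4363),
    ("rs356221", "A", "T", 1.15, 0.94, 1.40, 0.16, False, 0.6257, 0.5963),
    ("rs894278", "G", "T", 1.13, 0.87, 1.46, 0.37, False, 0.3926, 0.3626),
    ("rs2301134", "A", "G", 1.00, 0.74, 1.34, 0.97, False, 0.2559, 0.2454),
    ("rs2301135", "G", "C", 1.24, 0.87, 1.76, 0.23, False, 0.3559, 0.3581),
    ("rs2583988", "T", "C", 1.21, 1.08, 1.35, 0.001, False, 0.2981, 0.2648),
    ("rs2619363", "T", "G", 1.13, 1.02, 1.24, 0.01, False, 0.3051, 0.2802),
    ("rs2619364", "G", "A", 1.24, 1.11, 1.40, 0.0003, False, 0.302, 0.2587),
    ("rs2736990", "G", "A", 1.22, 1.13, 1.31, 1e-5, True, 0.6092, 0.5602),
    ("rs2737029", "G", "A", 1.38, 1.20, 1.59, 1e-5, True, 0.5205, 0.4478),
    ("rs7684318", "C", "T", 1.53, 1.22, 1.91, 0.0003, False, 0.5913, 0.5229),
    ("rs11931074", "T", "G", 1.36, 1.29, 1.44, 1e-5, True, 0.2825, 0.2501),
]

#: Published control-arm risk-allele frequencies by ethnicity for selected
#: variants, used as defaults when simulating ethnicity-contrasted data.
ETHNICITY_CONTROL_AF: dict[str, dict[str, float]] = {
    "rs11931074": {
        "East Asian": 0.5297,
        "European": 0.069,
        "Latino": 0.2296,
        "West Asian": 0.2404,
        "Mixed": 0.076,
    },
    "rs2736990": {
        "East Asian": 0.6191,
        "European": 0.47,
        "Latino": 0.5255,
        "West Asian": 0.5255,
        "Mixed": 0.5255,
    },
    "rs356219": {
        "East Asian": 0.555,
        "European": 0.3776,
        "Latino": 0.4745,
        "West Asian": 0.4745,
        "Mixed": 0.3483,
    },
    "rs356165": {
        "East Asian": 0.5489,
        "European": 0.3399,
        "Latino": 0.3979,
        "West Asian": 0.3979,
        "Mixed": 0.3979,
    },
}


def example_roster_records(
    seed: int = 0,
    variant_id: str = "rs11931074",
    risk_allele: str = "T",
    other_allele: str = "G",
    true_or: float = 1.36,
    mark_superseded: bool = False,
) -> list[StudyRecord]:
    """The 36-study roster with synthetic genotype counts at the listed arm sizes.

    Counts are drawn from HWE controls at the ethnicity-specific published
    control frequency for ``variant_id`` (0.3 where none is recorded) with
    the case distribution tilted multiplicatively by ``true_or``.  With
    ``mark_superseded`` the overlapping 2006/2008 Japanese cohorts are
    linked via ``superseded_by``.
    """
    af_map = ETHNICITY_CONTROL_AF.get(variant_id, {})
    records: list[StudyRecord] = []
    superseder = {"2006Mizuta I": "s02"} if mark_superseded else {}
    for i, (author_year, ethnicity, country, n_cases, n_controls, nos) in enumerate(
        EXAMPLE_ROSTER
    ):
        rng = np.random.default_rng([seed, i])
        q = af_map.get(ethnicity, 0.30)
        control_p = np.array([q * q, 2 * q * (1 - q), (1 - q) * (1 - q)])
        case_p = case_probabilities(q, true_or, "multiplicative")
        ctrl = rng.multinomial(n_controls, control_p)
        case = rng.multinomial(n_cases, case_p)
        records.append(
            StudyRecord(
                study_id=f"s{i + 1:02d}",
                author_year=author_year,
                ethnicity=ethnicity,
                country=country,
                nos_score=nos,
                variant_id=variant_id,
                risk_allele=risk_allele,
                other_allele=other_allele,
                case_counts=GenotypeCounts(int(case[0]), int(case[1]), int(case[2])),
                control_counts=GenotypeCounts(int(ctrl[0]), int(ctrl[1]), int(ctrl[2])),
                superseded_by=superseder.get(author_year),
            )
        )
    return records


def write_example_roster_tsv(
    path: str | Path, seed: int = 0, **kwargs
) -> list[StudyRecord]:
    """Write the example roster (with synthetic counts) in the input TSV schema."""
    records = example_roster_records(seed=seed, **kwargs)
    write_records_tsv(records, path)
    return records


def _estimate_to_result(entry: tuple, group: str = "overall") -> PooledResult:
    variant_id, _risk, _other, or_, ci_low, ci_high, p, is_floor, _afp, _afc = entry
    p_raw = p / 2.0 if is_floor else p
    # reconstruct z/se from the printed CI so the object is self-consistent
    log_or = math.log(or_)
    se = (math.log(ci_high) - math.log(ci_low)) / (2 * 1.959963984540054)
    z, _ = wald_p(log_or, se)
    return PooledResult(
        variant_id=variant_id,
        group=group,
        genetic_model="allele",
        method=FIXED_MH,
        k=4,
        pooled_or=or_,
        ci_low=ci_low,
        ci_high=ci_high,
        z=z,
        p=p_raw,
        q=0.0,
        df=3,
        p_q=1.0,
        i_squared=0.0,
        tau_squared=0.0,
    )


def published_overall_results(group: str = "overall") -> list[PooledResult]:
    """The 16 published overall allele-model estimates as PooledResult objects."""
    return [_estimate_to_result(entry, group=group) for entry in PUBLISHED_OVERALL_ESTIMATES]
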