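"""Disease burden: DALY tables, the relative-burden ratio and the disease typology.

A disease's *relative burden per capita* is the ratio of its DALY rate in
low- and middle-income countries (UMIC + LoMIC + LIC pooled: pooled DALYs
over pooled population) to its DALY rate in high-income countries.  The
ratio bins diseases into five types:

=====  ===================  ==============================
type   ratio range          reading
=====  ===================  ==============================
1a     r < 0.75             more burden in HICs
1b     0.75 <= r < 1.25     equal burden
1c     1.25 <= r < 3.00     a bit more burden in LMICs
2      3.00 <= r < 35.0     more burden in LMICs
3      r >= 35.0            quasi-exclusive of LMICs
=====  ===================  ==============================

Lower bounds are inclusive, upper bounds exclusive; a disease with zero
HIC burden but positive LMIC burden has ratio +inf and is type 3.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from functools import total_ordering
from typing import Iterable, Mapping, TextIO

import pandas as pd

from .errors import RowValidationError, SchemaError, UndefinedRatioError, UndefinedShareError
from .registry import IncomeGroup, LMIC_GROUPS

logger = logging.getLogger(__name__)

__all__ = [
    "DiseaseType",
    "TypeThresholds",
    "BurdenTable",
    "load_burden_table",
    "relative_burden_ratio",
    "classify_disease_type",
    "classify_registry",
    "burden_shares",
]


@total_ordering
class DiseaseType(Enum):
    """Five-level typology ordered from HIC-dominated to LMIC-exclusive burden."""

    T1a = "1a"
    T1b = "1b"
    T1c = "1c"
    T2 = "2"
    T3 = "3"

    @property
    def _rank(self) -> int:
        return list(DiseaseType).index(self)

    def __lt__(self, other: "DiseaseType") -> bool:
        if not isinstance(other, DiseaseType):
            return NotImplemented
        return self._rank < other._rank


@dataclass(frozen=True)
class TypeThresholds:
    """Cut-points of the burden-ratio bins; strictly increasing."""

    cut_1a_1b: float = 0.75
    cut_1b_1c: float = 1.25
    cut_1c_2: float = 3.00
    cut_2_3: float = 35.0

    def __post_init__(self) -> None:
        cuts = (self.cut_1a_1b, self.cut_1b_1c, self.cut_1c_2, self.cut_2_3)
        if not all(a < b for a, b in zip(cuts, cuts[1:])):
            raise ValueError(f"thresholds must be strictly increasing, got {cuts}")


@dataclass
class BurdenTable:
    """DALYs per (cause, income group) plus group populations, for one year.

    A cause missing a group is treated as zero DALYs there (logged once at
    load time); populations must be positive.
    """

    year: int
    dalys: dict[tuple[str, IncomeGroup], float] = field(default_factory=dict)
    population: dict[IncomeGroup, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (cause, group), v in self.dalys.items():
            if v < 0:
                raise RowValidationError(
                    f"negative DALYs for ({cause}, {group.value}): {v}"
                )
        for group, pop in self.population.items():
            if pop <= 0:
                raise RowValidationError(
                    f"non-positive population for {group.value}: {pop}"
                )

    @property
    def cause_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for cause, _ in self.dalys:
            seen.setdefault(cause)
        return list(seen)

    def daly(self, cause_id: str, group: IncomeGroup) -> float:
        return self.dalys.get((cause_id, group), 0.0)

    def total_dalys(self, cause_id: str) -> float:
        return sum(self.daly(cause_id, g) for g in IncomeGroup)


def load_burden_table(
    burden_source: TextIO | str, population_source: TextIO | str
) -> BurdenTable:
    """Load the DALY table and population table from CSV.

    Burden CSV columns: ``cause_id, income_group, dalys``; population CSV
    columns: ``income_group, population, year``.
    """
    burden = pd.read_csv(burden_source)
    pop = pd.read_csv(population_source)
    for df, cols, what in (
        (burden, {"cause_id", "income_group", "dalys"}, "burden table"),
        (pop, {"income_group", "population", "year"}, "population table"),
    ):
        missing = cols - set(df.columns)
        if missing:
            raise SchemaError(f"{what}: missing column(s) {sorted(missing)}")
    dalys = {
        (str(r.cause_id), IncomeGroup(r.income_group)): float(r.dalys)
        for r in burden.itertuples()
    }
    population = {
        IncomeGroup(r.income_group): float(r.population) for r in pop.itertuples()
    }
    year = int(pop["year"].iloc[0]) if len(pop) else 0
    table = BurdenTable(year=year, dalys=dalys, population=population)
    # warn once per cause missing a group (treated as zero)
    for cause in table.cause_ids:
        missing_groups = [g.value for g in IncomeGroup if (cause, g) not in dalys]
        if missing_groups:
            logger.warning(
                "cause %s has no DALY entry for %s; treating as 0",
                cause,
                missing_groups,
            )
    return table


def relative_burden_ratio(cause_id: str, table: BurdenTable) -> float:
    """LMIC-over-HIC burden-per-capita ratio for one cause.

    LMIC pools UMIC+LoMIC+LIC DALYs and populations before dividing
    (a single pooled rate, not an average of group rates).  Returns +inf
    when the HIC rate is zero but the LMIC rate positive; raises
    :class:`UndefinedRatioError` when both rates are zero.
    """
    lmic_dalys = sum(table.daly(cause_id, g) for g in LMIC_GROUPS)
    lmic_pop = sum(table.population[g] for g in LMIC_GROUPS)
    hic_rate = table.daly(cause_id, IncomeGroup.HIC) / table.population[IncomeGroup.HIC]
    lmic_rate = lmic_dalys / lmic_pop
    if hic_rate == 0.0:
        if lmic_rate == 0.0:
            raise UndefinedRatioError(
                f"cause {cause_id!r} has zero burden in both HICs and LMICs"
            )
        return math.inf
    return lmic_rate / hic_rate


def classify_disease_type(
    ratio: float, thresholds: TypeThresholds | None = None
) -> DiseaseType:
    """Bin a relative-burden ratio into the five-type disease typology.

    Lower bounds inclusive, upper bounds exclusive; +inf is type 3.
    Negative ratios are a domain error.
    """
    if thresholds is None:
        thresholds = TypeThresholds()
    if math.isnan(ratio) or ratio < 0:
        raise ValueError(f"ratio must be non-negative or +inf, got {ratio}")
    if ratio < thresholds.cut_1a_1b:
        return DiseaseType.T1a
    if ratio < thresholds.cut_1b_1c:
        return DiseaseType.T1b
    if ratio < thresholds.cut_1c_2:
        return DiseaseType.T1c
    if ratio < thresholds.cut_2_3:
        return DiseaseType.T2
    return DiseaseType.T3


def classify_registry(
    table: BurdenTable,
    thresholds: TypeThresholds | None = None,
    cause_ids: Iterable[str] | None = None,
) -> dict[str, DiseaseType]:
    """Type every cause in the table (or the given subset).

    Causes with zero burden everywhere are excluded with a warning rather
    than silently typed.
    """
    out: dict[str, DiseaseType] = {}
    for cause in cause_ids if cause_ids is not None else table.cause_ids:
        try:
            ratio = relative_burden_ratio(cause, table)
        except UndefinedRatioError:
            logger.warning(
                "cause %s has zero burden everywhere; excluded from typing", cause
            )
            continue
        out[cause] = classify_disease_type(ratio, thresholds)
    return out


def burden_shares(
    table: BurdenTable,
    partition: Mapping[str, object],
    scope: IncomeGroup | None = None,
) -> dict[object, float]:
    """Share of DALYs per partition key, over the world or one income group.

    ``partition`` maps cause_id → key (e.g. its disease type); causes absent
    from the partition are outside the scope.  Shares sum to 1.
    """
    groups = [scope] if scope is not None else list(IncomeGroup)
    totals: dict[object, float] = {}
    grand_total = 0.0
    for cause, key in partition.items():
        v = sum(table.daly(cause, g) for g in groups)
        totals[key] = totals.get(key, 0.0) + v
        grand_total += v
    if grand_total == 0.0:
        raise UndefinedShareError(
            f"zero total DALYs in scope {scope.value if scope else 'world'}"
        )
    return {k: v / grand_total for k, v in totals.items()}
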