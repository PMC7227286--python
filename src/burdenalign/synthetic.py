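"""Synthetic worlds and publication corpora with recorded ground truth.

The generator builds a self-consistent miniature of the study setting —
income groups with countries and populations, a disease registry whose
burden ratios land in prescribed typology bins, a journal table with
impact factors, and a publication corpus sampled from configurable
group-level publishing behaviour — so that every pipeline stage can be
exercised and its estimates compared against known expectations.

Default parameters mirror the broad empirical picture the pipeline is
meant to detect: output concentrated in high-income countries (~80%), a
publication mix skewed towards diseases with more burden per capita in
HICs, international collaboration around 20% of publications for HICs and
MICs but ~75% for LICs, and a citation premium for HIC-burden diseases
with a penalty for LMIC-exclusive ones.  The corpus ground truth carries
the *analytical expectations* of the fractional-counting estimates (cell
shares, collaboration rates, normalised-citation effects), so recovery
tests can compare estimates to expectations at any corpus size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .burden import BurdenTable, DiseaseType, TypeThresholds
from .corpus import PublicationRecord
from .errors import ConfigError
from .indicators import JournalEntry, JournalTable, QuartileIndex, Quartile
from .registry import (
    Disease,
    DiseaseGroup,
    DiseaseRegistry,
    IncomeGroup,
    IncomeTable,
    LMIC_GROUPS,
)

__all__ = [
    "WorldConfig",
    "CorpusConfig",
    "SyntheticWorld",
    "CorpusGroundTruth",
    "generate_world",
    "generate_corpus",
]

_GROUPS = list(IncomeGroup)
_TYPES = list(DiseaseType)

#: Ratio-sampling bounds per intended type, nested inside the typology bins.
DEFAULT_RATIO_BOUNDS: dict[DiseaseType, tuple[float, float]] = {
    DiseaseType.T1a: (0.05, 0.74),
    DiseaseType.T1b: (0.75, 1.24),
    DiseaseType.T1c: (1.25, 2.99),
    DiseaseType.T2: (3.00, 34.9),
    DiseaseType.T3: (35.0, 300.0),
}

#: Disease counts per type replicating the size of the study's disease universe.
DEFAULT_TYPE_SIZES: dict[DiseaseType, int] = {
    DiseaseType.T1a: 34,
    DiseaseType.T1b: 28,
    DiseaseType.T1c: 26,
    DiseaseType.T2: 22,
    DiseaseType.T3: 24,
}


@dataclass
class WorldConfig:
    """Configuration of the static world (countries, diseases, burden, journals)."""

    seed: int = 0
    n_countries: dict[IncomeGroup, int] = field(
        default_factory=lambda: {
            IncomeGroup.HIC: 40,
            IncomeGroup.UMIC: 40,
            IncomeGroup.LoMIC: 30,
            IncomeGroup.LIC: 25,
        }
    )
    populations: dict[IncomeGroup, float] = field(
        default_factory=lambda: {
            IncomeGroup.HIC: 1.15e9,
            IncomeGroup.UMIC: 2.50e9,
            IncomeGroup.LoMIC: 2.45e9,
            IncomeGroup.LIC: 0.85e9,
        }
    )
    type_sizes: dict[DiseaseType, int] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_SIZES)
    )
    ratio_bounds: dict[DiseaseType, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RATIO_BOUNDS)
    )
    mesh_overlap_fraction: float = 0.0
    n_journals: int = 200
    n_categories: int = 5
    categories_per_journal: int = 1
    if_log_mean: float = 0.8
    if_log_sigma: float = 0.7
    year_window: tuple[int, int] = (2010, 2014)
    burden_year: int = 2010

    def validate(self) -> None:
        thresholds = TypeThresholds()
        bins = {
            DiseaseType.T1a: (0.0, thresholds.cut_1a_1b),
            DiseaseType.T1b: (thresholds.cut_1a_1b, thresholds.cut_1b_1c),
            DiseaseType.T1c: (thresholds.cut_1b_1c, thresholds.cut_1c_2),
            DiseaseType.T2: (thresholds.cut_1c_2, thresholds.cut_2_3),
            DiseaseType.T3: (thresholds.cut_2_3, math.inf),
        }
        for t, n in self.type_sizes.items():
            if n <= 0:
                raise ConfigError(f"type {t.value}: non-positive disease count")
            lo, hi = self.ratio_bounds[t]
            blo, bhi = bins[t]
            if not (blo <= lo <= hi < bhi):
                raise ConfigError(
                    f"type {t.value}: ratio bounds [{lo}, {hi}] not nested in "
                    f"bin [{blo}, {bhi})"
                )
        for g, p in self.populations.items():
            if p <= 0:
                raise ConfigError(f"group {g.value}: non-positive population")
        for g, n in self.n_countries.items():
            if n <= 0:
                raise ConfigError(f"group {g.value}: non-positive country count")
        if self.n_journals < 4 or self.n_categories < 1:
            raise ConfigError("need at least 4 journals and 1 category")
        if not 0.0 <= self.mesh_overlap_fraction <= 1.0:
            raise ConfigError("mesh_overlap_fraction must be in [0, 1]")


@dataclass
class SyntheticWorld:
    """A generated world plus its construction-time ground truth."""

    config: WorldConfig
    registry: DiseaseRegistry
    burden: BurdenTable
    income: IncomeTable
    journals: JournalTable
    intended_types: dict[str, DiseaseType]
    true_ratios: dict[str, float]
    countries: dict[IncomeGroup, list[str]]


def generate_world(config: WorldConfig | None = None) -> SyntheticWorld:
    """Build a reproducible synthetic world from ``config`` (seeded RNG).

    DALYs are constructed so that every disease's pooled LMIC-over-HIC
    burden-per-capita ratio equals its sampled target exactly, which pins
    the disease's classified type to the intended bin by construction.
    """
    config = config or WorldConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    prefixes = {
        IncomeGroup.HIC: "HA",
        IncomeGroup.UMIC: "UA",
        IncomeGroup.LoMIC: "MA",
        IncomeGroup.LIC: "LA",
    }
    # unique 4-char codes per group: prefix + 2-digit index
    countries = {
        g: [f"{prefixes[g]}{i:02d}" for i in range(config.n_countries[g])]
        for g in _GROUPS
    }
    income = IncomeTable(
        reference_year=config.burden_year,
        assignments={c: g for g in _GROUPS for c in countries[g]},
    )

    registry = DiseaseRegistry()
    dalys: dict[tuple[str, IncomeGroup], float] = {}
    intended: dict[str, DiseaseType] = {}
    ratios: dict[str, float] = {}
    pop_hic = config.populations[IncomeGroup.HIC]
    pop_lmic = sum(config.populations[g] for g in LMIC_GROUPS)

    mesh_counter = 0
    prev_mesh: str | None = None
    disease_idx = 0
    for dtype in _TYPES:
        lo, hi = config.ratio_bounds[dtype]
        for _ in range(config.type_sizes[dtype]):
            disease_idx += 1
            cause_id = f"GHE{disease_idx:03d}"
            # log-uniform target ratio within the type's sampling bounds
            ratio = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            # sample the disease's total world DALYs (independent of its
            # type, so type-level DALY shares track type sizes), then split
            # between HIC and the LMIC pool to hit the target ratio exactly
            total = float(np.exp(rng.uniform(np.log(1e6), np.log(1e8))))
            hic_rate = total / (pop_hic + ratio * pop_lmic)
            daly_hic = hic_rate * pop_hic
            daly_lmic_total = ratio * hic_rate * pop_lmic
            # split pooled LMIC DALYs by population with random perturbation;
            # the split does not affect the pooled ratio
            raw = np.array(
                [config.populations[g] for g in LMIC_GROUPS]
            ) * rng.uniform(0.5, 1.5, size=3)
            split = raw / raw.sum() * daly_lmic_total
            dalys[(cause_id, IncomeGroup.HIC)] = daly_hic
            for g, v in zip(LMIC_GROUPS, split):
                dalys[(cause_id, g)] = float(v)

            n_mesh = int(rng.integers(1, 4))
            mesh_ids = set()
            for _ in range(n_mesh):
                mesh_counter += 1
                mesh_ids.add(f"D{500000 + mesh_counter:06d}")
            if prev_mesh is not None and rng.random() < config.mesh_overlap_fraction:
                mesh_ids.add(prev_mesh)
            prev_mesh = sorted(mesh_ids)[0]

            group = (
                DiseaseGroup.COMMUNICABLE
                if dtype in (DiseaseType.T2, DiseaseType.T3)
                else DiseaseGroup.NONCOMMUNICABLE
            )
            registry.add(
                Disease(
                    cause_id=cause_id,
                    name=f"Synthetic disease {disease_idx:03d}",
                    group=group,
                    icd10_codes=(f"Z{disease_idx:03d}",),
                    mesh_ids=frozenset(mesh_ids),
                )
            )
            intended[cause_id] = dtype
            ratios[cause_id] = ratio

    burden = BurdenTable(
        year=config.burden_year,
        dalys=dalys,
        population=dict(config.populations),
    )

    journals = JournalTable()
    categories = [f"F{i + 1:02d}" for i in range(config.n_categories)]
    for j in range(config.n_journals):
        jid = f"J{j:04d}"
        impact = float(rng.lognormal(config.if_log_mean, config.if_log_sigma))
        cats = set()
        cats.add(categories[j % config.n_categories])
        extra = config.categories_per_journal - 1
        if extra > 0:
            others = [c for c in categories if c not in cats]
            cats |= set(
                rng.choice(others, size=min(extra, len(others)), replace=False)
            )
        for year in range(config.year_window[0], config.year_window[1] + 1):
            journals.add(
                JournalEntry(
                    journal_id=jid,
                    year=year,
                    subject_categories=frozenset(cats),
                    impact_factor=round(impact, 3),
                )
            )

    return SyntheticWorld(
        config=config,
        registry=registry,
        burden=burden,
        income=income,
        journals=journals,
        intended_types=intended,
        true_ratios=ratios,
        countries=countries,
    )


# ---------------------------------------------------------------------------
# corpus
# ---------------------------------------------------------------------------

def _default_specialisation() -> dict[IncomeGroup, dict[DiseaseType, float]]:
    rows = {
        IncomeGroup.HIC: [0.40, 0.27, 0.18, 0.10, 0.05],
        IncomeGroup.UMIC: [0.30, 0.25, 0.22, 0.15, 0.08],
        IncomeGroup.LoMIC: [0.25, 0.18, 0.17, 0.25, 0.15],
        IncomeGroup.LIC: [0.10, 0.12, 0.13, 0.30, 0.35],
    }
    return {g: dict(zip(_TYPES, row)) for g, row in rows.items()}


@dataclass
class CorpusConfig:
    """Configuration of the sampled publication corpus.

    ``specialisation`` gives P(disease type | lead income group);
    ``group_mix`` the probability a record's lead group is each income
    group; ``collaboration_rate`` the per-group probability of an
    international record (one partner country from another group, equal
    fractional split).  Citation means are ``base_mean[year] × effect``,
    with ``effect = type_effect × group_effect`` of the lead cell, drawn
    from a negative binomial with the given dispersion.
    """

    seed: int = 0
    total_publications: int = 5000
    group_mix: dict[IncomeGroup, float] = field(
        default_factory=lambda: {
            IncomeGroup.HIC: 0.790,
            IncomeGroup.UMIC: 0.170,
            IncomeGroup.LoMIC: 0.034,
            IncomeGroup.LIC: 0.006,
        }
    )
    specialisation: dict[IncomeGroup, dict[DiseaseType, float]] = field(
        default_factory=_default_specialisation
    )
    collaboration_rate: dict[IncomeGroup, float] = field(
        default_factory=lambda: {
            IncomeGroup.HIC: 0.20,
            IncomeGroup.UMIC: 0.20,
            IncomeGroup.LoMIC: 0.20,
            IncomeGroup.LIC: 0.75,
        }
    )
    base_mean: dict[int, float] = field(
        default_factory=lambda: {2010: 12.0, 2011: 10.0, 2012: 8.0, 2013: 6.0, 2014: 4.5}
    )
    dispersion: float = 1.2
    type_effect: dict[DiseaseType, float] = field(
        default_factory=lambda: dict(
            zip(_TYPES, [1.20, 1.10, 1.00, 0.90, 0.80])
        )
    )
    group_effect: dict[IncomeGroup, float] = field(
        default_factory=lambda: {
            IncomeGroup.HIC: 1.05,
            IncomeGroup.UMIC: 0.90,
            IncomeGroup.LoMIC: 0.85,
            IncomeGroup.LIC: 0.95,
        }
    )
    pharma_authored_prob: dict[DiseaseType, float] = field(
        default_factory=lambda: dict(zip(_TYPES, [0.050, 0.040, 0.030, 0.020, 0.010]))
    )
    pharma_funded_prob: dict[DiseaseType, float] = field(
        default_factory=lambda: dict(zip(_TYPES, [0.060, 0.045, 0.030, 0.020, 0.012]))
    )
    q1_propensity: dict[DiseaseType, float] = field(
        default_factory=lambda: dict(zip(_TYPES, [0.25, 0.25, 0.26, 0.28, 0.30]))
    )
    other_doc_rate: float = 0.05

    def validate(self) -> None:
        if self.total_publications <= 0:
            raise ConfigError("total_publications must be positive")
        if abs(sum(self.group_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("group_mix must sum to 1")
        for g, row in self.specialisation.items():
            if abs(sum(row.values()) - 1.0) > 1e-9:
                raise ConfigError(f"specialisation row for {g.value} must sum to 1")
        for name, probs in (
            ("collaboration_rate", self.collaboration_rate.values()),
            ("pharma_authored_prob", self.pharma_authored_prob.values()),
            ("pharma_funded_prob", self.pharma_funded_prob.values()),
            ("q1_propensity", self.q1_propensity.values()),
        ):
            if not all(0.0 <= p <= 1.0 for p in probs):
                raise ConfigError(f"{name} values must be in [0, 1]")
        if any(m <= 0 for m in self.base_mean.values()) or self.dispersion <= 0:
            raise ConfigError("citation means and dispersion must be positive")
        if any(e <= 0 for e in self.type_effect.values()) or any(
            e <= 0 for e in self.group_effect.values()
        ):
            raise ConfigError("citation effects must be positive")

    def effect(self, dtype: DiseaseType, group: IncomeGroup) -> float:
        return self.type_effect[dtype] * self.group_effect[group]


@dataclass
class CorpusGroundTruth:
    """Analytical expectations of the fractional-counting pipeline estimates.

    ``expected_cell_share[(type, group)]`` is the expected fractional
    publication share of the cell under the configured mixing and
    collaboration process; ``expected_group_collab_rate`` the expected
    international fraction of a group's fractional weight;
    ``expected_mncs_by_type`` the expected normalised-citation score per
    type (world average 1).
    """

    config: CorpusConfig
    expected_cell_share: dict[tuple[DiseaseType, IncomeGroup], float]
    expected_type_share: dict[DiseaseType, float]
    expected_group_share: dict[IncomeGroup, float]
    expected_group_collab_rate: dict[IncomeGroup, float]
    expected_record_collab_rate: float
    expected_mncs_by_type: dict[DiseaseType, float]


def _partner_dist(config: CorpusConfig, lead: IncomeGroup) -> dict[IncomeGroup, float]:
    """Partner-group distribution for an international record with this lead."""
    rest = {g: m for g, m in config.group_mix.items() if g is not lead}
    total = sum(rest.values())
    return {g: m / total for g, m in rest.items()}


def _ground_truth(config: CorpusConfig) -> CorpusGroundTruth:
    cell: dict[tuple[DiseaseType, IncomeGroup], float] = {
        (t, g): 0.0 for t in _TYPES for g in _GROUPS
    }
    intl_weight = {g: 0.0 for g in _GROUPS}
    total_weight = {g: 0.0 for g in _GROUPS}
    for lead in _GROUPS:
        m = config.group_mix[lead]
        c = config.collaboration_rate[lead]
        partner = _partner_dist(config, lead)
        # weight reaching group h given this lead
        w = {h: 0.0 for h in _GROUPS}
        w[lead] += (1.0 - c) * 1.0 + c * 0.5
        for h, p in partner.items():
            w[h] += c * 0.5 * p
        for t in _TYPES:
            s = config.specialisation[lead][t]
            for h in _GROUPS:
                cell[(t, h)] += m * s * w[h]
        for h in _GROUPS:
            total_weight[h] += m * w[h]
            intl_h = c * 0.5 * (1.0 if h is lead else 0.0) + c * 0.5 * partner.get(h, 0.0)
            intl_weight[h] += m * intl_h
    type_share = {t: sum(cell[(t, g)] for g in _GROUPS) for t in _TYPES}
    group_share = {g: sum(cell[(t, g)] for t in _TYPES) for g in _GROUPS}
    collab_rate = {
        g: intl_weight[g] / total_weight[g] if total_weight[g] else 0.0
        for g in _GROUPS
    }
    record_collab = sum(
        config.group_mix[g] * config.collaboration_rate[g] for g in _GROUPS
    )
    # expected normalised-citation score per type: the effect of the lead
    # cell relative to the corpus-wide mean effect (type and field-year are
    # sampled independently, and base means cancel in the normalisation)
    joint = {
        (t, g): config.group_mix[g] * config.specialisation[g][t]
        for t in _TYPES
        for g in _GROUPS
    }
    mean_effect = sum(p * config.effect(t, g) for (t, g), p in joint.items())
    mncs_by_type = {}
    for t in _TYPES:
        p_t = sum(joint[(t, g)] for g in _GROUPS)
        if p_t == 0.0:  # type unreachable under this specialisation
            mncs_by_type[t] = math.nan
            continue
        e_t = sum(joint[(t, g)] * config.effect(t, g) for g in _GROUPS) / p_t
        mncs_by_type[t] = e_t / mean_effect
    return CorpusGroundTruth(
        config=config,
        expected_cell_share=cell,
        expected_type_share=type_share,
        expected_group_share=group_share,
        expected_group_collab_rate=collab_rate,
        expected_record_collab_rate=record_collab,
        expected_mncs_by_type=mncs_by_type,
    )


def generate_corpus(
    world: SyntheticWorld, config: CorpusConfig | None = None
) -> tuple[list[PublicationRecord], CorpusGroundTruth]:
    """Sample a publication corpus from the configured group-level behaviour.

    Per record: a lead income group is drawn from ``group_mix``; a disease
    type from that group's specialisation row, then a disease uniformly
    within the type; affiliations are domestic (1–3 instances of one lead
    country) or, with the group's collaboration rate, split 50/50 with one
    partner country from another group; the journal is drawn Q1-or-not by
    the type's Q1 propensity; citations come from a negative binomial with
    mean ``base_mean[year] × effect(type, lead group)``; pharma flags are
    Bernoulli by type.  Reproducible given the seed.
    """
    if len(world.registry) == 0:
        raise ConfigError("cannot sample a corpus from an empty world")
    config = config or CorpusConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    by_type: dict[DiseaseType, list[str]] = {t: [] for t in _TYPES}
    for cause, t in world.intended_types.items():
        by_type[t].append(cause)
    for t, causes in by_type.items():
        if not causes and any(
            config.specialisation[g][t] > 0 for g in _GROUPS
        ):
            raise ConfigError(f"specialisation assigns mass to empty type {t.value}")

    # Q1/non-Q1 journal pools per year (any category, best-quartile rule)
    qindex = QuartileIndex(world.journals)
    years = list(range(world.config.year_window[0], world.config.year_window[1] + 1))
    q1_pool: dict[int, list[str]] = {}
    rest_pool: dict[int, list[str]] = {}
    all_journals = sorted({e.journal_id for e in world.journals})
    for y in years:
        q1_pool[y] = [
            j for j in all_journals if qindex.best_quartile(j, y) is Quartile.Q1
        ]
        rest_pool[y] = [
            j for j in all_journals if qindex.best_quartile(j, y) is not Quartile.Q1
        ]

    groups = _GROUPS
    mix = np.array([config.group_mix[g] for g in groups])
    spec_rows = {
        g: np.array([config.specialisation[g][t] for t in _TYPES]) for g in groups
    }

    records: list[PublicationRecord] = []
    for i in range(config.total_publications):
        lead = groups[int(rng.choice(len(groups), p=mix))]
        dtype = _TYPES[int(rng.choice(len(_TYPES), p=spec_rows[lead]))]
        cause = by_type[dtype][int(rng.integers(len(by_type[dtype])))]
        disease = world.registry[cause]
        year = int(rng.choice(years))
        doc_type = "other" if rng.random() < config.other_doc_rate else (
            "review" if rng.random() < 0.1 else "article"
        )

        lead_country = world.countries[lead][
            int(rng.integers(len(world.countries[lead])))
        ]
        if rng.random() < config.collaboration_rate[lead]:
            partner = _partner_dist(config, lead)
            pgroups = list(partner)
            pg = pgroups[
                int(rng.choice(len(pgroups), p=np.array([partner[g] for g in pgroups])))
            ]
            partner_country = world.countries[pg][
                int(rng.integers(len(world.countries[pg])))
            ]
            affiliations = (lead_country, partner_country)
        else:
            k = int(rng.integers(1, 4))
            affiliations = (lead_country,) * k

        pool = q1_pool[year] if rng.random() < config.q1_propensity[dtype] else rest_pool[year]
        if not pool:  # degenerate configs may have an empty side
            pool = all_journals
        journal_id = pool[int(rng.integers(len(pool)))]

        mu = config.base_mean[year] * config.effect(dtype, lead)
        k_disp = config.dispersion
        citations = int(rng.negative_binomial(k_disp, k_disp / (k_disp + mu)))

        records.append(
            PublicationRecord(
                pub_id=f"P{i:06d}",
                year=year,
                doc_type=doc_type,
                mesh_ids=disease.mesh_ids,
                affiliation_countries=affiliations,
                journal_id=journal_id,
                citations=citations,
                pharma_authored=bool(
                    rng.random() < config.pharma_authored_prob[dtype]
                ),
                pharma_funded=bool(rng.random() < config.pharma_funded_prob[dtype]),
            )
        )
    return records, _ground_truth(config)
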