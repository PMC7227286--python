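"""End-to-end orchestration: inputs → classification → counting → indicator tables.

A run either loads the five input files (disease concordance, burden +
population, income table, corpus JSONL, journal table, optionally a pharma
company list) or generates a synthetic world and corpus, then produces the
analysis tables: global shares by income group and disease type, relative
research effort by type, type-by-income distributions, pharma subsets, Q1
and citation indicators by type, and domestic-only indicators by type and
income level.

Subset analyses (domestic / international / pharma) are computed by
filtering records; the citation baselines are always computed once from
the full reference corpus, never re-derived per subset, matching the
"worldwide reference" semantics of field normalisation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import pandas as pd

from . import corpus as corpus_mod
from .burden import (
    BurdenTable,
    DiseaseType,
    TypeThresholds,
    burden_shares,
    classify_registry,
    load_burden_table,
    relative_burden_ratio,
)
from .corpus import (
    PublicationRecord,
    filter_corpus,
    flag_pharma,
    fractional_country_weights,
    is_international,
    read_corpus_jsonl,
    write_corpus_jsonl,
)
from .errors import ConfigError, UndefinedShareError
from .indicators import (
    JournalTable,
    QuartileIndex,
    field_year_baselines,
    income_group_weights,
    load_journal_table,
    mncs,
    pp_top10,
    publication_shares,
    q1_share,
    relative_research_effort,
)
from .registry import (
    CompanyList,
    DiseaseRegistry,
    IncomeGroup,
    IncomeTable,
    load_company_list,
    load_income_table,
    load_registry,
    write_registry,
)
from .synthetic import (
    CorpusConfig,
    SyntheticWorld,
    WorldConfig,
    generate_corpus,
    generate_world,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "ReportBundle",
    "run_pipeline",
    "subset_indicators",
    "write_bundle",
    "write_world_files",
    "SUBSET_LABELS",
]

SUBSET_LABELS = ("all", "domestic", "international", "pharma_authored", "pharma_funded")

_TYPES = list(DiseaseType)
_GROUPS = list(IncomeGroup)


@dataclass
class RunConfig:
    """Inputs, policies and output location of one pipeline run.

    Either all input paths are given, or ``synthetic`` is true and the
    world/corpus configs are used; never neither.
    """

    registry_path: str | None = None
    burden_path: str | None = None
    population_path: str | None = None
    income_path: str | None = None
    corpus_path: str | None = None
    journals_path: str | None = None
    companies_path: str | None = None
    synthetic: bool = False
    world_config: WorldConfig = field(default_factory=WorldConfig)
    corpus_config: CorpusConfig = field(default_factory=CorpusConfig)
    disease_policy: str = "fractional"
    unknown_country: str = "error"
    year_window: tuple[int, int] = (2010, 2014)
    thresholds: TypeThresholds = field(default_factory=TypeThresholds)
    seed: int = 0

    def validate(self) -> None:
        if self.synthetic:
            return
        required = {
            "registry_path": self.registry_path,
            "burden_path": self.burden_path,
            "population_path": self.population_path,
            "income_path": self.income_path,
            "corpus_path": self.corpus_path,
            "journals_path": self.journals_path,
        }
        missing = [k for k, v in required.items() if not v]
        if missing:
            raise ConfigError(
                f"non-synthetic run requires input paths: missing {missing}"
            )
        absent = [v for v in required.values() if v and not Path(v).exists()]
        if absent:
            raise ConfigError(f"input path(s) not found: {absent}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        cfg = cls()
        inputs = d.get("inputs", {})
        for key in (
            "registry_path",
            "burden_path",
            "population_path",
            "income_path",
            "corpus_path",
            "journals_path",
            "companies_path",
        ):
            if key in inputs:
                setattr(cfg, key, inputs[key])
        if d.get("synthetic"):
            cfg.synthetic = True
            syn = d["synthetic"] if isinstance(d["synthetic"], Mapping) else {}
            world = syn.get("world", {})
            corpus = syn.get("corpus", {})
            for k, v in world.items():
                if hasattr(cfg.world_config, k):
                    setattr(cfg.world_config, k, v)
            for k, v in corpus.items():
                if hasattr(cfg.corpus_config, k):
                    setattr(cfg.corpus_config, k, v)
        policies = d.get("policies", {})
        cfg.disease_policy = policies.get("disease_counting", cfg.disease_policy)
        cfg.unknown_country = policies.get("unknown_country", cfg.unknown_country)
        if "seed" in d:
            cfg.seed = int(d["seed"])
            cfg.world_config.seed = cfg.seed
            cfg.corpus_config.seed = cfg.seed + 1
        return cfg


@dataclass
class ReportBundle:
    """All analysis tables of one run, plus the metadata to reproduce them."""

    table_global_shares: pd.DataFrame
    table_relative_effort: pd.DataFrame
    table_by_income: pd.DataFrame
    table_pharma: pd.DataFrame
    table_q1_and_citations: pd.DataFrame
    table_domestic_by_income: pd.DataFrame
    metadata: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            name: getattr(self, name)
            for name in (
                "table_global_shares",
                "table_relative_effort",
                "table_by_income",
                "table_pharma",
                "table_q1_and_citations",
                "table_domestic_by_income",
            )
        }


@dataclass
class _PreparedRecord:
    """A record with all derived weights/flags the tables need."""

    record: PublicationRecord
    type_weights: dict[DiseaseType, float]   # disease credit summed by type
    group_weights: dict[IncomeGroup, float]  # fractional country credit by group
    international: bool
    pharma_authored: bool
    pharma_funded: bool


def _prepare(
    records: Sequence[PublicationRecord],
    registry: DiseaseRegistry,
    type_of: Mapping[str, DiseaseType],
    income: IncomeTable,
    companies: CompanyList | None,
    disease_policy: str,
    unknown_country: str,
) -> list[_PreparedRecord]:
    prepared = []
    for rec in records:
        dw = corpus_mod.disease_weights(rec, registry, policy=disease_policy)
        tw: dict[DiseaseType, float] = {}
        for cause, w in dw.items():
            t = type_of.get(cause)
            if t is None:
                continue  # disease excluded from typing (zero burden)
            tw[t] = tw.get(t, 0.0) + w
        cw = fractional_country_weights(rec)
        gw = income_group_weights(cw, income, unknown=unknown_country)
        if companies is not None:
            authored, funded = flag_pharma(rec, companies)
        else:
            authored = bool(rec.pharma_authored)
            funded = bool(rec.pharma_funded)
        prepared.append(
            _PreparedRecord(
                record=rec,
                type_weights=tw,
                group_weights=gw,
                international=is_international(rec),
                pharma_authored=authored,
                pharma_funded=funded,
            )
        )
    return prepared


def _subset_filter(label: str) -> Callable[[_PreparedRecord], bool]:
    return {
        "all": lambda p: True,
        "domestic": lambda p: bool(p.record.affiliation_countries)
        and not p.international,
        "international": lambda p: p.international,
        "pharma_authored": lambda p: p.pharma_authored,
        "pharma_funded": lambda p: p.pharma_funded,
    }[label]


def _type_subset(
    prepared: Sequence[_PreparedRecord], dtype: DiseaseType
) -> tuple[list[PublicationRecord], list[float]]:
    recs, weights = [], []
    for p in prepared:
        w = p.type_weights.get(dtype, 0.0)
        if w > 0:
            recs.append(p.record)
            weights.append(w)
    return recs, weights


def _indicator_row(
    recs: Sequence[PublicationRecord],
    weights: Sequence[float],
    qindex: QuartileIndex,
    baselines,
    journals: JournalTable,
) -> dict:
    row: dict = {"n_fractional": float(sum(weights))}
    if not recs:
        row.update(q1_share=float("nan"), mncs=float("nan"), pp_top10=float("nan"))
        return row
    try:
        row["q1_share"] = q1_share(recs, weights, qindex)
    except UndefinedShareError:
        row["q1_share"] = float("nan")
    row["mncs"] = mncs(recs, weights, baselines, journals)
    row["pp_top10"] = pp_top10(recs, weights, baselines, journals)
    return row


@dataclass
class _Context:
    """Loaded inputs and derived per-record state shared by all tables."""

    registry: DiseaseRegistry
    burden: BurdenTable
    income: IncomeTable
    journals: JournalTable
    prepared: list[_PreparedRecord]
    type_of: dict[str, DiseaseType]
    baselines: dict
    qindex: QuartileIndex
    filter_report: corpus_mod.FilterReport
    n_raw: int


def _build_context(config: RunConfig) -> _Context:
    config.validate()
    if config.synthetic:
        world = generate_world(config.world_config)
        registry, burden, income, journals = (
            world.registry,
            world.burden,
            world.income,
            world.journals,
        )
        raw_records, _truth = generate_corpus(world, config.corpus_config)
        companies = None
    else:
        with open(config.registry_path, encoding="utf-8") as f:
            registry = load_registry(f)
        burden = load_burden_table(config.burden_path, config.population_path)
        with open(config.income_path, encoding="utf-8") as f:
            income = load_income_table(f)
        journals = load_journal_table(config.journals_path)
        with open(config.corpus_path, encoding="utf-8") as f:
            raw_records = list(read_corpus_jsonl(f))
        companies = None
        if config.companies_path:
            with open(config.companies_path, encoding="utf-8") as f:
                companies = load_company_list(f)

    records, filter_report = filter_corpus(raw_records, year_window=config.year_window)
    type_of = classify_registry(burden, config.thresholds)

    prepared = _prepare(
        records,
        registry,
        type_of,
        income,
        companies,
        config.disease_policy,
        config.unknown_country,
    )

    # citation baselines and quartiles from the full reference corpus
    baselines = field_year_baselines(records, journals)
    qindex = QuartileIndex(journals)
    return _Context(
        registry=registry,
        burden=burden,
        income=income,
        journals=journals,
        prepared=prepared,
        type_of=type_of,
        baselines=baselines,
        qindex=qindex,
        filter_report=filter_report,
        n_raw=len(raw_records),
    )


def subset_indicators(config: RunConfig, subset: str) -> pd.DataFrame:
    """Q1 share and citation indicators by disease type for one subset label."""
    if subset not in SUBSET_LABELS:
        raise ConfigError(f"unknown subset {subset!r}; expected one of {SUBSET_LABELS}")
    ctx = _build_context(config)
    keep = _subset_filter(subset)
    sub = [p for p in ctx.prepared if keep(p)]
    rows = []
    for t in _TYPES:
        recs, weights = _type_subset(sub, t)
        row = {"subset": subset, "disease_type": t.value}
        row.update(
            _indicator_row(recs, weights, ctx.qindex, ctx.baselines, ctx.journals)
        )
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis and return every table plus run metadata."""
    ctx = _build_context(config)
    registry, burden, journals = ctx.registry, ctx.burden, ctx.journals
    prepared, type_of = ctx.prepared, ctx.type_of
    baselines, qindex, filter_report = ctx.baselines, ctx.qindex, ctx.filter_report
    ratios = {c: relative_burden_ratio(c, burden) for c in type_of}

    # ---- table 1: global shares by income group and by disease type ----
    pub_by_group = publication_shares(p.group_weights for p in prepared)
    pub_by_type = publication_shares(p.type_weights for p in prepared)
    daly_by_type = burden_shares(burden, type_of)
    group_dalys = {
        g: sum(burden.daly(c, g) for c in type_of) for g in _GROUPS
    }
    total_dalys = sum(group_dalys.values())
    total_pop = sum(burden.population.values())
    rows = []
    for g in _GROUPS:
        rows.append(
            {
                "dimension": "income_group",
                "key": g.value,
                "pub_share": pub_by_group.get(g, 0.0),
                "daly_share": group_dalys[g] / total_dalys,
                "population_share": burden.population[g] / total_pop,
            }
        )
    for t in _TYPES:
        rows.append(
            {
                "dimension": "disease_type",
                "key": t.value,
                "pub_share": pub_by_type.get(t, 0.0),
                "daly_share": daly_by_type.get(t, 0.0),
                "population_share": float("nan"),
            }
        )
    table_global = pd.DataFrame(rows)

    # ---- table 2: relative research effort by disease type ----
    rows = []
    for t in _TYPES:
        ps = pub_by_type.get(t, 0.0)
        ds = daly_by_type.get(t, 0.0)
        rows.append(
            {
                "disease_type": t.value,
                "pub_share": ps,
                "daly_share": ds,
                "relative_effort": relative_research_effort(ps, ds)
                if ds > 0
                else float("nan"),
            }
        )
    table_effort = pd.DataFrame(rows)

    # ---- table 3: type distribution within each income group ----
    rows = []
    for g in _GROUPS:
        try:
            within = publication_shares(
                {
                    t: p.type_weights.get(t, 0.0) * p.group_weights.get(g, 0.0)
                    for t in p.type_weights
                }
                for p in prepared
            )
        except UndefinedShareError:
            within = {}
        daly_within = burden_shares(burden, type_of, scope=g)
        for t in _TYPES:
            ps = within.get(t, 0.0)
            ds = daly_within.get(t, 0.0)
            rows.append(
                {
                    "income_group": g.value,
                    "disease_type": t.value,
                    "pub_share": ps,
                    "daly_share": ds,
                    "relative_effort": ps / ds if ds > 0 else float("nan"),
                }
            )
    table_by_income = pd.DataFrame(rows)

    # ---- table 4: pharma-authored / pharma-funded relative effort by type ----
    rows = []
    for label in ("pharma_authored", "pharma_funded"):
        keep = _subset_filter(label)
        sub = [p for p in prepared if keep(p)]
        try:
            shares = publication_shares(p.type_weights for p in sub)
        except UndefinedShareError:
            shares = {}
        for t in _TYPES:
            ps = shares.get(t, 0.0)
            ds = daly_by_type.get(t, 0.0)
            rows.append(
                {
                    "subset": label,
                    "disease_type": t.value,
                    "pub_share": ps,
                    "daly_share": ds,
                    "relative_effort": ps / ds if ds > 0 else float("nan"),
                    "n_fractional": sum(p.type_weights.get(t, 0.0) for p in sub),
                }
            )
    table_pharma = pd.DataFrame(rows)

    # ---- table 5: Q1 share and citation indicators by type (full corpus) ----
    rows = []
    for t in _TYPES:
        recs, weights = _type_subset(prepared, t)
        row = {"disease_type": t.value}
        row.update(_indicator_row(recs, weights, qindex, baselines, journals))
        rows.append(row)
    table_q1_cit = pd.DataFrame(rows)

    # ---- table 6: domestic-only Q1/citations by type and income group ----
    rows = []
    domestic = [p for p in prepared if _subset_filter("domestic")(p)]
    for g in _GROUPS:
        for t in _TYPES:
            recs, weights = [], []
            for p in domestic:
                w = p.type_weights.get(t, 0.0) * p.group_weights.get(g, 0.0)
                if w > 0:
                    recs.append(p.record)
                    weights.append(w)
            row = {"income_group": g.value, "disease_type": t.value}
            row.update(_indicator_row(recs, weights, qindex, baselines, journals))
            rows.append(row)
    table_domestic = pd.DataFrame(rows)

    metadata = {
        "seed": config.seed,
        "synthetic": config.synthetic,
        "disease_policy": config.disease_policy,
        "unknown_country_policy": config.unknown_country,
        "lmic_pooling": "population_weighted_pooled_rate",
        "year_window": list(config.year_window),
        "thresholds": dataclasses.asdict(config.thresholds),
        "n_records_raw": ctx.n_raw,
        "n_records_kept": filter_report.kept,
        "n_dropped_doc_type": filter_report.dropped_doc_type,
        "n_dropped_year": filter_report.dropped_year,
        "n_diseases": len(registry),
        "n_diseases_typed": len(type_of),
        "type_counts": {
            t.value: sum(1 for v in type_of.values() if v is t) for t in _TYPES
        },
        "burden_ratios_min_max": [min(ratios.values()), max(ratios.values())]
        if ratios
        else None,
    }

    return ReportBundle(
        table_global_shares=table_global,
        table_relative_effort=table_effort,
        table_by_income=table_by_income,
        table_pharma=table_pharma,
        table_q1_and_citations=table_q1_cit,
        table_domestic_by_income=table_domestic,
        metadata=metadata,
    )


def write_bundle(bundle: ReportBundle, out_dir: str | Path) -> None:
    """Write every table as CSV plus a JSON metadata sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in bundle.tables().items():
        df.to_csv(out / f"{name}.csv", index=False)
    with open(out / "run_metadata.json", "w", encoding="utf-8") as f:
        json.dump(bundle.metadata, f, indent=2)


def write_world_files(
    world: SyntheticWorld,
    records: Sequence[PublicationRecord],
    out_dir: str | Path,
) -> dict[str, str]:
    """Write a synthetic world + corpus in the formats the pipeline ingests.

    Returns the mapping of logical input name → written path, suitable for
    building a non-synthetic :class:`RunConfig`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    p = out / "registry.csv"
    with open(p, "w", encoding="utf-8", newline="") as f:
        write_registry(world.registry, f)
    paths["registry_path"] = str(p)

    p = out / "burden.csv"
    pd.DataFrame(
        [
            {"cause_id": c, "income_group": g.value, "dalys": v}
            for (c, g), v in world.burden.dalys.items()
        ]
    ).to_csv(p, index=False)
    paths["burden_path"] = str(p)

    p = out / "population.csv"
    pd.DataFrame(
        [
            {"income_group": g.value, "population": v, "year": world.burden.year}
            for g, v in world.burden.population.items()
        ]
    ).to_csv(p, index=False)
    paths["population_path"] = str(p)

    p = out / "income.csv"
    pd.DataFrame(
        [
            {
                "country_code": c,
                "income_group": g.value,
                "year": world.income.reference_year,
            }
            for c, g in world.income.assignments.items()
        ]
    ).to_csv(p, index=False)
    paths["income_path"] = str(p)

    p = out / "journals.csv"
    pd.DataFrame(
        [
            {
                "journal_id": e.journal_id,
                "year": e.year,
                "subject_categories": "|".join(sorted(e.subject_categories)),
                "impact_factor": e.impact_factor,
            }
            for e in world.journals
        ]
    ).to_csv(p, index=False)
    paths["journals_path"] = str(p)

    p = out / "corpus.jsonl"
    with open(p, "w", encoding="utf-8") as f:
        write_corpus_jsonl(records, f)
    paths["corpus_path"] = str(p)

    p = out / "ground_truth.json"
    with open(p, "w", encoding="utf-8") as f:
        json.dump(
            {
                "intended_types": {
                    c: t.value for c, t in world.intended_types.items()
                },
                "true_ratios": world.true_ratios,
                "world_seed": world.config.seed,
            },
            f,
            indent=2,
        )
    paths["ground_truth_path"] = str(p)
    return paths
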