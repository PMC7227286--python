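"""Research-effort and visibility indicators.

This module computes, for arbitrary aggregates of publications:

* publication shares (by disease type, income group, or both), using
  fractional weights so shares over a complete partition sum to 1;
* the *relative research effort*: a group's share of publications divided
  by its share of DALYs — 1 means attention proportional to burden;
* journal-impact-factor quartiles per subject category and year, where Q1
  groups the 25% of journals with the highest IFs, and the share of
  publications in Q1 journals;
* field- and year-normalised citation indicators: the Mean Normalised
  Citation Score (MNCS; citations divided by the world mean for the same
  field and year, world average = 1) and PPtop10% (the share of
  publications among the 10% most cited of their field and year, with
  publications tied at the threshold counted fractionally so the world
  value is exactly 10%).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dataclass_field
from enum import Enum
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd

from .corpus import PublicationRecord
from .errors import (
    MissingBaselineError,
    RowValidationError,
    SchemaError,
    UndefinedRatioError,
    UndefinedShareError,
)
from .registry import IncomeGroup, IncomeTable, income_group_of

logger = logging.getLogger(__name__)

__all__ = [
    "JournalEntry",
    "JournalTable",
    "load_journal_table",
    "Quartile",
    "assign_quartiles",
    "QuartileIndex",
    "FieldYearBaseline",
    "field_year_baselines",
    "income_group_weights",
    "publication_shares",
    "relative_research_effort",
    "q1_share",
    "mncs",
    "pp_top10",
]


# ---------------------------------------------------------------------------
# journals and quartiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JournalEntry:
    """One journal-year: subject categories and impact factor."""

    journal_id: str
    year: int
    subject_categories: frozenset[str]
    impact_factor: float

    def __post_init__(self) -> None:
        if not self.subject_categories:
            raise RowValidationError(
                f"journal {self.journal_id!r} ({self.year}) has no subject categories"
            )
        if self.impact_factor < 0:
            raise RowValidationError(
                f"journal {self.journal_id!r} ({self.year}) has negative IF"
            )


class JournalTable:
    """(journal_id, year)-keyed journal entries with nearest-year fallback.

    Impact-factor editions lag publication years, so a record from a year
    absent for its journal resolves to the journal's nearest available year
    (logged at debug level).
    """

    def __init__(self, entries: Iterable[JournalEntry] = ()):
        self._entries: dict[tuple[str, int], JournalEntry] = {}
        self._years: dict[str, list[int]] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: JournalEntry) -> None:
        key = (entry.journal_id, entry.year)
        if key in self._entries:
            raise RowValidationError(
                f"duplicate journal-year ({entry.journal_id}, {entry.year})"
            )
        self._entries[key] = entry
        self._years.setdefault(entry.journal_id, []).append(entry.year)
        self._years[entry.journal_id].sort()

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    def resolve(self, journal_id: str, year: int) -> JournalEntry | None:
        """Entry for the journal in ``year``, falling back to the nearest year."""
        entry = self._entries.get((journal_id, year))
        if entry is not None:
            return entry
        years = self._years.get(journal_id)
        if not years:
            return None
        nearest = min(years, key=lambda y: (abs(y - year), y))
        logger.debug(
            "journal %s has no %d edition; using %d", journal_id, year, nearest
        )
        return self._entries[(journal_id, nearest)]

    @property
    def category_years(self) -> set[tuple[str, int]]:
        out: set[tuple[str, int]] = set()
        for e in self._entries.values():
            for c in e.subject_categories:
                out.add((c, e.year))
        return out


def load_journal_table(source: TextIO | str) -> JournalTable:
    """Load journal CSV: journal_id, year, subject_categories (pipe-delimited), impact_factor."""
    df = pd.read_csv(source)
    required = {"journal_id", "year", "subject_categories", "impact_factor"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"journal table: missing column(s) {sorted(missing)}")
    table = JournalTable()
    for r in df.itertuples():
        table.add(
            JournalEntry(
                journal_id=str(r.journal_id),
                year=int(r.year),
                subject_categories=frozenset(
                    c.strip() for c in str(r.subject_categories).split("|") if c.strip()
                ),
                impact_factor=float(r.impact_factor),
            )
        )
    return table


class Quartile(str, Enum):
    Q1 = "Q1"
    Q2 = "Q2"
    Q3 = "Q3"
    Q4 = "Q4"


def assign_quartiles(
    journal_table: JournalTable, category: str, year: int
) -> dict[str, Quartile]:
    """JIF quartiles for every journal of a subject category in one year.

    Journals are ranked by descending impact factor; a journal at rank
    ``r`` of ``N`` is Q1 if ``r/N <= 0.25``, Q2 if ``<= 0.5``, Q3 if
    ``<= 0.75``, else Q4.  Journals tied on IF all take the best quartile
    of their tied block.  A single-journal category is Q1 (the journal is
    the top of its category).  An empty category-year yields an empty map.
    """
    entries = [
        e
        for e in journal_table
        if e.year == year and category in e.subject_categories
    ]
    if not entries:
        return {}
    if len(entries) == 1:
        return {entries[0].journal_id: Quartile.Q1}
    entries.sort(key=lambda e: (-e.impact_factor, e.journal_id))
    n = len(entries)
    out: dict[str, Quartile] = {}
    i = 0
    while i < n:
        j = i
        while j < n and entries[j].impact_factor == entries[i].impact_factor:
            j += 1
        best_rank = i + 1  # best rank of the tied block
        frac = best_rank / n
        if frac <= 0.25:
            q = Quartile.Q1
        elif frac <= 0.5:
            q = Quartile.Q2
        elif frac <= 0.75:
            q = Quartile.Q3
        else:
            q = Quartile.Q4
        for e in entries[i:j]:
            out[e.journal_id] = q
        i = j
    return out


class QuartileIndex:
    """Precomputed quartiles for every (category, year) of a journal table.

    ``best_quartile`` applies the best-quartile rule for journals indexed
    in several categories.
    """

    def __init__(self, journal_table: JournalTable):
        self._journal_table = journal_table
        self._by_category_year: dict[tuple[str, int], dict[str, Quartile]] = {
            (cat, yr): assign_quartiles(journal_table, cat, yr)
            for cat, yr in journal_table.category_years
        }

    def best_quartile(self, journal_id: str, year: int) -> Quartile | None:
        entry = self._journal_table.resolve(journal_id, year)
        if entry is None:
            return None
        quartiles = [
            self._by_category_year[(cat, entry.year)][journal_id]
            for cat in entry.subject_categories
        ]
        order = list(Quartile)
        return min(quartiles, key=order.index)


# ---------------------------------------------------------------------------
# field-year citation baselines
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldYearBaseline:
    """World citation reference for one (subject category, year).

    ``top10_threshold`` is the smallest citation value ``t`` such that the
    count of publications cited strictly more than ``t`` is at most 10% of
    the field-year; ``tie_fraction`` is the fractional top-10% credit given
    to publications cited exactly ``t``, chosen so the whole field-year's
    credit is exactly 10%.
    """

    field: str
    year: int
    mean_citations: float
    top10_threshold: int
    tie_fraction: float
    n_pubs: int


def _resolve_categories(
    record: PublicationRecord, journal_table: JournalTable
) -> list[tuple[str, int]]:
    """(category, baseline year) pairs for a record via its journal."""
    if record.journal_id is None:
        return []
    entry = journal_table.resolve(record.journal_id, record.year)
    if entry is None:
        return []
    return [(cat, record.year) for cat in sorted(entry.subject_categories)]


def field_year_baselines(
    reference_corpus: Sequence[PublicationRecord],
    journal_table: JournalTable,
) -> dict[tuple[str, int], FieldYearBaseline]:
    """Compute the citation baseline of every (field, year) in the reference set.

    Each reference record contributes its citation count to every subject
    category of its journal, under its own publication year.
    """
    citations: dict[tuple[str, int], list[int]] = {}
    for rec in reference_corpus:
        for key in _resolve_categories(rec, journal_table):
            citations.setdefault(key, []).append(rec.citations)
    baselines: dict[tuple[str, int], FieldYearBaseline] = {}
    for (cat, year), values in citations.items():
        n = len(values)
        mean = sum(values) / n
        target = 0.1 * n
        # smallest observed citation value t with #(c > t) <= 0.1 n;
        # #(c > t) is non-increasing in t so scan ascending
        threshold = None
        for t in sorted(set(values)):
            above = sum(1 for c in values if c > t)
            if above <= target:
                threshold = t
                break
        assert threshold is not None  # t = max(values) always satisfies
        above = sum(1 for c in values if c > threshold)
        ties = sum(1 for c in values if c == threshold)
        tie_fraction = (target - above) / ties
        baselines[(cat, year)] = FieldYearBaseline(
            field=cat,
            year=year,
            mean_citations=mean,
            top10_threshold=threshold,
            tie_fraction=tie_fraction,
            n_pubs=n,
        )
    return baselines


# ---------------------------------------------------------------------------
# shares and effort
# ---------------------------------------------------------------------------

def income_group_weights(
    country_weights: Mapping[str, float],
    income_table: IncomeTable,
    *,
    unknown: str = "error",
) -> dict[IncomeGroup, float]:
    """Aggregate fractional country weights to income groups.

    Under ``unknown="unclassified"`` the weight of unassigned countries is
    dropped (logged); the record then contributes less than one unit to
    group aggregates.
    """
    out: dict[IncomeGroup, float] = {}
    for country, w in country_weights.items():
        group = income_group_of(country, income_table, unknown=unknown)
        if group is None:
            logger.info("dropping weight %.3f of unclassified country %s", w, country)
            continue
        out[group] = out.get(group, 0.0) + w
    return out


def publication_shares(
    weighted_keys: Iterable[Mapping[object, float]],
) -> dict[object, float]:
    """Shares per key from per-record key→weight maps.

    Each element of ``weighted_keys`` is one record's attribution (e.g.
    {disease type: weight} or {(type, income group): weight}); empty maps
    are records excluded from the analysis.  Shares are the summed weights
    normalised by the total, so a complete partition sums to 1.
    """
    totals: dict[object, float] = {}
    grand = 0.0
    for keymap in weighted_keys:
        for key, w in keymap.items():
            totals[key] = totals.get(key, 0.0) + w
            grand += w
    if grand == 0.0:
        raise UndefinedShareError("no weight in scope (empty aggregate)")
    return {k: v / grand for k, v in totals.items()}


def relative_research_effort(pub_share: float, daly_share: float) -> float:
    """Publications-per-burden ratio: share of publications over share of DALYs."""
    if daly_share == 0.0:
        raise UndefinedRatioError(
            "relative research effort undefined for zero DALY share"
        )
    return pub_share / daly_share


# ---------------------------------------------------------------------------
# weighted citation / quartile indicators over a subset
# ---------------------------------------------------------------------------

def q1_share(
    subset: Sequence[PublicationRecord],
    weights: Sequence[float],
    quartile_index: QuartileIndex,
) -> float:
    """Weighted fraction of a subset published in Q1 journals.

    A record counts as Q1 when its journal-year is Q1 in at least one of
    the journal's categories (best-quartile rule).  Records whose journal
    is absent from the journal table are excluded from the denominator
    (logged).
    """
    num = 0.0
    den = 0.0
    n_excluded = 0
    for rec, w in zip(subset, weights):
        q = (
            quartile_index.best_quartile(rec.journal_id, rec.year)
            if rec.journal_id is not None
            else None
        )
        if q is None:
            n_excluded += 1
            continue
        den += w
        if q is Quartile.Q1:
            num += w
    if n_excluded:
        logger.info("q1_share: %d records without journal match excluded", n_excluded)
    if den == 0.0:
        raise UndefinedShareError("q1_share over an empty denominator")
    return num / den


def _normalised_score(
    record: PublicationRecord,
    baselines: Mapping[tuple[str, int], FieldYearBaseline],
    journal_table: JournalTable,
) -> float:
    keys = _resolve_categories(record, journal_table)
    if not keys:
        raise MissingBaselineError(
            f"record {record.pub_id}: journal {record.journal_id!r} not resolvable"
        )
    scores = []
    for key in keys:
        base = baselines.get(key)
        if base is None:
            raise MissingBaselineError(
                f"record {record.pub_id}: no baseline for field-year {key}"
            )
        if base.mean_citations == 0.0:
            if record.citations:
                raise MissingBaselineError(
                    f"field-year {key} has zero mean citations but record "
                    f"{record.pub_id} is cited"
                )
            scores.append(1.0)  # cited exactly at a zero field mean
        else:
            scores.append(record.citations / base.mean_citations)
    return sum(scores) / len(scores)


def mncs(
    subset: Sequence[PublicationRecord],
    weights: Sequence[float],
    baselines: Mapping[tuple[str, int], FieldYearBaseline],
    journal_table: JournalTable,
) -> float:
    """Mean Normalised Citation Score of a weighted subset.

    Per record, citations are divided by the field-year world mean,
    averaged with equal weight across the journal's categories; the subset
    value is the weighted mean of per-record scores.  The whole reference
    corpus scores 1 by construction when journals are single-category.
    """
    num = 0.0
    den = 0.0
    for rec, w in zip(subset, weights):
        num += w * _normalised_score(rec, baselines, journal_table)
        den += w
    if den == 0.0:
        raise UndefinedShareError("MNCS over an empty subset")
    return num / den


def _top10_credit(
    record: PublicationRecord,
    baselines: Mapping[tuple[str, int], FieldYearBaseline],
    journal_table: JournalTable,
) -> float:
    keys = _resolve_categories(record, journal_table)
    if not keys:
        raise MissingBaselineError(
            f"record {record.pub_id}: journal {record.journal_id!r} not resolvable"
        )
    credits = []
    for key in keys:
        base = baselines.get(key)
        if base is None:
            raise MissingBaselineError(
                f"record {record.pub_id}: no baseline for field-year {key}"
            )
        if record.citations > base.top10_threshold:
            credits.append(1.0)
        elif record.citations == base.top10_threshold:
            credits.append(base.tie_fraction)
        else:
            credits.append(0.0)
    return sum(credits) / len(credits)


def pp_top10(
    subset: Sequence[PublicationRecord],
    weights: Sequence[float],
    baselines: Mapping[tuple[str, int], FieldYearBaseline],
    journal_table: JournalTable,
) -> float:
    """Share of a weighted subset among the top 10% most cited of their field-year.

    Records strictly above the field-year threshold count in full; records
    exactly at it count the baseline's tie fraction, which makes the world
    value exactly 10% for single-category corpora.
    """
    num = 0.0
    den = 0.0
    for rec, w in zip(subset, weights):
        num += w * _top10_credit(rec, baselines, journal_table)
        den += w
    if den == 0.0:
        raise UndefinedShareError("PPtop10 over an empty subset")
    return num / den
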