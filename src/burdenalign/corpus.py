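"""Publication records: filtering, fractional counting, collaboration, pharma flags.

A publication is attributed to countries by *fractional counting*: each
author-affiliation instance carries ``1/n`` of the publication (``n`` the
number of instances), aggregated by country, so every publication
contributes exactly one unit of credit.  A publication listing two or more
distinct countries is an *international collaboration*.  Disease credit is
split the same way across the diseases a record's MeSH descriptors match
(policy ``"fractional"``), or given in full to each matched disease
(policy ``"full"``).

Corpus I/O is JSONL: one record per line with the field names of
:class:`PublicationRecord`.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from typing import Iterable, Iterator, Sequence, TextIO

from .registry import CompanyList, DiseaseRegistry, map_mesh_to_diseases

__all__ = [
    "PublicationRecord",
    "read_corpus_jsonl",
    "write_corpus_jsonl",
    "filter_corpus",
    "FilterReport",
    "fractional_country_weights",
    "is_international",
    "disease_weights",
    "flag_pharma",
]

DEFAULT_YEAR_WINDOW = (2010, 2014)

DOC_TYPES = ("article", "review", "other")


@dataclass
class PublicationRecord:
    """One publication with the fields the indicators need.

    ``affiliation_countries`` holds one country code per author-affiliation
    instance, repeats allowed; an empty list excludes the record from
    country-level analyses.  ``pharma_authored``/``pharma_funded`` may be
    pre-set or derived from raw strings by :func:`flag_pharma`.
    """

    pub_id: str
    year: int
    doc_type: str
    mesh_ids: frozenset[str] = field(default_factory=frozenset)
    affiliation_countries: tuple[str, ...] = ()
    journal_id: str | None = None
    citations: int = 0
    affiliation_texts: tuple[str, ...] = ()
    funding_texts: tuple[str, ...] = ()
    pharma_authored: bool | None = None
    pharma_funded: bool | None = None

    def __post_init__(self) -> None:
        if self.citations < 0:
            raise ValueError(f"{self.pub_id}: negative citation count")
        if self.doc_type not in DOC_TYPES:
            raise ValueError(f"{self.pub_id}: unknown doc_type {self.doc_type!r}")


def write_corpus_jsonl(records: Iterable[PublicationRecord], sink: TextIO) -> int:
    n = 0
    for rec in records:
        d = asdict(rec)
        d["mesh_ids"] = sorted(rec.mesh_ids)
        d["affiliation_countries"] = list(rec.affiliation_countries)
        d["affiliation_texts"] = list(rec.affiliation_texts)
        d["funding_texts"] = list(rec.funding_texts)
        sink.write(json.dumps(d) + "\n")
        n += 1
    return n


def read_corpus_jsonl(source: TextIO) -> Iterator[PublicationRecord]:
    for line in source:
        line = line.strip()
        if not line:
            continue
        d = json.loads(line)
        yield PublicationRecord(
            pub_id=str(d["pub_id"]),
            year=int(d["year"]),
            doc_type=d["doc_type"],
            mesh_ids=frozenset(d.get("mesh_ids", ())),
            affiliation_countries=tuple(d.get("affiliation_countries", ())),
            journal_id=d.get("journal_id"),
            citations=int(d.get("citations", 0)),
            affiliation_texts=tuple(d.get("affiliation_texts", ())),
            funding_texts=tuple(d.get("funding_texts", ())),
            pharma_authored=d.get("pharma_authored"),
            pharma_funded=d.get("pharma_funded"),
        )


@dataclass
class FilterReport:
    kept: int = 0
    dropped_doc_type: int = 0
    dropped_year: int = 0

    @property
    def dropped(self) -> int:
        return self.dropped_doc_type + self.dropped_year


def filter_corpus(
    records: Iterable[PublicationRecord],
    year_window: tuple[int, int] = DEFAULT_YEAR_WINDOW,
    doc_types: Sequence[str] = ("article", "review"),
) -> tuple[list[PublicationRecord], FilterReport]:
    """Keep articles/reviews inside the year window; report drop counts.

    Document type is checked first, so a record failing both tests counts
    as a doc-type drop.
    """
    lo, hi = year_window
    kept: list[PublicationRecord] = []
    report = FilterReport()
    for rec in records:
        if rec.doc_type not in doc_types:
            report.dropped_doc_type += 1
        elif not lo <= rec.year <= hi:
            report.dropped_year += 1
        else:
            kept.append(rec)
    report.kept = len(kept)
    return kept, report


def fractional_country_weights(record: PublicationRecord) -> dict[str, float]:
    """Per-country fractional credit: 1/n per affiliation instance, summed.

    Weights sum to exactly 1 for a non-empty affiliation list; an empty
    list yields empty weights (the record is excluded from country
    analyses).
    """
    countries = record.affiliation_countries
    if not countries:
        return {}
    w = 1.0 / len(countries)
    out: dict[str, float] = {}
    for c in countries:
        out[c] = out.get(c, 0.0) + w
    return out


def is_international(record: PublicationRecord) -> bool:
    """True iff the record lists two or more distinct affiliation countries."""
    return len(set(record.affiliation_countries)) >= 2


def disease_weights(
    record: PublicationRecord,
    registry: DiseaseRegistry,
    policy: str = "fractional",
) -> dict[str, float]:
    """Credit per matched disease.

    ``"fractional"`` splits one unit equally across matched diseases (type
    shares then sum to 100%); ``"full"`` gives each matched disease weight
    1.  No match yields empty weights.
    """
    if policy not in ("fractional", "full"):
        raise ValueError(f"unknown disease-counting policy {policy!r}")
    matched = map_mesh_to_diseases(record.mesh_ids, registry)
    if not matched:
        return {}
    w = 1.0 / len(matched) if policy == "fractional" else 1.0
    return {cause: w for cause in sorted(matched)}


_NORMALISE_RE = re.compile(r"[^a-z0-9 ]+")


def _normalise(text: str) -> str:
    """Lower-case and strip punctuation for alias matching."""
    return _NORMALISE_RE.sub(" ", text.lower())


def _any_alias_match(texts: Sequence[str], companies: CompanyList) -> bool:
    normalised = [_normalise(t) for t in texts]
    for company in companies.companies:
        for alias in company.aliases:
            needle = _normalise(alias).strip()
            if needle and any(needle in t for t in normalised):
                return True
    return False


def flag_pharma(
    record: PublicationRecord, companies: CompanyList
) -> tuple[bool, bool]:
    """(authored, funded) pharma flags for one record.

    Pre-set boolean flags pass through unchanged; otherwise the raw
    affiliation / funding strings are matched against company aliases
    (case-insensitive, punctuation-stripped substring).  The two flags are
    independent: a record may be both authored and funded.
    """
    if record.pharma_authored is not None:
        authored = record.pharma_authored
    else:
        authored = _any_alias_match(record.affiliation_texts, companies)
    if record.pharma_funded is not None:
        funded = record.pharma_funded
    else:
        funded = _any_alias_match(record.funding_texts, companies)
    return authored, funded
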