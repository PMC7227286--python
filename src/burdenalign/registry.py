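"""Disease registry, country-income table and pharma company list.

The registry is the disease universe of the analysis: one entry per cause
in the burden cause list, each carrying its ICD-10 code ranges and the set
of MeSH descriptor identifiers used to delineate its publications in the
literature.  The income table maps ISO-3166 alpha-3 country codes to the
four World Bank income groups for a reference year, and the company list
holds canonical pharma company names with their matchable aliases.

File dialects
-------------
* Concordance table: UTF-8 CSV or TSV (autodetected from the header line),
  columns ``cause_id, name, group, icd10_codes, mesh_ids``; list cells are
  pipe-delimited.
* Income table: CSV with columns ``country_code, income_group, year``.
* Company list: CSV with columns ``canonical_name, aliases`` (aliases
  pipe-delimited).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, TextIO

from .errors import (
    ConflictError,
    RowValidationError,
    SchemaError,
    UnknownCountryError,
)

__all__ = [
    "DiseaseGroup",
    "IncomeGroup",
    "LMIC_GROUPS",
    "Disease",
    "DiseaseRegistry",
    "IncomeTable",
    "Company",
    "CompanyList",
    "load_registry",
    "write_registry",
    "load_income_table",
    "load_company_list",
    "map_mesh_to_diseases",
    "income_group_of",
]


class DiseaseGroup(str, Enum):
    """Top-level cause groups covered by the analysis."""

    COMMUNICABLE = "communicable_maternal_perinatal_nutritional"
    NONCOMMUNICABLE = "noncommunicable"


class IncomeGroup(str, Enum):
    """World Bank income classes (HIC, upper/lower-middle, low)."""

    HIC = "HIC"
    UMIC = "UMIC"
    LoMIC = "LoMIC"
    LIC = "LIC"


#: The three groups pooled into "LMIC" for the burden-per-capita ratio.
LMIC_GROUPS = (IncomeGroup.UMIC, IncomeGroup.LoMIC, IncomeGroup.LIC)


@dataclass(frozen=True)
class Disease:
    """A single cause: identifier, name, group, ICD-10 ranges, MeSH ids."""

    cause_id: str
    name: str
    group: DiseaseGroup
    icd10_codes: tuple[str, ...]
    mesh_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.mesh_ids:
            raise RowValidationError(
                f"disease {self.cause_id!r} has an empty MeSH descriptor set"
            )


class DiseaseRegistry:
    """Ordered collection of :class:`Disease` with unique cause ids.

    Also maintains the inverted MeSH-descriptor index used to map a
    publication's descriptors back to diseases.
    """

    def __init__(self, diseases: Iterable[Disease] = ()):
        self._diseases: dict[str, Disease] = {}
        self._mesh_index: dict[str, set[str]] = {}
        for d in diseases:
            self.add(d)

    def add(self, disease: Disease) -> None:
        if disease.cause_id in self._diseases:
            raise ConflictError(f"duplicate cause_id {disease.cause_id!r}")
        self._diseases[disease.cause_id] = disease
        for mesh_id in disease.mesh_ids:
            self._mesh_index.setdefault(mesh_id, set()).add(disease.cause_id)

    def __len__(self) -> int:
        return len(self._diseases)

    def __iter__(self):
        return iter(self._diseases.values())

    def __contains__(self, cause_id: str) -> bool:
        return cause_id in self._diseases

    def __getitem__(self, cause_id: str) -> Disease:
        return self._diseases[cause_id]

    @property
    def cause_ids(self) -> list[str]:
        return list(self._diseases)

    def diseases_for_mesh(self, mesh_id: str) -> set[str]:
        """Cause ids whose descriptor set contains ``mesh_id``."""
        return set(self._mesh_index.get(mesh_id, ()))


@dataclass
class IncomeTable:
    """Country → income-group assignment for one reference year."""

    reference_year: int
    assignments: dict[str, IncomeGroup] = field(default_factory=dict)

    def __contains__(self, country_code: str) -> bool:
        return country_code in self.assignments


@dataclass(frozen=True)
class Company:
    canonical_name: str
    aliases: frozenset[str]

    def __post_init__(self) -> None:
        if not self.aliases:
            raise RowValidationError(
                f"company {self.canonical_name!r} has no aliases"
            )


@dataclass
class CompanyList:
    """Pharma companies with alias strings used for affiliation/funding matching."""

    companies: list[Company] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.canonical_name for c in self.companies]
        if len(names) != len(set(names)):
            raise ConflictError("duplicate canonical company names")

    def __len__(self) -> int:
        return len(self.companies)


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------

_LIST_DELIM = "|"


def _open_reader(source: TextIO | str, required: set[str], what: str) -> csv.DictReader:
    """Build a DictReader with the delimiter sniffed from the header line."""
    if isinstance(source, str):
        source = io.StringIO(source)
    text = source.read()
    header_line = text.splitlines()[0] if text.strip() else ""
    delimiter = "\t" if "\t" in header_line else ","
    reader = csv.DictReader(io.StringIO(text), delimiter=delimiter)
    fields = set(reader.fieldnames or ())
    missing = required - fields
    if missing:
        raise SchemaError(
            f"{what}: missing required column(s) {sorted(missing)}; found {sorted(fields)}"
        )
    return reader


def load_registry(source: TextIO | str) -> DiseaseRegistry:
    """Load the disease concordance table (CSV or TSV).

    Raises :class:`SchemaError` for a missing column,
    :class:`RowValidationError` (with row number) for an empty MeSH cell and
    :class:`ConflictError` for a duplicated cause id.
    """
    reader = _open_reader(
        source,
        {"cause_id", "name", "group", "icd10_codes", "mesh_ids"},
        "concordance table",
    )
    registry = DiseaseRegistry()
    for i, row in enumerate(reader, start=1):
        mesh_cell = (row["mesh_ids"] or "").strip()
        if not mesh_cell:
            raise RowValidationError(
                f"empty mesh_ids cell for cause_id {row['cause_id']!r}", row=i
            )
        try:
            group = DiseaseGroup(row["group"].strip())
        except ValueError as exc:
            raise RowValidationError(
                f"unknown disease group {row['group']!r}", row=i
            ) from exc
        icd10 = tuple(
            c.strip() for c in (row["icd10_codes"] or "").split(_LIST_DELIM) if c.strip()
        )
        registry.add(
            Disease(
                cause_id=row["cause_id"].strip(),
                name=row["name"].strip(),
                group=group,
                icd10_codes=icd10,
                mesh_ids=frozenset(
                    m.strip() for m in mesh_cell.split(_LIST_DELIM) if m.strip()
                ),
            )
        )
    return registry


def write_registry(registry: DiseaseRegistry, sink: TextIO) -> None:
    """Write a registry back in the canonical CSV dialect (round-trippable)."""
    writer = csv.writer(sink)
    writer.writerow(["cause_id", "name", "group", "icd10_codes", "mesh_ids"])
    for d in registry:
        writer.writerow(
            [
                d.cause_id,
                d.name,
                d.group.value,
                _LIST_DELIM.join(d.icd10_codes),
                _LIST_DELIM.join(sorted(d.mesh_ids)),
            ]
        )


def load_income_table(source: TextIO | str) -> IncomeTable:
    """Load the country-code → income-group table."""
    reader = _open_reader(
        source, {"country_code", "income_group", "year"}, "income table"
    )
    assignments: dict[str, IncomeGroup] = {}
    year: int | None = None
    for i, row in enumerate(reader, start=1):
        code = row["country_code"].strip()
        if code in assignments:
            raise ConflictError(f"country {code!r} assigned twice")
        try:
            assignments[code] = IncomeGroup(row["income_group"].strip())
        except ValueError as exc:
            raise RowValidationError(
                f"unknown income group {row['income_group']!r}", row=i
            ) from exc
        row_year = int(row["year"])
        if year is None:
            year = row_year
        elif year != row_year:
            raise RowValidationError(
                f"mixed reference years {year} and {row_year}", row=i
            )
    return IncomeTable(reference_year=year if year is not None else 0,
                       assignments=assignments)


def load_company_list(source: TextIO | str) -> CompanyList:
    """Load the pharma company alias list."""
    reader = _open_reader(source, {"canonical_name", "aliases"}, "company list")
    companies = []
    for i, row in enumerate(reader, start=1):
        aliases = frozenset(
            a.strip() for a in (row["aliases"] or "").split(_LIST_DELIM) if a.strip()
        )
        if not aliases:
            raise RowValidationError(
                f"company {row['canonical_name']!r} has an empty alias cell", row=i
            )
        companies.append(
            Company(canonical_name=row["canonical_name"].strip(), aliases=aliases)
        )
    return CompanyList(companies=companies)


# ---------------------------------------------------------------------------
# lookups
# ---------------------------------------------------------------------------

def map_mesh_to_diseases(
    mesh_ids: Iterable[str], registry: DiseaseRegistry
) -> set[str]:
    """Cause ids of every disease whose descriptor set intersects ``mesh_ids``.

    Descriptors unknown to the registry simply do not match; a descriptor
    shared by several diseases maps to all of them.
    """
    out: set[str] = set()
    for mesh_id in mesh_ids:
        out |= registry.diseases_for_mesh(mesh_id)
    return out


def income_group_of(
    country: str,
    table: IncomeTable,
    *,
    unknown: str = "error",
) -> IncomeGroup | None:
    """Income group of ``country`` in the reference year.

    ``unknown`` selects the policy for codes absent from the table:
    ``"error"`` (default) raises :class:`UnknownCountryError`;
    ``"unclassified"`` returns ``None`` so the caller can exclude the
    affiliation instance from group-level aggregates.
    """
    try:
        return table.assignments[country]
    except KeyError:
        if unknown == "unclassified":
            return None
        raise UnknownCountryError(
            f"country code {country!r} has no income-group assignment "
            f"for {table.reference_year}"
        ) from None
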