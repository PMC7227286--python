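import pytest

from burdenalign import (
    CorpusConfig,
    WorldConfig,
    generate_corpus,
    generate_world,
    load_company_list,
    load_income_table,
    load_registry,
)

REGISTRY_CSV = """\
cause_id,name,group,icd10_codes,mesh_ids
GHE010,Tuberculosis,communicable_maternal_perinatal_nutritional,A15-A19,D014376
GHE020,Malaria,communicable_maternal_perinatal_nutritional,B50-B54,D008288|D016778
GHE030,Breast cancer,noncommunicable,C50,D001943
"""

INCOME_CSV = """\
country_code,income_group,year
NLD,HIC,2010
ESP,HIC,2010
CHN,UMIC,2010
IND,LoMIC,2010
ETH,LIC,2010
"""

COMPANIES_CSV = """\
canonical_name,aliases
Roche,roche|hoffmann-la roche
Novartis,novartis
Pfizer,pfizer
"""


@pytest.fixture
def tiny_registry():
    return load_registry(REGISTRY_CSV)


@pytest.fixture
def tiny_income():
    return load_income_table(INCOME_CSV)


@pytest.fixture
def tiny_companies():
    return load_company_list(COMPANIES_CSV)


@pytest.fixture(scope="session")
def world():
    """Default synthetic world, shared across tests (read-only)."""
    return generate_world(WorldConfig(seed=11))


@pytest.fixture(scope="session")
def small_corpus(world):
    """A 2000-record corpus on the shared world, with its ground truth."""
    records, truth = generate_corpus(
        world, CorpusConfig(seed=12, total_publications=2000)
    )
    return records, truth
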