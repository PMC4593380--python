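"""Shared fixtures: packaged tables, domain map, and PDB-text loading."""

from importlib import resources

import pytest

from mxamut.catalog import read_mutation_table, screen_missense
from mxamut.classify import load_classify_config, load_feature_fixture
from mxamut.domains import load_domain_map
from mxamut.structure import read_structure


@pytest.fixture(scope="session")
def table1_records():
    with resources.as_file(resources.files("mxamut.data").joinpath("table1.tsv")) as p:
        return read_mutation_table(p)


@pytest.fixture(scope="session")
def screened_catalog(table1_records):
    return screen_missense(table1_records)


@pytest.fixture(scope="session")
def domain_map():
    return load_domain_map()


@pytest.fixture(scope="session")
def feature_fixture():
    return load_feature_fixture()


@pytest.fixture(scope="session")
def classify_config():
    return load_classify_config()


@pytest.fixture
def load_pdb(tmp_path):
    """Write PDB text to a temp file and parse it."""

    def _load(text, name="fixture.pdb"):
        path = tmp_path / name
        path.write_text(text)
        return read_structure(path)

    return _load


# Published per-mutation domain placement (Table 2 analogue), used by both
# the domain tests and the acceptance suite.
TABLE2_DOMAINS = {
    "L95P": "G domain", "P96S": "G domain", "S134L": "G domain",
    "P218S": "G domain", "V263M": "G domain", "R310S": "G domain",
    "K326N": "G domain",
    "L643V": "BSE", "R649W": "BSE", "T651M": "BSE", "R654Q": "BSE", "R655C": "BSE",
    "G392V": "Stalk", "V449G": "Stalk", "N491K": "Stalk", "R522C": "Stalk",
    "L619I": "Stalk",
    "E632K": "Hinge 1",
    "G540D": "L4", "Y538C": "L4", "S572Y": "L4",
    "T27S": "N'-loop",
}

# Published four-tier verdicts.
TABLE3_IMPACT = {
    "L95P": "drastic", "P96S": "drastic", "G392V": "drastic", "V449G": "drastic",
    "P218S": "drastic", "R522C": "drastic", "E632K": "drastic",
    "V263M": "moderate", "K326N": "moderate", "R649W": "moderate",
    "T651M": "moderate", "R654Q": "moderate", "R655C": "moderate",
    "S134L": "very_moderate", "R310S": "very_moderate", "N491K": "very_moderate",
    "L619I": "very_moderate", "L643V": "very_moderate",
    "T27S": "unpredictable", "Y538C": "unpredictable", "G540D": "unpredictable",
    "S572Y": "unpredictable",
}
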