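from __future__ import annotations

from pathlib import Path

import pytest

from protsyn.fixtures import GroundTruth, table1_fixture
from protsyn.readers import Source, parse_biogrid, parse_ncbigene, parse_uniprot


def parse_corpus(directory: Path) -> dict[Source, list]:
    """Parse the three fixture files of a corpus directory."""
    return {
        Source.UNIPROT: list(parse_uniprot(directory / "uniprot.xml")),
        Source.BIOGRID: list(parse_biogrid(directory / "biogrid.xml")),
        Source.NCBIGENE: list(parse_ncbigene(directory / "ncbigene.xml")),
    }


@pytest.fixture(scope="session")
def table1_dir(tmp_path_factory) -> Path:
    directory = tmp_path_factory.mktemp("table1")
    table1_fixture(directory)
    return directory


@pytest.fixture(scope="session")
def table1_truth() -> GroundTruth:
    return table1_fixture(None)


@pytest.fixture()
def table1_records(table1_truth) -> dict[Source, list]:
    return {source: list(records) for source, records in table1_truth.records.items()}
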