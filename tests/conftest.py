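import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ontosample import (
    build_dictionary, convert_part_of, information_content, merge_dictionaries,
    parse_obo,
)
from ontosample.fixtures import make_toy_ontology
from ontosample.metaio import EXPECTED_FIELDS, SampleRecord


@pytest.fixture(scope="session")
def toy_paths(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("toy_ontology")
    tissue, disease = make_toy_ontology(outdir)
    return tissue, disease


@pytest.fixture(scope="session")
def tissue_graph(toy_paths):
    return convert_part_of(parse_obo(toy_paths[0]))


@pytest.fixture(scope="session")
def disease_graph(toy_paths):
    return convert_part_of(parse_obo(toy_paths[1]))


@pytest.fixture(scope="session")
def tissue_ic(tissue_graph):
    return information_content(tissue_graph)


@pytest.fixture(scope="session")
def tissue_dictionary(tissue_graph):
    return build_dictionary(tissue_graph)


@pytest.fixture(scope="session")
def merged_dictionary(tissue_graph, disease_graph):
    return merge_dictionaries([build_dictionary(tissue_graph),
                               build_dictionary(disease_graph)])


def records_from_frame(df):
    """Turn a fixture metadata DataFrame into SampleRecord objects."""
    text_cols = [c for c in df.columns if c != "sample_id"]
    return [SampleRecord(row.sample_id,
                         {c: getattr(row, c) for c in text_cols})
            for row in df.itertuples()]


@pytest.fixture
def make_records():
    def _make(texts: dict[str, str]):
        """One record per (sample_id -> title text) pair; other fields empty."""
        return [SampleRecord(sid, {f: (text if f == "title" else "")
                                   for f in EXPECTED_FIELDS})
                for sid, text in texts.items()]
    return _make
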