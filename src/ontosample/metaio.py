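"""Readers and writers for sample metadata and the pipeline's artifact files.

All tabular formats are UTF-8 TSV with a header row.  Tabs and newlines
inside free-text metadata fields are escaped as ``\\t`` / ``\\n`` on write
and unescaped on read, so a record round-trips byte-exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from ontosample.annotator import Annotation, SemanticSet
from ontosample.ontology import OntologyGraph
from ontosample.semcompare import ScoreMatrix
from ontosample.similarity import SampleSimilarityMatrix

logger = logging.getLogger(__name__)

#: the informative GEO-style fields selected for annotation
EXPECTED_FIELDS = ("title", "summary", "source_name_ch1", "organism_ch1",
                   "characteristics_ch1", "description")

_ID_COLUMN_NAMES = ("sample_id", "gsm", "sample", "id")


@dataclass
class SampleRecord:
    """One sample's free-text metadata plus optional filter attributes.

    ``fields`` always contains every expected field name (missing ones as
    empty strings) and preserves any extra columns.
    """

    sample_id: str
    fields: dict[str, str] = field(default_factory=dict)
    platform: str | None = None
    experiment_type: str | None = None
    organism: str | None = None

    def __post_init__(self):
        for name in EXPECTED_FIELDS:
            self.fields.setdefault(name, "")
        if self.organism is None and self.fields.get("organism_ch1"):
            self.organism = self.fields["organism_ch1"]


def _escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace("\t", "\\t").replace("\n", "\\n")


def _unescape(text: str) -> str:
    out, i = [], 0
    while i < len(text):
        if text[i] == "\\" and i + 1 < len(text):
            nxt = text[i + 1]
            out.append({"t": "\t", "n": "\n", "\\": "\\"}.get(nxt, "\\" + nxt))
            i += 2
        else:
            out.append(text[i])
            i += 1
    return "".join(out)


def read_metadata(path) -> list[SampleRecord]:
    """Read a GEO-style metadata TSV into :class:`SampleRecord` objects.

    The sample-id column is the first column named ``sample_id``/``gsm``/
    ``sample``/``id`` (case-insensitive), else the first column.  Column
    names are normalized to lowercase; empty cells become empty strings.
    Duplicate sample ids raise an error listing them.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    id_col = next((c for c in df.columns if c in _ID_COLUMN_NAMES), None)
    if id_col is None:
        if len(df.columns) == 0:
            raise ValueError("metadata file has no columns")
        id_col = df.columns[0]
        logger.info("using first column %r as sample id", id_col)
    ids = df[id_col].tolist()
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValueError(f"duplicate sample ids: {dupes}")
    records = []
    for _, row in df.iterrows():
        fields = {c: _unescape(row[c]) for c in df.columns if c != id_col}
        records.append(SampleRecord(
            sample_id=row[id_col],
            fields=fields,
            platform=fields.get("platform") or fields.get("platform_id") or None,
            experiment_type=(fields.get("experiment_type")
                             or fields.get("library_strategy") or None),
        ))
    return records


def write_metadata(records: list[SampleRecord], path) -> None:
    columns = list(EXPECTED_FIELDS)
    extra = sorted({k for r in records for k in r.fields} - set(columns))
    columns += extra
    rows = [{"sample_id": r.sample_id,
             **{c: _escape(r.fields.get(c, "")) for c in columns}}
            for r in records]
    pd.DataFrame(rows, columns=["sample_id"] + columns).to_csv(path, sep="\t", index=False)


def filter_samples(records: list[SampleRecord], organism: str | None = None,
                   experiment_type: str | None = None,
                   platform: str | None = None) -> list[SampleRecord]:
    """Case-insensitive exact-match filtering on the provided attributes;
    omitted attributes pass everything through.  Order-preserving and
    idempotent."""

    def match(value: str | None, wanted: str | None) -> bool:
        if wanted is None:
            return True
        return (value or "").strip().casefold() == wanted.strip().casefold()

    return [r for r in records
            if match(r.organism, organism)
            and match(r.experiment_type, experiment_type)
            and match(r.platform, platform)]


# -- ontology writer ---------------------------------------------------------

def write_obo(graph: OntologyGraph, path) -> None:
    """Write an OBO v1.2 flat file; deterministic term/edge ordering so a
    parse -> write -> parse round trip preserves concepts, edges and the
    synonym multiset.  Converted part-of edges are written back as
    ``relationship: part_of``."""
    lines = ["format-version: 1.2", ""]
    by_child: dict[str, list[tuple[str, str]]] = {}
    for child, parent, rel in sorted(graph.edges):
        by_child.setdefault(child, []).append((parent, rel))
    for cid in sorted(graph.concepts):
        c = graph.concepts[cid]
        lines.append("[Term]")
        lines.append(f"id: {c.id}")
        if c.name:
            lines.append(f"name: {c.name}")
        if c.namespace:
            lines.append(f"namespace: {c.namespace}")
        for text, scope in c.synonyms:
            escaped = text.replace('"', '\\"')
            lines.append(f'synonym: "{escaped}" {scope} []')
        for parent, rel in by_child.get(cid, []):
            if rel == "is_a":
                lines.append(f"is_a: {parent}")
            elif rel == "part_of_converted":
                lines.append("relationship: part_of " + parent)
            else:
                lines.append(f"relationship: {rel} {parent}")
        if c.obsolete:
            lines.append("is_obsolete: true")
        lines.append("")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines))


# -- score matrices ----------------------------------------------------------

def read_scores(path, bed_path=None) -> ScoreMatrix:
    """Read a unit x sample TSV (first column = unit id, header = sample
    ids); optionally attach unit coordinates from a BED file keyed by the
    name column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    coords = read_bed(bed_path).set_index("name") if bed_path else None
    return ScoreMatrix(df, coords)


def write_scores(scores: ScoreMatrix, path) -> None:
    scores.values.to_csv(path, sep="\t", index_label="unit_id")


def read_bed(path) -> pd.DataFrame:
    """Read a BED file (3+3 columns, 0-based half-open) into a DataFrame
    with columns chrom/start/end/name/score/strand (missing optional
    columns filled with defaults)."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(names)]
    df.columns = names[: df.shape[1]]
    for col, default in (("name", ""), ("score", 0), ("strand", ".")):
        if col not in df.columns:
            df[col] = default
    return df


def write_bed(coords: pd.DataFrame, path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name", "score", "strand")
            if c in coords.columns]
    coords[cols].to_csv(path, sep="\t", header=False, index=False)


# -- annotations and semantic sets -------------------------------------------

def write_annotations(annotations: list[Annotation], path) -> None:
    rows = [{"sample_id": a.sample_id, "field": a.field,
             "concept_id": a.concept_id, "concept_name": a.concept_name,
             "matched_text": _escape(a.matched_text),
             "start": a.start, "end": a.end} for a in annotations]
    pd.DataFrame(rows, columns=["sample_id", "field", "concept_id", "concept_name",
                                "matched_text", "start", "end"]
                 ).to_csv(path, sep="\t", index=False)


def read_annotations(path) -> list[Annotation]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, keep_default_na=False)
    return [Annotation(str(r.sample_id), str(r.concept_id), str(r.concept_name),
                       _unescape(str(r.matched_text)), str(r.field),
                       int(r.start), int(r.end))
            for r in df.itertuples()]


def write_similarity(matrix: SampleSimilarityMatrix, path) -> None:
    matrix.to_dataframe().to_csv(path, sep="\t", index_label="id")


def read_similarity(path) -> SampleSimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return SampleSimilarityMatrix(list(df.index), df.to_numpy())


def write_sets(sets: list[SemanticSet], path) -> None:
    rows = [{"set_id": f"S{i}",
             "sample_ids": ",".join(s.sample_ids),
             "concept_ids": ",".join(sorted(s.concept_ids)),
             "label": _escape(s.label)} for i, s in enumerate(sets)]
    pd.DataFrame(rows, columns=["set_id", "sample_ids", "concept_ids", "label"]
                 ).to_csv(path, sep="\t", index=False)


def read_sets(path) -> list[SemanticSet]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [SemanticSet(r.sample_ids.split(","),
                        frozenset(r.concept_ids.split(",")),
                        _unescape(r.label))
            for r in df.itertuples()]
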