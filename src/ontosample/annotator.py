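"""Dictionary-lookup named entity recognition over sample metadata.

The pipeline follows the classic Conceptmapper-style stages: sentence
detection, tokenization, optional Porter stemming and stop-word removal,
then n-gram lookup of dictionary variants inside each sentence.  Matching is
configurable along the usual axes — all matches versus longest-only,
overlap allowance, ordered tokens versus permutations — and the per-sample
results deduplicate into *semantic sets*: the set of unique ontology
concepts associated with one sample.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass

from ontosample._porter import stem as porter_stem
from ontosample._stopwords import DEFAULT_STOPWORDS
from ontosample.lexicon import ConceptDictionary, normalize_case

logger = logging.getLogger(__name__)

#: metadata columns annotated by default (the informative GEO-style fields)
DEFAULT_FIELDS = ("title", "summary", "source_name_ch1",
                  "characteristics_ch1", "description")

_TOKEN_RE = re.compile(r"[0-9A-Za-z]+")

#: tokens before a period that do not end a sentence
_ABBREVIATIONS = frozenset({
    "e.g", "i.e", "etc", "vs", "cf", "al", "dr", "st", "no", "fig",
    "approx", "resp", "spp", "subsp", "ca",
})


@dataclass
class AnnotatorConfig:
    """Configuration of the lookup pipeline.

    ``find_all=False`` keeps only maximal non-overlapping matches (ties:
    earliest start, then longer span, then smallest concept id).
    ``order_independent=True`` matches any permutation of a variant's tokens
    within a window exactly as long as the variant.  ``allow_overlap``
    applies in find-all mode: when False, matches strictly contained in a
    longer match are suppressed.
    """

    stemmer: str = "none"            # "none" | "porter"
    stopwords: str = "none"          # "none" | "default"
    order_independent: bool = False
    find_all: bool = False
    allow_overlap: bool = False
    fields: tuple[str, ...] = DEFAULT_FIELDS

    def __post_init__(self):
        if self.stemmer not in ("none", "porter"):
            raise ValueError(f"unknown stemmer: {self.stemmer!r}")
        if self.stopwords not in ("none", "default"):
            raise ValueError(f"unknown stopword option: {self.stopwords!r}")


@dataclass(frozen=True)
class Annotation:
    """One concept mention located in one metadata field of one sample."""

    sample_id: str
    concept_id: str
    concept_name: str
    matched_text: str
    field: str
    start: int
    end: int

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class SemanticSet:
    """Unique ontology concepts associated with one sample, or with a
    collapsed group of samples."""

    sample_ids: list[str]
    concept_ids: frozenset[str]
    label: str = ""

    def __post_init__(self):
        if not self.sample_ids:
            raise ValueError("semantic set needs at least one sample")
        self.concept_ids = frozenset(self.concept_ids)
        if not self.concept_ids:
            raise ValueError("semantic set needs at least one concept")


def split_sentences(text: str) -> list[tuple[str, int]]:
    """Split text into ``(sentence, offset)`` pairs.

    Boundaries are periods, semicolons and newlines; a period does not split
    when the preceding token is a single letter or a known abbreviation
    (so ``"E. coli culture."`` stays one sentence).  Each returned sentence
    ``s`` at offset ``o`` satisfies ``text[o:o+len(s)] == s``.
    """
    if not text:
        return []
    boundaries = [0]
    for i, ch in enumerate(text):
        if ch in ";\n":
            boundaries.append(i + 1)
        elif ch == ".":
            if i + 1 < len(text) and not text[i + 1].isspace():
                continue
            before = text[:i]
            m = re.search(r"[0-9A-Za-z.\-]+$", before)
            token = (m.group(0) if m else "").lower().lstrip(".")
            if len(token) == 1 and token.isalpha():
                continue
            if token.rstrip(".") in _ABBREVIATIONS or token in _ABBREVIATIONS:
                continue
            boundaries.append(i + 1)
    boundaries.append(len(text))
    sentences = []
    for a, b in zip(boundaries, boundaries[1:]):
        chunk = text[a:b]
        stripped = chunk.strip()
        if not stripped:
            continue
        offset = a + chunk.index(stripped[0])
        sentences.append((text[offset:offset + len(stripped)], offset))
    return sentences


def tokenize(text: str, case_policy: str = "insensitive") -> list[tuple[str, tuple[int, int]]]:
    """Maximal alphanumeric runs with character spans; hyphens and
    underscores act as separators.  Tokens are case-normalized per policy,
    spans always index the original text."""
    return [(normalize_case(m.group(0), case_policy), (m.start(), m.end()))
            for m in _TOKEN_RE.finditer(text)]


class _CompiledDictionary:
    """Variant token sequences indexed for contiguous (and optionally
    order-independent) lookup, with stemming/stop-word transforms applied at
    compile time to mirror the text-side transforms."""

    def __init__(self, dictionary: ConceptDictionary, config: AnnotatorConfig):
        self.dictionary = dictionary
        self.case_policy = dictionary.build_config.case_policy
        self.config = config
        stops = DEFAULT_STOPWORDS if config.stopwords == "default" else frozenset()
        self.ordered: dict[tuple[str, ...], set[str]] = defaultdict(set)
        self.unordered: dict[tuple[str, ...], set[str]] = defaultdict(set)
        self.lengths: set[int] = set()
        for entry in dictionary.entries:
            for variant in entry.variants:
                tokens = [t for t, _ in tokenize(variant, self.case_policy)]
                if config.stemmer == "porter":
                    tokens = [porter_stem(t) for t in tokens]
                if stops:
                    kept = [t for t in tokens if t not in stops]
                    # a variant must retain at least one token
                    tokens = kept if kept else tokens
                if not tokens:
                    continue
                key = tuple(tokens)
                self.ordered[key].add(entry.concept_id)
                if config.order_independent:
                    self.unordered[tuple(sorted(key))].add(entry.concept_id)
                self.lengths.add(len(key))

    def lookup(self, seq: tuple[str, ...]) -> set[str]:
        hits = set(self.ordered.get(seq, ()))
        if self.config.order_independent:
            hits |= self.unordered.get(tuple(sorted(seq)), set())
        return hits


def _field_matches(text: str, sample_id: str, fieldname: str,
                   compiled: _CompiledDictionary) -> set[Annotation]:
    config = compiled.config
    stops = DEFAULT_STOPWORDS if config.stopwords == "default" else frozenset()
    out: set[Annotation] = set()
    for sentence, offset in split_sentences(text):
        toks = tokenize(sentence, compiled.case_policy)
        if config.stemmer == "porter":
            toks = [(porter_stem(t), sp) for t, sp in toks]
        if stops:
            toks = [(t, sp) for t, sp in toks if t not in stops]
        for length in sorted(compiled.lengths):
            if length > len(toks):
                break
            for i in range(len(toks) - length + 1):
                window = toks[i:i + length]
                hits = compiled.lookup(tuple(t for t, _ in window))
                if not hits:
                    continue
                start = offset + window[0][1][0]
                end = offset + window[-1][1][1]
                for cid in hits:
                    out.add(Annotation(sample_id, cid,
                                       compiled.dictionary.name_of(cid),
                                       text[start:end], fieldname, start, end))
    return out


def _suppress_contained(matches: set[Annotation]) -> set[Annotation]:
    spans = {(a.start, a.end) for a in matches}
    kept = set()
    for a in matches:
        contained = any(s <= a.start and a.end <= e and (s, e) != (a.start, a.end)
                        for s, e in spans)
        if not contained:
            kept.add(a)
    return kept


def _longest_only(matches: set[Annotation]) -> list[Annotation]:
    chosen: list[Annotation] = []
    for a in sorted(matches, key=lambda a: (a.start, -(a.end - a.start), a.concept_id)):
        if all(a.end <= c.start or a.start >= c.end for c in chosen):
            chosen.append(a)
    return chosen


def annotate(documents, dictionary: ConceptDictionary,
             config: AnnotatorConfig | None = None) -> list[Annotation]:
    """Run the lookup pipeline over sample metadata records.

    ``documents`` is an iterable of :class:`~ontosample.metaio.SampleRecord`
    or of ``(sample_id, {field: text})`` mappings.  Every dictionary variant
    whose (transformed) token sequence occurs in a sentence is reported;
    duplicated annotations (same sample, field, concept and span, e.g. found
    through two variants) are removed.  Output order is deterministic:
    by sample, field, start, end, concept id.
    """
    config = config or AnnotatorConfig()
    compiled = _CompiledDictionary(dictionary, config)
    annotations: list[Annotation] = []
    for doc in documents:
        if hasattr(doc, "sample_id") and hasattr(doc, "fields"):
            sample_id, fields = doc.sample_id, doc.fields
        else:
            sample_id, fields = doc
        for fieldname in config.fields:
            if fieldname not in fields:
                raise ValueError(
                    f"field {fieldname!r} not present in record {sample_id!r}")
            text = fields[fieldname] or ""
            matches = _field_matches(text, sample_id, fieldname, compiled)
            if config.find_all:
                if not config.allow_overlap:
                    matches = _suppress_contained(matches)
                annotations.extend(matches)
            else:
                annotations.extend(_longest_only(matches))
    annotations.sort(key=lambda a: (a.sample_id, a.field, a.start, a.end, a.concept_id))
    return annotations


def filter_generic(annotations: list[Annotation],
                   stoplist: set[str]) -> list[Annotation]:
    """Drop annotations of generic/uninformative concepts.

    ``stoplist`` may contain concept ids or concept names (names compared
    case-insensitively).  The number removed is logged.
    """
    lowered = {s.casefold() for s in stoplist}
    kept = [a for a in annotations
            if a.concept_id not in stoplist
            and a.concept_name.casefold() not in lowered]
    removed = len(annotations) - len(kept)
    if removed:
        logger.info("filter_generic: removed %d annotation(s)", removed)
    return kept


def to_semantic_sets(annotations: list[Annotation],
                     all_sample_ids: list[str] | None = None,
                     ) -> tuple[dict[str, SemanticSet], list[str]]:
    """Deduplicate annotations into one semantic set per annotated sample.

    Returns ``(sets, unannotated)``; ``unannotated`` lists the ids from
    ``all_sample_ids`` (if given) that received no annotation.
    """
    concepts: dict[str, set[str]] = defaultdict(set)
    names: dict[str, str] = {}
    for a in annotations:
        concepts[a.sample_id].add(a.concept_id)
        names[a.concept_id] = a.concept_name
    sets = {}
    for sample_id in sorted(concepts):
        cids = frozenset(concepts[sample_id])
        label = ", ".join(sorted(names.get(c, c) for c in cids))
        sets[sample_id] = SemanticSet([sample_id], cids, label)
    if all_sample_ids is None:
        unannotated: list[str] = []
    else:
        unannotated = [s for s in all_sample_ids if s not in sets]
    return sets, unannotated
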