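"""Compile ontologies and symbol tables into lookup dictionaries.

A dictionary entry pairs a concept with its canonical name and a set of
variants (the canonical plus any synonyms whose scope was requested).  The
compiled dictionary can be serialized to a small XML dialect so it can be
inspected or exchanged with Conceptmapper-style annotators:

.. code-block:: xml

    <conceptDictionary source="tissue.obo" scopes="BROAD,EXACT,NARROW,RELATED"
                       case="insensitive" includeObsolete="false">
      <token id="T:3" canonical="breast epithelium">
        <variant base="breast epithelium"/>
        <variant base="breast"/>
      </token>
    </conceptDictionary>

One ``token`` element per entry (attribute ``id`` = concept accession,
``canonical`` = canonical name), one ``variant`` child per variant string
(attribute ``base``).  The writer is canonical (entries sorted by id,
variants canonical-first then sorted), so write -> read -> write is
byte-identical.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from lxml import etree

from ontosample.ontology import SYNONYM_SCOPES, OntologyGraph

logger = logging.getLogger(__name__)

CASE_POLICIES = ("sensitive", "insensitive", "fold_digits")


def normalize_case(text: str, policy: str) -> str:
    """Apply a case policy: ``sensitive`` keeps text as-is, ``insensitive``
    casefolds, ``fold_digits`` lowercases letters while leaving digits
    untouched (relevant for symbols like ``H3K27ac``)."""
    if policy == "sensitive":
        return text
    if policy == "insensitive":
        return text.casefold()
    if policy == "fold_digits":
        return "".join(c.lower() if c.isalpha() else c for c in text)
    raise ValueError(f"unknown case policy: {policy!r}")


@dataclass
class DictionaryBuildConfig:
    """Which synonyms enter the dictionary and how case is normalized."""

    synonym_scopes: frozenset[str] = frozenset(SYNONYM_SCOPES)
    case_policy: str = "insensitive"
    include_obsolete: bool = False

    def __post_init__(self):
        scopes = frozenset(s.upper() for s in self.synonym_scopes)
        if not scopes:
            raise ValueError("synonym_scopes must be non-empty")
        unknown = scopes - set(SYNONYM_SCOPES)
        if unknown:
            raise ValueError(f"unknown synonym scopes: {sorted(unknown)}")
        object.__setattr__(self, "synonym_scopes", scopes)
        if self.case_policy not in CASE_POLICIES:
            raise ValueError(f"unknown case policy: {self.case_policy!r}")


@dataclass
class DictionaryEntry:
    concept_id: str
    canonical: str
    variants: list[str]

    def __post_init__(self):
        if not self.canonical or not self.canonical.strip():
            raise ValueError(f"entry {self.concept_id!r}: empty canonical name")
        self.variants = [v for v in self.variants if v.strip()]
        if not self.variants:
            raise ValueError(f"entry {self.concept_id!r}: no usable variants")


@dataclass
class ConceptDictionary:
    entries: list[DictionaryEntry]
    source: str = ""
    build_config: DictionaryBuildConfig = field(default_factory=DictionaryBuildConfig)

    def __post_init__(self):
        ids = [e.concept_id for e in self.entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate concept ids in dictionary: {dupes}")
        self._by_id = {e.concept_id: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, concept_id: str) -> DictionaryEntry:
        return self._by_id[concept_id]

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self._by_id

    def name_of(self, concept_id: str) -> str:
        return self._by_id[concept_id].canonical


def _dedupe(variants: list[str], policy: str) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for v in variants:
        norm = normalize_case(v, policy)
        if not norm.strip():
            continue
        if norm not in seen:
            seen.add(norm)
            out.append(norm if policy != "sensitive" else v)
    return out


def build_dictionary(graph: OntologyGraph,
                     config: DictionaryBuildConfig | None = None) -> ConceptDictionary:
    """One entry per (non-obsolete) concept: canonical name plus synonyms in
    the configured scopes, de-duplicated after case normalization."""
    config = config or DictionaryBuildConfig()
    entries = []
    for cid in sorted(graph.concepts):
        concept = graph.concepts[cid]
        if concept.obsolete and not config.include_obsolete:
            continue
        if not concept.name:
            logger.warning("skipping %s: no name", cid)
            continue
        variants = [concept.name] + [text for text, scope in concept.synonyms
                                     if scope in config.synonym_scopes]
        entries.append(DictionaryEntry(cid, concept.name,
                                       _dedupe(variants, config.case_policy)))
    if not entries:
        raise ValueError("ontology produced an empty dictionary")
    return ConceptDictionary(entries, source=graph.source or "", build_config=config)


_MARK_RE = re.compile(r"^(H\d+(?:\.\d+)?)([A-Za-z]\d+)([A-Za-z]+\d*)$", re.IGNORECASE)


def _mark_variants(symbol: str) -> list[str]:
    """Spelling variants for a histone-mark symbol.

    Rule: a symbol of shape <histone><residue+position><modification>
    (e.g. ``H3`` ``K27`` ``ac``) yields the joined form, the joined form with
    the modification capitalized, and the space-separated form.  Symbols not
    matching the shape yield only themselves.
    """
    m = _MARK_RE.match(symbol)
    if not m:
        return [symbol]
    h, res, mod = m.groups()
    return [symbol,
            f"{h}{res}{mod[0].upper()}{mod[1:]}",
            f"{h}{res}{mod.lower()}",
            f"{h} {res} {mod}"]


def build_symbol_dictionary(table, mark_mode: bool = False,
                            case_policy: str = "sensitive") -> ConceptDictionary:
    """Compile a gene / epigenetic-mark symbol table into a dictionary.

    ``table`` is a TSV path or DataFrame with columns ``symbol`` and
    ``aliases`` (pipe-separated, may be empty).  Duplicate symbols are merged
    with a warning.  In ``mark_mode`` each symbol additionally receives
    histone-mark spelling variants (see :func:`_mark_variants`).
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t", dtype=str, keep_default_na=False)
    table.columns = [c.strip().lower() for c in table.columns]
    if "symbol" not in table.columns:
        raise ValueError("symbol table needs a 'symbol' column")
    if len(table) == 0:
        raise ValueError("empty symbol table")
    merged: dict[str, list[str]] = {}
    for _, row in table.iterrows():
        symbol = str(row["symbol"]).strip()
        if not symbol:
            raise ValueError("symbol column contains an empty value")
        aliases = [a.strip() for a in str(row.get("aliases", "")).split("|") if a.strip()]
        if symbol in merged:
            logger.warning("duplicate symbol %r: merging aliases", symbol)
        merged.setdefault(symbol, [])
        merged[symbol].extend(aliases)
    entries = []
    for symbol in merged:
        variants = _mark_variants(symbol) if mark_mode else [symbol]
        variants = variants + merged[symbol]
        entries.append(DictionaryEntry(symbol, symbol, _dedupe(variants, case_policy)))
    config = DictionaryBuildConfig(case_policy=case_policy)
    return ConceptDictionary(entries, source="symbol-table", build_config=config)


def merge_dictionaries(dicts: list[ConceptDictionary]) -> ConceptDictionary:
    """Concatenate dictionaries built over different ontologies (e.g. a cell
    ontology extended with an anatomy ontology); colliding ids are rejected."""
    if not dicts:
        raise ValueError("nothing to merge")
    entries: list[DictionaryEntry] = []
    for d in dicts:
        entries.extend(d.entries)
    sources = ";".join(d.source for d in dicts if d.source)
    return ConceptDictionary(entries, source=sources, build_config=dicts[0].build_config)


def write_dictionary_xml(dictionary: ConceptDictionary, path) -> None:
    """Serialize to the XML dialect documented in the module docstring."""
    if not dictionary.entries:
        raise ValueError("refusing to write an empty dictionary")
    cfg = dictionary.build_config
    root = etree.Element("conceptDictionary")
    root.set("source", dictionary.source)
    root.set("scopes", ",".join(sorted(cfg.synonym_scopes)))
    root.set("case", cfg.case_policy)
    root.set("includeObsolete", "true" if cfg.include_obsolete else "false")
    for entry in sorted(dictionary.entries, key=lambda e: e.concept_id):
        tok = etree.SubElement(root, "token")
        tok.set("id", entry.concept_id)
        tok.set("canonical", entry.canonical)
        canon_norm = normalize_case(entry.canonical, cfg.case_policy)
        ordered = sorted(entry.variants, key=lambda v: (v != canon_norm and v != entry.canonical, v))
        for variant in ordered:
            etree.SubElement(tok, "variant").set("base", variant)
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)


def read_dictionary_xml(path) -> ConceptDictionary:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed dictionary XML: {exc}") from exc
    root = tree.getroot()
    if root.tag != "conceptDictionary":
        raise ValueError(f"unexpected root element at {tree.getpath(root)}")
    config = DictionaryBuildConfig(
        synonym_scopes=frozenset((root.get("scopes") or ",".join(SYNONYM_SCOPES)).split(",")),
        case_policy=root.get("case", "insensitive"),
        include_obsolete=root.get("includeObsolete") == "true",
    )
    entries = []
    for tok in root.iterfind("token"):
        cid = tok.get("id")
        canonical = tok.get("canonical")
        if cid is None or canonical is None:
            raise ValueError(f"token missing id/canonical at {tree.getpath(tok)}")
        variants = []
        for var in tok.iterfind("variant"):
            base = var.get("base")
            if base is None:
                raise ValueError(f"variant missing base at {tree.getpath(var)}")
            variants.append(base)
        entries.append(DictionaryEntry(cid, canonical, variants))
    if not entries:
        raise ValueError("dictionary XML contains no token elements")
    return ConceptDictionary(entries, source=root.get("source", ""), build_config=config)
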