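"""OBO ontology parsing, graph queries and intrinsic information content.

An ontology is modelled as a directed acyclic graph of concepts connected by
``is_a`` edges (child -> parent).  ``part_of`` edges, which are widespread in
anatomy ontologies, can be converted so that every traversal treats them as
``is_a``; all other relationship types are dropped at conversion time.

Information content (IC) quantifies concept specificity from the graph
topology alone (no annotation corpus needed), so it is defined for every OBO
ontology.  Three intrinsic estimators are provided; all are normalized to
[0, 1] with IC(root) = 0 and IC non-decreasing from ancestor to descendant.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

SYNONYM_SCOPES = ("EXACT", "BROAD", "NARROW", "RELATED")

#: relationship labels treated as hierarchy edges during traversal
TRAVERSAL_RELATIONS = ("is_a", "part_of_converted")

_SYNONYM_RE = re.compile(
    r'^"(?P<text>(?:[^"\\]|\\.)*)"'
    r"(?:\s+(?P<scope>EXACT|BROAD|NARROW|RELATED))?"
    r"(?:\s+\w+)?"  # optional synonym type name
    r"(?:\s*\[.*\])?\s*$"
)


class OboParseError(ValueError):
    """Raised for malformed OBO input; the message names the offending line."""


class OntologyCycleError(ValueError):
    """Raised when the is-a hierarchy contains a directed cycle."""

    def __init__(self, cycle: list[str]):
        self.cycle = list(cycle)
        super().__init__("cyclic is_a hierarchy: " + " -> ".join(self.cycle + [self.cycle[0]]))


@dataclass
class Concept:
    """One ontology term.

    ``synonyms`` is a list of ``(text, scope)`` pairs with scope one of the
    four OBO scopes (EXACT, BROAD, NARROW, RELATED).
    """

    id: str
    name: str = ""
    synonyms: list[tuple[str, str]] = field(default_factory=list)
    obsolete: bool = False
    namespace: str | None = None


class OntologyGraph:
    """A concept DAG with scoped synonyms and normalized hierarchy edges.

    Parameters
    ----------
    concepts : mapping of concept id to :class:`Concept`.
    edges : set of ``(child_id, parent_id, relation)`` triples.  Only
        ``is_a`` and ``part_of_converted`` edges participate in traversal;
        other relations (``part_of`` before conversion, ``develops_from``,
        ...) are carried but inert.
    """

    def __init__(self, concepts: Mapping[str, Concept], edges: Iterable[tuple[str, str, str]],
                 source: str | None = None):
        self.concepts: dict[str, Concept] = dict(concepts)
        self.edges: set[tuple[str, str, str]] = set(edges)
        self.source = source
        self._validate()
        self._traversal_graph: nx.DiGraph | None = None
        self._ancestor_cache: dict[str, frozenset[str]] = {}
        self._descendant_cache: dict[str, frozenset[str]] = {}

    def _validate(self) -> None:
        dangling = [(c, p, r) for c, p, r in self.edges
                    if c not in self.concepts or p not in self.concepts]
        if dangling:
            logger.warning("dropping %d edge(s) referencing unknown concepts", len(dangling))
            self.edges -= set(dangling)
        dag = nx.DiGraph()
        dag.add_nodes_from(self._active_ids())
        dag.add_edges_from((c, p) for c, p, r in self.edges
                           if r in TRAVERSAL_RELATIONS and not self.concepts[c].obsolete
                           and not self.concepts[p].obsolete)
        try:
            cycle = nx.find_cycle(dag)
        except nx.NetworkXNoCycle:
            return
        raise OntologyCycleError([edge[0] for edge in cycle])

    # -- basic queries ---------------------------------------------------

    def _active_ids(self) -> list[str]:
        return [cid for cid, c in self.concepts.items() if not c.obsolete]

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, cid: str) -> bool:
        return cid in self.concepts

    @property
    def traversal(self) -> nx.DiGraph:
        """Child -> parent digraph over is-a (and converted part-of) edges."""
        if self._traversal_graph is None:
            g = nx.DiGraph()
            g.add_nodes_from(self._active_ids())
            g.add_edges_from((c, p) for c, p, r in self.edges
                             if r in TRAVERSAL_RELATIONS
                             and not self.concepts[c].obsolete
                             and not self.concepts[p].obsolete)
            self._traversal_graph = g
        return self._traversal_graph

    @property
    def roots(self) -> list[str]:
        """Non-obsolete concepts with no parent edge, sorted by id."""
        g = self.traversal
        return sorted(n for n in g.nodes if g.out_degree(n) == 0)

    def _check_active(self, cid: str) -> None:
        if cid not in self.concepts:
            raise KeyError(f"unknown concept id: {cid!r}")
        if self.concepts[cid].obsolete:
            raise ValueError(f"concept {cid!r} is obsolete and excluded from traversal")

    def ancestors(self, cid: str) -> frozenset[str]:
        """Reflexive transitive closure of the is-a hierarchy above ``cid``."""
        self._check_active(cid)
        cached = self._ancestor_cache.get(cid)
        if cached is None:
            cached = frozenset(nx.descendants(self.traversal, cid)) | {cid}
            self._ancestor_cache[cid] = cached
        return cached

    def descendants(self, cid: str) -> frozenset[str]:
        """Reflexive transitive closure below ``cid``."""
        self._check_active(cid)
        cached = self._descendant_cache.get(cid)
        if cached is None:
            cached = frozenset(nx.ancestors(self.traversal, cid)) | {cid}
            self._descendant_cache[cid] = cached
        return cached

    def depth(self, cid: str) -> int:
        """1-based length of the longest root-to-concept path."""
        self._check_active(cid)
        order = nx.topological_sort(nx.reverse_view(self.traversal))
        depth: dict[str, int] = {}
        for node in order:  # parents before children in reversed view
            parents = list(self.traversal.successors(node))
            depth[node] = 1 if not parents else 1 + max(depth[p] for p in parents)
        return depth[cid]


def parse_obo(path) -> OntologyGraph:
    """Parse an OBO v1.2 flat file into an :class:`OntologyGraph`.

    Captures id, name, namespace, scoped synonyms, ``is_a`` and
    ``relationship:`` edges, and the obsolete flag.  Obsolete terms are
    retained but never traversed.  OWL input is rejected.

    Raises
    ------
    OboParseError
        On malformed stanzas; the message names the line number.
    OntologyCycleError
        If the is-a hierarchy is cyclic.
    """
    path = str(path)
    if path.endswith((".owl", ".rdf")):
        raise OboParseError(
            "OWL input is not supported; supply an OBO v1.2 flat file")
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()

    concepts: dict[str, Concept] = {}
    edges: set[tuple[str, str, str]] = set()

    in_term = False
    ignored_stanza = False
    cur: Concept | None = None
    cur_line = 0

    def _flush():
        nonlocal cur
        if cur is None:
            return
        if not cur.id:
            raise OboParseError(f"[Term] stanza starting at line {cur_line} has no id")
        if cur.id in concepts:
            raise OboParseError(f"duplicate term id {cur.id!r} at line {cur_line}")
        concepts[cur.id] = cur
        cur = None

    n_terms = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("!", 1)[0].rstrip() if not raw.lstrip().startswith("!") else ""
        # '!' inside quoted synonym text must survive comment stripping
        if raw.count('"') >= 2 and raw.split(":", 1)[0].strip() == "synonym":
            line = raw.rstrip()
        if not line.strip():
            continue
        if line.startswith("["):
            _flush()
            if line.strip() == "[Term]":
                in_term, ignored_stanza = True, False
                cur = Concept(id="")
                cur_line = lineno
                n_terms += 1
            else:
                in_term, ignored_stanza = False, True
            continue
        if ignored_stanza or not in_term:
            continue  # header or [Typedef] content
        if ":" not in line:
            raise OboParseError(f"malformed line {lineno}: {raw!r} (expected 'tag: value')")
        tag, value = line.split(":", 1)
        tag = tag.strip()
        value = value.strip()
        assert cur is not None
        if tag == "id":
            cur.id = value
        elif tag == "name":
            cur.name = value
        elif tag == "namespace":
            cur.namespace = value
        elif tag == "is_obsolete":
            cur.obsolete = value.lower() == "true"
        elif tag == "synonym":
            m = _SYNONYM_RE.match(value)
            if not m:
                raise OboParseError(f"malformed synonym at line {lineno}: {raw!r}")
            text = m.group("text").replace('\\"', '"')
            scope = m.group("scope") or "RELATED"
            cur.synonyms.append((text, scope))
        elif tag == "is_a":
            parent = value.split("!", 1)[0].strip()
            if not parent:
                raise OboParseError(f"empty is_a target at line {lineno}")
            edges.add((cur.id, parent, "is_a"))
        elif tag == "relationship":
            parts = value.split("!", 1)[0].split()
            if len(parts) < 2:
                raise OboParseError(f"malformed relationship at line {lineno}: {raw!r}")
            rel, parent = parts[0], parts[1]
            edges.add((cur.id, parent, rel))
        # other tags (def, xref, subset, ...) are ignored
    _flush()

    if n_terms == 0:
        raise OboParseError(f"no [Term] stanza found in {path}")

    # edges may be recorded before their subject id is known; fix child ids
    # recorded as "" (term whose id line came after is_a — not valid OBO, but
    # guard anyway)
    edges = {(c, p, r) for c, p, r in edges if c}
    return OntologyGraph(concepts, edges, source=path)


def convert_part_of(graph: OntologyGraph) -> OntologyGraph:
    """Return a graph in which ``part_of`` edges behave as ``is_a``.

    ``part_of`` edges are re-labelled ``part_of_converted``; every other
    non-is-a relation (``develops_from``, ...) is dropped with a logged
    count.  Idempotent: converting twice equals converting once.
    """
    converted: set[tuple[str, str, str]] = set()
    dropped = 0
    for child, parent, rel in graph.edges:
        if rel in ("is_a", "part_of_converted"):
            converted.add((child, parent, rel))
        elif rel == "part_of":
            converted.add((child, parent, "part_of_converted"))
        else:
            dropped += 1
    if dropped:
        logger.info("convert_part_of: dropped %d non-hierarchy edge(s)", dropped)
    return OntologyGraph(graph.concepts, converted, source=graph.source)


def ancestors(graph: OntologyGraph, cid: str) -> frozenset[str]:
    """Reflexive set of ancestors of ``cid`` (includes ``cid`` itself)."""
    return graph.ancestors(cid)


@dataclass
class ICTable:
    """Intrinsic information content per concept, normalized to [0, 1]."""

    method: str
    values: dict[str, float]

    def __getitem__(self, cid: str) -> float:
        return self.values[cid]

    def __contains__(self, cid: str) -> bool:
        return cid in self.values


def information_content(graph: OntologyGraph, method: str = "seco") -> ICTable:
    """Compute intrinsic IC for every non-obsolete concept.

    Methods
    -------
    ``seco``
        ``IC(c) = 1 - log(hypo(c) + 1) / log(N)`` where ``hypo(c)`` counts
        strict descendants and ``N`` is the number of non-obsolete concepts.
        Roots score 0, leaves score 1.
    ``sanchez``
        ``-log((|leaves(c)| / |subsumers(c)| + 1) / (L + 1))`` with ``L`` the
        total leaf count, rescaled by its maximum so values span [0, 1].
    ``zhou``
        Equal-weight blend of the SECO term and a depth term
        ``log(depth(c)) / log(max_depth)``.

    A single-concept ontology has no topology to measure; IC is defined as 0
    everywhere with a warning.
    """
    method = method.lower()
    if method not in ("seco", "sanchez", "zhou"):
        raise ValueError(f"unknown IC method: {method!r}")
    active = graph._active_ids()
    n = len(active)
    if n == 0:
        raise ValueError("empty ontology")
    if n == 1:
        logger.warning("single-concept ontology: IC defined as 0")
        return ICTable(method, {active[0]: 0.0})

    hypo = {c: len(graph.descendants(c)) - 1 for c in active}

    if method == "seco":
        values = {c: 1.0 - math.log(hypo[c] + 1) / math.log(n) for c in active}
        return ICTable(method, values)

    if method == "sanchez":
        leaves = {c for c in active if hypo[c] == 0}
        raw = {}
        for c in active:
            leaf_desc = len(graph.descendants(c) & leaves) or 1
            subsumers = len(graph.ancestors(c))
            raw[c] = -math.log((leaf_desc / subsumers + 1) / (len(leaves) + 1))
        top = max(raw.values())
        values = {c: (raw[c] / top if top > 0 else 0.0) for c in active}
        return ICTable(method, values)

    # zhou: blend of descendant-count and depth specificity
    order = list(nx.topological_sort(nx.reverse_view(graph.traversal)))
    depth: dict[str, int] = {}
    for node in order:
        parents = list(graph.traversal.successors(node))
        depth[node] = 1 if not parents else 1 + max(depth[p] for p in parents)
    max_depth = max(depth.values())
    values = {}
    for c in active:
        seco_term = 1.0 - math.log(hypo[c] + 1) / math.log(n)
        depth_term = (math.log(depth[c]) / math.log(max_depth)) if max_depth > 1 else 0.0
        values[c] = 0.5 * seco_term + 0.5 * depth_term
    return ICTable(method, values)
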