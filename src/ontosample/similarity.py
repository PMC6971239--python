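"""Semantic similarity between concepts and between samples' semantic sets.

Pairwise measures are built on the most informative common ancestor (MICA):
Resnik returns IC(MICA); Lin normalizes it by the concepts' own IC;
Jiang-Conrath turns the IC distance into a similarity ``1 / (1 + d)``;
edge-based Rada uses the shortest path through a common ancestor.  Group-wise
similarity lifts a pairwise measure to concept sets (best-match average by
default), multiple ontologies combine element-wise, and samples collapse into
semantically homogeneous clusters by cutting an agglomerative tree on
``1 - similarity`` at ``1 - threshold``.
"""

from __future__ import annotations

import logging
from collections import Counter, deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ontosample.annotator import SemanticSet
from ontosample.ontology import ICTable, OntologyGraph

logger = logging.getLogger(__name__)

PAIRWISE_MEASURES = ("resnik", "lin", "jiang_conrath", "edge_rada")
GROUPWISE_STRATEGIES = ("bma", "max", "average", "min")
LINKAGES = ("average", "complete", "single")


@dataclass
class SimilarityConfig:
    measure: str = "lin"
    groupwise: str = "bma"
    ic: ICTable | None = None

    def __post_init__(self):
        if self.measure not in PAIRWISE_MEASURES:
            raise ValueError(f"unknown pairwise measure: {self.measure!r}")
        if self.groupwise not in GROUPWISE_STRATEGIES:
            raise ValueError(f"unknown groupwise strategy: {self.groupwise!r}")


@dataclass
class CollapseConfig:
    threshold: float = 0.9
    linkage: str = "average"

    def __post_init__(self):
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("collapse threshold must be in [0, 1]")
        if self.linkage not in LINKAGES:
            raise ValueError(f"unknown linkage: {self.linkage!r}")


@dataclass
class SampleSimilarityMatrix:
    """Symmetric similarity matrix over semantic sets or samples."""

    ids: list[str]
    values: np.ndarray
    ontology_sources: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def _check_concepts(graph: OntologyGraph, *cids: str) -> None:
    for c in cids:
        if c not in graph.concepts:
            raise KeyError(f"unknown concept id: {c!r}")
        if graph.concepts[c].obsolete:
            raise ValueError(f"concept {c!r} is obsolete")


def mica(graph: OntologyGraph, ic: ICTable, c1: str, c2: str) -> str | None:
    """Most informative common ancestor; ties broken by maximal IC then
    smallest id.  ``None`` when the concepts share no ancestor (possible in
    multi-root ontologies)."""
    common = graph.ancestors(c1) & graph.ancestors(c2)
    if not common:
        return None
    return min(common, key=lambda a: (-ic[a], a))


def _updistances(graph: OntologyGraph, cid: str) -> dict[str, int]:
    """Shortest edge distance from ``cid`` up to each of its ancestors."""
    dist = {cid: 0}
    queue = deque([cid])
    while queue:
        node = queue.popleft()
        for parent in graph.traversal.successors(node):
            if parent not in dist:
                dist[parent] = dist[node] + 1
                queue.append(parent)
    return dist


def pairwise_similarity(graph: OntologyGraph, ic: ICTable, c1: str, c2: str,
                        measure: str = "lin") -> float:
    """Similarity between two concepts of the same ontology graph.

    Disconnected pairs (no common ancestor) score 0 with a warning.  Lin's
    0/0 case (two roots) is defined as 1 for identical concepts, else 0.
    """
    if measure not in PAIRWISE_MEASURES:
        raise ValueError(f"unknown pairwise measure: {measure!r}")
    _check_concepts(graph, c1, c2)
    m = mica(graph, ic, c1, c2)
    if m is None:
        logger.warning("concepts %s and %s share no ancestor; similarity 0", c1, c2)
        return 0.0
    ic_m = ic[m]
    if measure == "resnik":
        return ic_m
    if measure == "lin":
        denom = ic[c1] + ic[c2]
        if denom == 0.0:
            return 1.0 if c1 == c2 else 0.0
        return 2.0 * ic_m / denom
    if measure == "jiang_conrath":
        return 1.0 / (1.0 + ic[c1] + ic[c2] - 2.0 * ic_m)
    # edge_rada: shortest path joining the concepts through a common ancestor
    d1 = _updistances(graph, c1)
    d2 = _updistances(graph, c2)
    path = min(d1[a] + d2[a] for a in d1.keys() & d2.keys())
    return 1.0 / (1.0 + path)


def groupwise_similarity(graph: OntologyGraph, ic: ICTable,
                         set_a, set_b, measure: str = "lin",
                         strategy: str = "bma",
                         _cache: dict | None = None) -> float:
    """Similarity between two non-empty concept sets.

    ``bma`` (best-match average) is
    ``(mean_a max_b sim(a, b) + mean_b max_a sim(a, b)) / 2``; ``max``,
    ``average`` and ``min`` aggregate over all cross pairs.  Symmetric by
    construction.
    """
    set_a, set_b = sorted(set_a), sorted(set_b)
    if not set_a or not set_b:
        raise ValueError("group-wise similarity of an empty concept set")
    cache = _cache if _cache is not None else {}

    def sim(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in cache:
            cache[key] = pairwise_similarity(graph, ic, a, b, measure)
        return cache[key]

    cross = np.array([[sim(a, b) for b in set_b] for a in set_a])
    if strategy == "max":
        return float(cross.max())
    if strategy == "min":
        return float(cross.min())
    if strategy == "average":
        return float(cross.mean())
    if strategy == "bma":
        return float((cross.max(axis=1).mean() + cross.max(axis=0).mean()) / 2.0)
    raise ValueError(f"unknown groupwise strategy: {strategy!r}")


def sample_similarity_matrix(semantic_sets: dict[str, SemanticSet] | list[SemanticSet],
                             graph: OntologyGraph,
                             config: SimilarityConfig | None = None,
                             ic: ICTable | None = None) -> SampleSimilarityMatrix:
    """All pairwise group-wise similarities between semantic sets.

    Accepts either a mapping ``id -> SemanticSet`` or a list of sets (ids
    then default to the sets' first sample id).
    """
    from ontosample.ontology import information_content

    config = config or SimilarityConfig()
    ic = ic or config.ic or information_content(graph)
    if isinstance(semantic_sets, dict):
        ids = list(semantic_sets)
        sets = [semantic_sets[i] for i in ids]
    else:
        sets = list(semantic_sets)
        ids = [s.sample_ids[0] for s in sets]
    if len(sets) < 2:
        raise ValueError("need at least two semantic sets")
    unknown = sorted({c for s in sets for c in s.concept_ids
                      if c not in graph.concepts or graph.concepts[c].obsolete})
    if unknown:
        raise KeyError(f"semantic sets reference unknown/obsolete concepts: {unknown}")
    n = len(sets)
    values = np.empty((n, n))
    cache: dict = {}
    for i in range(n):
        for j in range(i, n):
            v = groupwise_similarity(graph, ic, sets[i].concept_ids,
                                     sets[j].concept_ids, config.measure,
                                     config.groupwise, _cache=cache)
            values[i, j] = values[j, i] = v
    return SampleSimilarityMatrix(ids, values,
                                  ontology_sources=[graph.source or ""])


def combine_ontologies(matrices: list[SampleSimilarityMatrix],
                       aggregator=None) -> SampleSimilarityMatrix:
    """Element-wise aggregation (default mean) of similarity matrices
    computed over the same samples from different ontologies."""
    if not matrices:
        raise ValueError("no matrices to combine")
    ref_ids = matrices[0].ids
    stacked = []
    for m in matrices:
        if set(m.ids) != set(ref_ids):
            raise ValueError("matrices cover different ids")
        order = [m.ids.index(i) for i in ref_ids]
        stacked.append(m.values[np.ix_(order, order)])
    arr = np.stack(stacked)
    combined = np.mean(arr, axis=0) if aggregator is None else np.apply_along_axis(aggregator, 0, arr)
    combined = (combined + combined.T) / 2.0  # guard against asymmetric aggregators
    sources = [s for m in matrices for s in m.ontology_sources]
    return SampleSimilarityMatrix(ref_ids, combined, ontology_sources=sources)


def collapse(semantic_sets: list[SemanticSet],
             matrix: SampleSimilarityMatrix,
             config: CollapseConfig | None = None,
             graph: OntologyGraph | None = None) -> list[SemanticSet]:
    """Merge semantic sets whose similarity exceeds the threshold.

    Agglomerative clustering on distance ``1 - sim`` with the configured
    linkage, tree cut at ``1 - threshold``.  A merged set's concepts are the
    union; its label lists each concept with the number of member samples
    annotated with it in square brackets, e.g. ``"breast [8], epithelium [11]"``.
    """
    config = config or CollapseConfig()
    sets = list(semantic_sets)
    if len(sets) != len(matrix.ids):
        raise ValueError("matrix does not cover the given semantic sets")
    if len(sets) == 1:
        labels = np.array([1])
    else:
        dist = np.clip(1.0 - matrix.values, 0.0, None)
        np.fill_diagonal(dist, 0.0)
        condensed = squareform(dist, checks=False)
        tree = linkage(condensed, method=config.linkage)
        labels = fcluster(tree, t=1.0 - config.threshold + 1e-9, criterion="distance")

    def concept_name(cid: str) -> str:
        if graph is not None and cid in graph.concepts and graph.concepts[cid].name:
            return graph.concepts[cid].name
        return cid

    merged: list[SemanticSet] = []
    for lab in sorted(set(labels)):
        members = [sets[i] for i in np.flatnonzero(labels == lab)]
        sample_ids = sorted({sid for s in members for sid in s.sample_ids})
        concept_ids = frozenset().union(*(s.concept_ids for s in members))
        counts = Counter()
        for s in members:
            for c in s.concept_ids:
                counts[c] += len(s.sample_ids)
        label = ", ".join(f"{concept_name(c)} [{counts[c]}]"
                          for c in sorted(concept_ids, key=lambda c: (-counts[c], concept_name(c))))
        merged.append(SemanticSet(sample_ids, concept_ids, label))
    return merged
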