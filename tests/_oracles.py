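"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the package's own graph traversal, matching and
MICA search code paths: reachability is a plain DFS over the edge list,
concept matching is an exhaustive n-gram scan, and the most informative
common ancestor is found by enumerating the full common-ancestor set.
"""

from __future__ import annotations

import re

import numpy as np


def reachable_up(edges: set[tuple[str, str]], start: str) -> frozenset[str]:
    """Reflexive transitive closure over child->parent edges, by plain DFS."""
    adj: dict[str, list[str]] = {}
    for child, parent in edges:
        adj.setdefault(child, []).append(parent)
    seen = {start}
    stack = [start]
    while stack:
        node = stack.pop()
        for parent in adj.get(node, ()):
            if parent not in seen:
                seen.add(parent)
                stack.append(parent)
    return frozenset(seen)


def brute_force_mica_ic(edges: set[tuple[str, str]], ic: dict[str, float],
                        c1: str, c2: str) -> float | None:
    """IC of the most informative common ancestor, by full enumeration.
    Returns None for disconnected pairs."""
    common = reachable_up(edges, c1) & reachable_up(edges, c2)
    if not common:
        return None
    return max(ic[a] for a in common)


def brute_force_lin(edges, ic, c1, c2) -> float:
    mica_ic = brute_force_mica_ic(edges, ic, c1, c2)
    if mica_ic is None:
        return 0.0
    denom = ic[c1] + ic[c2]
    if denom == 0.0:
        return 1.0 if c1 == c2 else 0.0
    return 2.0 * mica_ic / denom


def brute_force_jiang(edges, ic, c1, c2) -> float:
    mica_ic = brute_force_mica_ic(edges, ic, c1, c2)
    if mica_ic is None:
        return 0.0
    return 1.0 / (1.0 + ic[c1] + ic[c2] - 2.0 * mica_ic)


def brute_force_seco_ic(edges: set[tuple[str, str]], nodes: list[str]) -> dict[str, float]:
    """SECO IC from descendant counts obtained by per-node exhaustive DFS."""
    down = {(p, c) for c, p in edges}
    n = len(nodes)
    out = {}
    for node in nodes:
        hypo = len(reachable_up(down, node)) - 1
        out[node] = 1.0 - np.log(hypo + 1) / np.log(n)
    return out


_WORD = re.compile(r"[0-9A-Za-z]+")


def ngram_matches(text: str, variant_map: dict[str, set[str]]
                  ) -> set[tuple[str, int, int]]:
    """Every (concept_id, start, end) where a variant's word sequence occurs
    contiguously in the text, case-insensitively.  ``variant_map`` maps a
    variant string to the concept ids carrying it."""
    words = [(m.group(0).casefold(), m.start(), m.end())
             for m in _WORD.finditer(text)]
    out: set[tuple[str, int, int]] = set()
    for variant, cids in variant_map.items():
        vtokens = [m.group(0).casefold() for m in _WORD.finditer(variant)]
        if not vtokens:
            continue
        L = len(vtokens)
        for i in range(len(words) - L + 1):
            if [w for w, _, _ in words[i:i + L]] == vtokens:
                for cid in cids:
                    out.add((cid, words[i][1], words[i + L - 1][2]))
    return out


def random_dag(rng: np.random.Generator, n_nodes: int,
               max_parents: int = 3) -> tuple[list[str], set[tuple[str, str]]]:
    """Random DAG over ``n_nodes`` named N0..: each node after the first
    gets 0-3 parents among earlier nodes (node 1 always gets one, so the
    graph is never edgeless)."""
    nodes = [f"N{i}" for i in range(n_nodes)]
    edges: set[tuple[str, str]] = set()
    for i in range(1, n_nodes):
        k = int(rng.integers(1, max_parents + 1)) if i == 1 else int(rng.integers(0, max_parents + 1))
        k = min(k, i)
        if k == 0 and rng.random() < 0.8:
            k = 1  # keep most nodes connected
        parents = rng.choice(i, size=k, replace=False) if k else []
        for p in parents:
            edges.add((nodes[i], nodes[int(p)]))
    return nodes, edges
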