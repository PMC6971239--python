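"""Semantically-driven statistical comparison of an omics score matrix.

A score matrix (genomic units x samples — e.g. promoter H3K27ac intensities
or gene expression) is compared across collapsed semantic sets, either *by
row* (one test per genomic unit, identifying differential units) or *by
column* (one global test per pair of sets on the pooled value
distributions).  P-values are corrected for multiple testing per set-pair
family (Benjamini-Hochberg by default).  Two-ontology designs iterate over
the primary ontology's sets (e.g. tissues) while testing the secondary
ontology's states within each (e.g. disease vs healthy).  The concordance
between a semantic sample grouping and a data-driven one is quantified by a
pair-counting Jaccard index.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ontosample.annotator import SemanticSet

logger = logging.getLogger(__name__)

TESTS = ("wilcoxon", "t", "ks")
MTC_METHODS = {"bh": "fdr_bh", "bonferroni": "bonferroni", "none": None}

#: sample-size bound below which the exact Wilcoxon null distribution is used
_EXACT_WILCOXON_MAX_N = 25


class ScoreMatrix:
    """Genomic-unit x sample numeric matrix with optional unit coordinates.

    ``values`` is a DataFrame indexed by unit id with sample-id columns;
    missing scores are NaN.  ``unit_coords`` is an optional DataFrame indexed
    by unit id with columns chrom/start/end[/strand] (0-based half-open).
    """

    def __init__(self, values: pd.DataFrame, unit_coords: pd.DataFrame | None = None):
        values = values.astype(float)
        if values.index.has_duplicates:
            raise ValueError("duplicate unit ids")
        if values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        self.values = values
        self.unit_coords = unit_coords

    @property
    def unit_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def restrict_samples(self, samples: list[str]) -> "ScoreMatrix":
        return ScoreMatrix(self.values[list(samples)], self.unit_coords)


@dataclass
class TestSpec:
    """Which two-sample test to run and how to correct it.

    ``test`` is one of ``wilcoxon`` (two-sided rank-sum, exact null for
    group sizes <= 25 without ties, normal approximation with continuity
    correction otherwise), ``t``, ``ks``, or a callable ``f(x, y) ->
    (statistic, p_value)``.  ``mtc_scope`` controls whether BH families are
    per set-pair (default, one family per reported panel) or global.
    """

    __test__ = False  # not a test class, despite the name

    test: str | Callable = "wilcoxon"
    mtc: str = "bh"
    alpha: float = 0.05
    min_group_size: int = 3
    mtc_scope: str = "per_pair"   # "per_pair" | "global"

    def __post_init__(self):
        if isinstance(self.test, str) and self.test not in TESTS:
            raise ValueError(f"unknown test: {self.test!r}")
        if self.mtc not in MTC_METHODS:
            raise ValueError(f"unknown correction: {self.mtc!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_group_size < 2:
            raise ValueError("min_group_size must be >= 2")
        if self.mtc_scope not in ("per_pair", "global"):
            raise ValueError(f"unknown mtc scope: {self.mtc_scope!r}")


@dataclass
class ComparisonRecord:
    set_a: str
    set_b: str
    unit_id: str          # "GLOBAL" for by-column records
    statistic: float
    p_value: float
    p_adjusted: float
    n_a: int
    n_b: int


@dataclass
class ComparisonResult:
    mode: str                       # "by_row" | "by_col"
    records: list[ComparisonRecord]
    context: str | None = None      # primary-ontology set label, if any
    n_skipped_units: int = 0
    dropped_samples: list[str] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])

    def significant(self, alpha: float = 0.05) -> list[ComparisonRecord]:
        return [r for r in self.records if r.p_adjusted < alpha]


def _run_single_test(x: np.ndarray, y: np.ndarray, test) -> tuple[float, float]:
    if callable(test):
        stat, p = test(x, y)
        return float(stat), float(p)
    if test == "wilcoxon":
        pooled = np.concatenate([x, y])
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = ("exact" if not has_ties
                  and max(len(x), len(y)) <= _EXACT_WILCOXON_MAX_N
                  else "asymptotic")
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    if test == "t":
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            # zero variance in both groups: undefined statistic, flagged p=1
            return float("nan"), 1.0
        res = stats.ttest_ind(x, y)
        p = res.pvalue
        return float(res.statistic), float(1.0 if math.isnan(p) else p)
    if test == "ks":
        res = stats.ks_2samp(x, y)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test: {test!r}")


def _row_tests(a: np.ndarray, b: np.ndarray, test) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-row two-sample tests of a (units x nA) against b (units x nB).

    Returns (statistics, p_values, tested_mask); rows where either group is
    all-NaN are skipped.  The Wilcoxon path is vectorized across rows that
    share the exact/asymptotic decision.
    """
    n_units = a.shape[0]
    stats_out = np.full(n_units, np.nan)
    p_out = np.full(n_units, np.nan)
    ok_a = ~np.all(np.isnan(a), axis=1)
    ok_b = ~np.all(np.isnan(b), axis=1)
    tested = ok_a & ok_b

    complete = tested & ~np.any(np.isnan(a), axis=1) & ~np.any(np.isnan(b), axis=1)
    if test == "wilcoxon" and complete.any():
        sub_a, sub_b = a[complete], b[complete]
        pooled = np.concatenate([sub_a, sub_b], axis=1)
        tie_rows = np.array([len(np.unique(row)) < row.size for row in pooled])
        small = max(sub_a.shape[1], sub_b.shape[1]) <= _EXACT_WILCOXON_MAX_N
        idx = np.flatnonzero(complete)
        for method, mask in (("exact", ~tie_rows if small else np.zeros(len(idx), bool)),
                             ("asymptotic", tie_rows if small else np.ones(len(idx), bool))):
            if mask.any():
                res = stats.mannwhitneyu(sub_a[mask], sub_b[mask], axis=1,
                                         alternative="two-sided", method=method)
                stats_out[idx[mask]] = res.statistic
                p_out[idx[mask]] = res.pvalue
        remaining = tested & ~complete
    else:
        remaining = tested

    for i in np.flatnonzero(remaining):
        x = a[i][~np.isnan(a[i])]
        y = b[i][~np.isnan(b[i])]
        stats_out[i], p_out[i] = _run_single_test(x, y, test)
    return stats_out, p_out, tested


def _adjust(pvals: np.ndarray, method: str) -> np.ndarray:
    mapped = MTC_METHODS[method]
    if mapped is None or len(pvals) == 0:
        return pvals.copy()
    return multipletests(pvals, method=mapped)[1]


def _set_label(s: SemanticSet) -> str:
    return s.label or ",".join(sorted(s.concept_ids))


def compare(scores: ScoreMatrix, semantic_sets: list[SemanticSet],
            mode: str = "by_row", spec: TestSpec | None = None) -> ComparisonResult:
    """Test score differences between every unordered pair of semantic sets.

    ``by_col`` pools all units x member samples of each set and runs one
    global test per pair; ``by_row`` tests each genomic unit separately and
    corrects p-values within each pair's unit family.  Samples named in a
    set but absent from the matrix are dropped (logged); sets smaller than
    ``spec.min_group_size`` after dropping are excluded, and at least two
    eligible sets are required.
    """
    spec = spec or TestSpec()
    if mode not in ("by_row", "by_col"):
        raise ValueError(f"unknown mode: {mode!r}")
    available = set(scores.sample_ids)
    dropped: list[str] = []
    eligible: list[tuple[SemanticSet, list[str]]] = []
    for s in semantic_sets:
        members = [sid for sid in s.sample_ids if sid in available]
        dropped.extend(sid for sid in s.sample_ids if sid not in available)
        if len(members) >= spec.min_group_size:
            eligible.append((s, members))
        else:
            logger.info("set %r excluded: %d sample(s) < min_group_size=%d",
                        _set_label(s), len(members), spec.min_group_size)
    if dropped:
        logger.info("dropped %d sample(s) absent from the score matrix", len(dropped))
    if len(eligible) < 2:
        raise ValueError("fewer than two semantic sets meet min_group_size")

    records: list[ComparisonRecord] = []
    n_skipped = 0
    pairs = [(i, j) for i in range(len(eligible)) for j in range(i + 1, len(eligible))]

    if mode == "by_col":
        for i, j in pairs:
            (sa, ma), (sb, mb) = eligible[i], eligible[j]
            x = scores.values[ma].to_numpy().ravel()
            y = scores.values[mb].to_numpy().ravel()
            x, y = x[~np.isnan(x)], y[~np.isnan(y)]
            stat, p = _run_single_test(x, y, spec.test)
            records.append(ComparisonRecord(_set_label(sa), _set_label(sb),
                                            "GLOBAL", stat, p, np.nan,
                                            len(ma), len(mb)))
        padj = _adjust(np.array([r.p_value for r in records]), spec.mtc)
        for r, q in zip(records, padj):
            r.p_adjusted = float(q)
    else:
        unit_ids = np.asarray(scores.unit_ids)
        per_pair_slices = []
        for i, j in pairs:
            (sa, ma), (sb, mb) = eligible[i], eligible[j]
            a = scores.values[ma].to_numpy()
            b = scores.values[mb].to_numpy()
            st, p, tested = _row_tests(a, b, spec.test)
            n_skipped += int((~tested).sum())
            idx = np.flatnonzero(tested)
            start = len(records)
            for k in idx:
                records.append(ComparisonRecord(_set_label(sa), _set_label(sb),
                                                str(unit_ids[k]), float(st[k]),
                                                float(p[k]), np.nan,
                                                len(ma), len(mb)))
            per_pair_slices.append((start, len(records)))
        if spec.mtc_scope == "global":
            padj = _adjust(np.array([r.p_value for r in records]), spec.mtc)
            for r, q in zip(records, padj):
                r.p_adjusted = float(q)
        else:
            for start, end in per_pair_slices:
                chunk = records[start:end]
                padj = _adjust(np.array([r.p_value for r in chunk]), spec.mtc)
                for r, q in zip(chunk, padj):
                    r.p_adjusted = float(q)
    return ComparisonResult(mode, records, n_skipped_units=n_skipped,
                            dropped_samples=sorted(set(dropped)))


def compare_two_level(scores: ScoreMatrix,
                      primary_sets: list[SemanticSet],
                      secondary_sets: list[SemanticSet],
                      mode: str = "by_row",
                      spec: TestSpec | None = None) -> list[ComparisonResult]:
    """Iterate over primary-ontology sets (e.g. tissues) and, within each,
    compare the secondary-ontology states (e.g. diseases vs healthy).

    Each sample may belong to at most one primary and one secondary set.
    Primary sets without at least two eligible secondary states are skipped;
    if none qualifies an empty list is returned with a warning.
    """
    spec = spec or TestSpec()
    for name, sets in (("primary", primary_sets), ("secondary", secondary_sets)):
        seen: set[str] = set()
        for s in sets:
            overlap = seen & set(s.sample_ids)
            if overlap:
                raise ValueError(
                    f"samples in more than one {name} set: {sorted(overlap)[:5]}")
            seen |= set(s.sample_ids)

    results: list[ComparisonResult] = []
    available = set(scores.sample_ids)
    for primary in primary_sets:
        samples_p = [s for s in primary.sample_ids if s in available]
        restricted: list[SemanticSet] = []
        for sec in secondary_sets:
            members = [s for s in sec.sample_ids if s in samples_p]
            if len(members) >= spec.min_group_size:
                restricted.append(SemanticSet(members, sec.concept_ids, sec.label))
        if len(restricted) < 2:
            logger.info("primary set %r skipped: fewer than two secondary states",
                        _set_label(primary))
            continue
        result = compare(scores.restrict_samples(samples_p), restricted, mode, spec)
        result.context = _set_label(primary)
        results.append(result)
    if not results:
        logger.warning("no primary set had two or more eligible secondary states")
    return results


def jaccard_concordance(groups_a, groups_b) -> float:
    """Pair-counting Jaccard index between two partitions of the same samples.

    Ratio of sample pairs co-grouped in both partitions to pairs co-grouped
    in either.  Partitions may be given as ``sample -> group`` mappings or as
    iterables of sample collections.  Two all-singleton partitions have no
    co-grouped pairs; the empty ratio is defined as 1.
    """
    la = _as_labels(groups_a)
    lb = _as_labels(groups_b)
    if set(la) != set(lb):
        raise ValueError("partitions cover different sample universes")
    samples = sorted(la)
    a = pd.Categorical([la[s] for s in samples]).codes
    b = pd.Categorical([lb[s] for s in samples]).codes
    contingency = pd.crosstab(a, b).to_numpy()

    def pairs(counts: np.ndarray) -> float:
        return float((counts * (counts - 1) / 2).sum())

    both = pairs(contingency)
    either = pairs(contingency.sum(axis=1)) + pairs(contingency.sum(axis=0)) - both
    if either == 0:
        return 1.0
    return both / either


def _as_labels(groups) -> dict[str, int]:
    if isinstance(groups, dict):
        first = next(iter(groups.values()), None)
        # tuples count as (hashable) group labels, not member collections
        if first is None or not isinstance(first, (set, frozenset, list)):
            return dict(groups)
        return {s: i for i, (_, members) in enumerate(sorted(groups.items()))
                for s in members}
    labels = {}
    for i, members in enumerate(groups):
        if isinstance(members, SemanticSet):
            members = members.sample_ids
        for s in members:
            if s in labels:
                raise ValueError(f"sample {s!r} appears in two groups")
            labels[s] = i
    return labels


def reshuffle_scores(scores: ScoreMatrix, seed: int) -> ScoreMatrix:
    """Permute all matrix values uniformly at random (fixed seed), keeping
    dimensions, unit ids and sample ids — the negative control that severs
    any link between metadata semantics and the omics data."""
    rng = np.random.default_rng(seed)
    flat = scores.values.to_numpy().ravel().copy()
    rng.shuffle(flat)
    shuffled = pd.DataFrame(flat.reshape(scores.values.shape),
                            index=scores.values.index,
                            columns=scores.values.columns)
    return ScoreMatrix(shuffled, scores.unit_coords)
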