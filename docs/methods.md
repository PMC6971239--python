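# Methods

This note documents the models and procedures implemented in `ontosample`,
the defaults and why they were chosen, what the synthetic fixtures emulate,
and the known limits of both.

## Ontology model

An OBO v1.2 file is parsed into a concept DAG. Each concept carries its
accession, canonical name, scoped synonyms (EXACT / BROAD / NARROW /
RELATED; a synonym line without a scope defaults to RELATED, following OBO
semantics), an obsolete flag and an optional namespace. Only OBO flat files
are accepted; OWL input is rejected with an explicit message rather than
half-parsed.

Hierarchy normalization: `is_a` edges are traversed as-is; `part_of` edges
— widespread in anatomy ontologies — are converted so that every traversal
treats them as `is_a`, because the similarity measures are defined over a
single edge type. All other relationship types (`develops_from`, ...) are
dropped at conversion, with a logged count. Conversion is idempotent, and
the package guarantees (and tests) that a topology expressed with `part_of`
yields exactly the same similarities as the identical topology expressed
with `is_a`.

`ancestors()` is reflexive (a concept is its own ancestor). This is not a
cosmetic choice: it makes `MICA(c, c) = c` and hence `Lin(c, c) = 1`, and
it makes the root's ancestor set well defined. Obsolete terms are kept in
the model for provenance but excluded from traversal, dictionaries and
similarity. Multiple inheritance is preserved; there is no tree-ification.
A cyclic `is_a` hierarchy is a hard error that names the cycle, and a
malformed stanza is a parse error that names the line.

## Information content

Similarity needs a specificity score for every concept in *any* OBO
ontology, including ones with no annotation corpus, so all three IC
estimators are intrinsic (topology-only):

- **SECO** (default): `IC(c) = 1 − log(hypo(c)+1) / log(N)`, where
  `hypo(c)` counts strict descendants and `N` is the number of non-obsolete
  concepts. The root of a single-rooted ontology scores exactly 0, leaves
  exactly 1.
- **Sánchez**: leaf/subsumer-ratio based, rescaled by its maximum to
  [0, 1].
- **Zhou**: an equal-weight blend of the SECO term with a relative-depth
  term `log(depth)/log(max_depth)`.

All three are monotone non-decreasing from ancestor to descendant
(property-tested on random DAGs). In multi-rooted graphs a root subsumes
only its own component, so its IC can be positive; the `IC(root) = 0`
identity is guaranteed for single-rooted ontologies. A single-concept
ontology has no topology to measure; IC is defined as 0 with a warning.

## Dictionaries and named entity recognition

A dictionary entry is one concept with its canonical name plus every
synonym whose scope is requested; variants are de-duplicated after case
normalization. Defaults: all four synonym scopes, case-insensitive
matching. These defaults are deliberate choices of this package (both axes
are fully configurable): including all scopes maximizes recall on
free-text metadata, and case-insensitivity is the only viable policy for
text typed by thousands of different submitters. The `fold_digits` policy
lowercases letters while leaving digits alone, which keeps symbols like
`H3K27ac` legible after folding. Gene/mark symbol tables (TSV:
`symbol<TAB>aliases`, pipe-separated aliases) compile the same way; in
histone-mark mode each symbol of shape `<histone><residue><mod>` also gets
the capitalized-modification and space-separated spellings
(`H3K27ac` → `H3K27Ac`, `H3 K27 ac`).

The matching pipeline: sentence detection (periods, semicolons, newlines;
a period does not split after a single letter or a known abbreviation, so
"E. coli" survives), tokenization into maximal alphanumeric runs (hyphens
and underscores separate tokens — "MCF-7" becomes two tokens, a documented
consequence), optional Porter stemming and stop-word skipping applied
symmetrically to text and dictionary variants at compile time, then n-gram
lookup of variant token sequences. A stop-word-only variant keeps its
original tokens rather than vanishing. With `order_independent` the lookup
window equals the variant's token count and accepts any permutation — a
pure-permutation reading, chosen over gap-tolerant windows as the minimal
unambiguous interpretation.

Match selection: `find_all` reports every occurrence; with overlaps
disallowed, matches strictly contained in a longer match are suppressed.
Longest-only selection is greedy and deterministic: earliest start, then
longer span, then smallest concept id. Duplicate detections of the same
(sample, field, concept, span) collapse to one. The find-all matcher is
tested for exact agreement with an independent brute-force n-gram scan.

Generic, uninformative concepts (e.g. a bare "disease" root match) can be
removed by a user stoplist of ids or names before semantic sets are formed.

## Semantic similarity, combination and collapsing

Pairwise measures (all symmetric; ties in the MICA search broken by
maximal IC then smallest id):

- Resnik: `IC(MICA)`
- Lin (default): `2·IC(MICA) / (IC(a) + IC(b))`, with the 0/0 root case
  defined as 1 iff the concepts are identical
- Jiang-Conrath similarity: `1 / (1 + IC(a) + IC(b) − 2·IC(MICA))`
- edge-based Rada: `1 / (1 + shortest path through a common ancestor)`

Lin is the default pairwise measure as the best performer in prior
benchmarking of this annotation task; concepts with no common ancestor
(possible in multi-rooted graphs) score 0 with a warning. Group-wise
similarity between semantic sets defaults to best-match average,
`BMA(A,B) = ½[mean_a max_b sim + mean_b max_a sim]`; max, average and min
are available. Note that BMA self-similarity is 1 by construction even for
multi-concept sets. Matrices from several ontologies over the same samples
combine element-wise (mean by default, any aggregator accepted).

Collapsing runs agglomerative clustering on distance `1 − sim` (average
linkage by default; complete and single available — the linkage behind the
published heatmaps is not stated anywhere authoritative, so it is a
documented, switchable default) and cuts the tree at `1 − τ`. At τ=1 only
similarity-exactly-1 sets merge; at τ=0 everything merges (similarities
are non-negative, so all distances are ≤ 1); cluster counts are monotone
in τ. A merged group's label lists each concept with the number of member
samples annotated with it in square brackets.

## Statistical comparison

The default test is the two-sided Wilcoxon rank-sum: exact null
distribution when both groups have ≤ 25 samples and no ties, normal
approximation with continuity correction otherwise. Student's t (zero
variance in both groups yields a flagged p = 1 rather than an error),
Kolmogorov-Smirnov, and arbitrary user callables returning
`(statistic, p)` are supported.

By-column mode pools all units × member samples per set and runs one
global test per pair; by-row mode tests each genomic unit. BH correction
(default; Bonferroni and none available) is applied within each set-pair's
unit family, because each pair is reported as its own panel; a single
global family is available via `mtc_scope="global"`. `min_group_size`
defaults to 3: smaller sets are excluded with a logged reason, and fewer
than two eligible sets is an error. Samples named in a set but absent from
the matrix are dropped, never imputed; a unit that is all-NA in one group
is skipped and counted.

Two-level designs require each sample to sit in at most one primary and
one secondary set; within each primary set the secondary states are
compared if at least two meet the size threshold.

Partition concordance uses the pair-counting Jaccard index: co-grouped
pairs in both partitions over co-grouped pairs in either, computed from
the contingency table. Two all-singleton partitions have no co-grouped
pairs; the 0/0 case is defined as 1 (they are identical partitions). The
pair-counting variant was chosen over best-match-overlap variants because
it is symmetric, parameter-free and standard for comparing clusterings.
The reshuffle control permutes all matrix values with a seeded generator,
preserving dimensions and the value multiset.

## Synthetic fixtures: what they emulate and what they don't

The generator stands in for the public resources a real analysis would
draw on. The toy tissue ontology (5 terms, one root, a diamond so that
"breast epithelium" has two parents and an EXACT synonym "breast") and the
7-term disease ontology (a generic "disease" root, cancer subtypes, a
"healthy" leaf) exercise multiple inheritance, synonym scopes and
generic-term filtering at a size where every expected value can be checked
by hand. Metadata are templated GEO-style records embedding each sample's
tissue and disease concept names, with distractor sentences (containing no
dictionary term) at a configurable rate; the paired ground-truth file
lists the intended (sample, concept) pairs, so annotation accuracy is
measured against a known truth rather than re-derived.

Score matrices are i.i.d. Normal(μ=10, σ=2) baseline with the planted
effect added as a constant shift of `effect_size · σ` (default 2, i.e. +2
pooled SD) to the first `n_true_units` units (default 10 of 500) in the
diseased samples of the first tissue; the default layout is 2 tissues ×
(disease, healthy) × 10 samples = 40 samples. Normal noise was chosen for
analytic transparency — the default test is rank-based and distribution-
free, so the testing layer is unaffected by this choice — and is a
stand-in, not a claim about ChIP-seq intensity distributions. Real
metadata are messier than the templates (typos, abbreviations, negations,
multi-condition samples), and real score matrices have correlated units,
heavy tails and batch structure; passing tests on these fixtures therefore
validate the machinery (parsing, matching, similarity algebra, test
plumbing, error control under independence), not performance on any real
corpus. Published accuracy figures for dictionary-lookup annotation of GEO
metadata depend on external gold standards and are not reproduced here.

At the fixture's own study conditions, per-unit Wilcoxon+BH recovery of
the planted units reaches a median sensitivity of about 0.55 with observed
FDR ≈ 0 (20 seeds); a +2 pooled-SD shift with 10-vs-10 samples sits near
the edge of what a rank test can pass through a BH threshold shared with
490 null units. The global by-column contrast is diluted by the 490
unshifted units and is typically non-significant under these defaults —
the by-row and two-level modes are the instruments matched to a localized
effect.

## Numerical and degenerate-input choices

- Collapse thresholds are applied with a 1e-9 tolerance on the distance
  cut so that similarity-exactly-1 merges are not lost to float round-off.
- Aggregated multi-ontology matrices are re-symmetrized
  (`(M + Mᵀ)/2`) to guard against asymmetric user aggregators.
- Similarity caches are per-call; ancestor sets are memoized per graph.
- Problem sizes in the test suite and acceptance script (500-unit
  matrices, 20-50 simulation seeds, 50 random DAGs for oracle checks) were
  chosen to estimate medians and error rates stably on a single CPU.
- The acceptance script derives all sub-seeds from `--seed` by fixed
  offsets; every random quantity it prints is recomputed at run time.

## Known limitations

- No OWL parsing, no reasoning beyond transitive closure, no ontology
  editing or merging.
- English-only matching; no machine-learning NER, abbreviation expansion
  or negation detection. Hyphen splitting can fragment cell-line names.
- Intrinsic IC only; no corpus-frequency IC.
- The score-matrix tests treat units independently; no count models,
  no peak calling or upstream summarization, no embedding methods
  (data-driven partitions are accepted as input).
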