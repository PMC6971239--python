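"""Deterministic generators for every input the pipeline consumes.

These stand in for the public resources a real analysis would use (GEO
metadata, ontology downloads, re-processed ChIP-seq score matrices): a toy
tissue ontology and a toy disease ontology, templated free-text metadata
with known ground-truth concept mentions, and score matrices with planted
differential units.  Everything is seeded; the same seed reproduces the
same bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
import pandas as pd

from ontosample.semcompare import ScoreMatrix

HEALTHY = "D:6"

#: 5-term tissue ontology: one root, diamond multiple inheritance, an EXACT
#: synonym on the breast term and a RELATED one on the mammary gland.
TOY_TISSUE_OBO = """\
format-version: 1.2

[Term]
id: T:0
name: anatomical entity

[Term]
id: T:1
name: epithelium
is_a: T:0

[Term]
id: T:2
name: mammary gland
synonym: "mamma" RELATED []
is_a: T:0

[Term]
id: T:3
name: breast epithelium
synonym: "breast" EXACT []
is_a: T:1
is_a: T:2

[Term]
id: T:4
name: colon epithelium
is_a: T:1
"""

#: same topology but T:3 -> T:2 expressed as part_of instead of is_a
TOY_TISSUE_PART_OF_OBO = TOY_TISSUE_OBO.replace(
    'synonym: "breast" EXACT []\nis_a: T:1\nis_a: T:2',
    'synonym: "breast" EXACT []\nis_a: T:1\nrelationship: part_of T:2')

#: 7-term disease ontology with a generic "disease" root (so root matches can
#: be removed by the generic-term filter) and healthy/disease leaves.
TOY_DISEASE_OBO = """\
format-version: 1.2

[Term]
id: D:0
name: disease

[Term]
id: D:1
name: cancer
is_a: D:0

[Term]
id: D:2
name: breast cancer
synonym: "breast carcinoma" EXACT []
is_a: D:1

[Term]
id: D:3
name: colon cancer
synonym: "colorectal cancer" RELATED []
is_a: D:1

[Term]
id: D:4
name: leukemia
is_a: D:1

[Term]
id: D:5
name: inflammatory disease
is_a: D:0

[Term]
id: D:6
name: healthy
is_a: D:0
"""


def make_toy_ontology(outdir, part_of_variant: bool = False) -> tuple[Path, Path]:
    """Write the toy tissue and disease OBO files; returns their paths.
    ``part_of_variant`` writes the tissue topology with one part_of edge."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tissue = outdir / "tissue.obo"
    disease = outdir / "disease.obo"
    tissue.write_text(TOY_TISSUE_PART_OF_OBO if part_of_variant else TOY_TISSUE_OBO,
                      encoding="utf-8")
    disease.write_text(TOY_DISEASE_OBO, encoding="utf-8")
    return tissue, disease


_CONCEPT_NAMES = {
    "T:0": "anatomical entity", "T:1": "epithelium", "T:2": "mammary gland",
    "T:3": "breast epithelium", "T:4": "colon epithelium",
    "D:0": "disease", "D:1": "cancer", "D:2": "breast cancer",
    "D:3": "colon cancer", "D:4": "leukemia", "D:5": "inflammatory disease",
    "D:6": "healthy",
}

#: distractor sentences free of any dictionary term
_DISTRACTORS = (
    "Libraries were prepared with a standard kit.",
    "Sequencing was performed on an Illumina instrument.",
    "Reads were aligned and duplicates marked.",
    "Replicate quality metrics passed thresholds.",
)


@dataclass
class FixtureSpec:
    """Study-condition parameters for the synthetic corpus and score matrix.

    ``effect_size`` is the planted shift in pooled-SD units; the baseline
    scores are i.i.d. Normal(mu=10, sigma=2).  ``tissue_layout`` maps each
    tissue concept to the disease states present for it; samples are split
    evenly across the (tissue, disease) combinations.  ``mention_noise`` is
    the probability that a sample's description carries a distractor
    sentence.
    """

    seed: int = 0
    n_samples: int = 40
    n_units: int = 500
    n_true_units: int = 10
    effect_size: float = 2.0
    tissue_layout: dict[str, list[str]] = dataclass_field(
        default_factory=lambda: {"T:3": ["D:2", HEALTHY], "T:4": ["D:3", HEALTHY]})
    mention_noise: float = 0.1
    mu: float = 10.0
    sigma: float = 2.0

    def __post_init__(self):
        if self.n_true_units > self.n_units:
            raise ValueError("n_true_units must be <= n_units")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")

    @property
    def combos(self) -> list[tuple[str, str]]:
        return [(t, d) for t, states in self.tissue_layout.items() for d in states]

    @property
    def target_group(self) -> tuple[str, str]:
        """The (tissue, disease) combination carrying the planted effect:
        the first non-healthy state in the layout."""
        for t, d in self.combos:
            if d != HEALTHY:
                return (t, d)
        raise ValueError("layout has no non-healthy state to plant an effect in")


@dataclass
class MetadataFixture:
    metadata: pd.DataFrame      # sample_id + free-text columns
    truth: pd.DataFrame         # (sample_id, concept_id) intended mentions
    memberships: pd.DataFrame   # (sample_id, tissue, disease)


def make_metadata(spec: FixtureSpec, outdir=None) -> MetadataFixture:
    """Generate templated free-text metadata embedding each sample's tissue
    and disease concept names, with optional distractor sentences.

    With ``mention_noise=0`` the corpus contains exactly the intended
    mentions, so find-all annotation recovers the ground truth exactly.
    """
    rng = np.random.default_rng(spec.seed)
    combos = spec.combos
    rows, truth_rows, member_rows = [], [], []
    for i in range(spec.n_samples):
        tissue, disease = combos[i % len(combos)]
        tname, dname = _CONCEPT_NAMES[tissue], _CONCEPT_NAMES[disease]
        sample_id = f"GSM{i:04d}"
        summary = f"Genome-wide profiling of {tname} samples."
        description = ""
        if rng.random() < spec.mention_noise:
            description = _DISTRACTORS[rng.integers(len(_DISTRACTORS))]
        rows.append({
            "sample_id": sample_id,
            "title": f"ChIP-seq of {tname} replicate {i}",
            "summary": summary,
            "source_name_ch1": tname,
            "organism_ch1": "Homo sapiens",
            "characteristics_ch1": f"condition: {dname}",
            "description": description,
        })
        truth_rows.append({"sample_id": sample_id, "concept_id": tissue})
        truth_rows.append({"sample_id": sample_id, "concept_id": disease})
        member_rows.append({"sample_id": sample_id, "tissue": tissue, "disease": disease})
    meta = pd.DataFrame(rows, columns=["sample_id", "title", "summary",
                                       "source_name_ch1", "organism_ch1",
                                       "characteristics_ch1", "description"])
    truth = pd.DataFrame(truth_rows, columns=["sample_id", "concept_id"])
    members = pd.DataFrame(member_rows, columns=["sample_id", "tissue", "disease"])
    fixture = MetadataFixture(meta, truth, members)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
        truth.to_csv(outdir / "truth_annotations.tsv", sep="\t", index=False)
        members.to_csv(outdir / "memberships.tsv", sep="\t", index=False)
    return fixture


def make_scores(spec: FixtureSpec, memberships: pd.DataFrame,
                outdir=None) -> tuple[ScoreMatrix, list[str]]:
    """Score matrix with a planted effect.

    Baseline values are i.i.d. Normal(mu, sigma); for the first
    ``n_true_units`` units, samples of the target (tissue, disease) group
    are shifted by ``effect_size * sigma``.  Returns the matrix and the
    planted unit ids.
    """
    rng = np.random.default_rng(spec.seed + 1)
    samples = memberships["sample_id"].tolist()
    unit_ids = [f"U{i:04d}" for i in range(spec.n_units)]
    values = rng.normal(spec.mu, spec.sigma, (spec.n_units, len(samples)))
    target_tissue, target_disease = spec.target_group
    target = ((memberships["tissue"] == target_tissue)
              & (memberships["disease"] == target_disease)).to_numpy()
    values[: spec.n_true_units, target] += spec.effect_size * spec.sigma
    truth_units = unit_ids[: spec.n_true_units]
    coords = pd.DataFrame({
        "chrom": "chr1",
        "start": np.arange(spec.n_units) * 2000,
        "end": np.arange(spec.n_units) * 2000 + 1000,
        "name": unit_ids,
        "score": 0,
        "strand": ".",
    }).set_index("name", drop=False)
    matrix = ScoreMatrix(pd.DataFrame(values, index=unit_ids, columns=samples), coords)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        matrix.values.to_csv(outdir / "scores.tsv", sep="\t", index_label="unit_id")
        pd.Series(truth_units, name="unit_id").to_csv(outdir / "truth_units.tsv",
                                                      sep="\t", index=False)
    return matrix, truth_units


def planted_two_group(seed: int, n_units: int = 500, n_true_units: int = 10,
                      n_per_group: int = 10, effect_size: float = 2.0,
                      mu: float = 10.0, sigma: float = 2.0,
                      ) -> tuple[ScoreMatrix, list[str], list[str], list[str]]:
    """Minimal planted fixture: two groups A and B of ``n_per_group``
    samples; the first ``n_true_units`` units are shifted by
    ``effect_size * sigma`` in B.  Returns (matrix, samples_a, samples_b,
    planted_unit_ids)."""
    rng = np.random.default_rng(seed)
    samples_a = [f"A{i:02d}" for i in range(n_per_group)]
    samples_b = [f"B{i:02d}" for i in range(n_per_group)]
    unit_ids = [f"U{i:04d}" for i in range(n_units)]
    values = rng.normal(mu, sigma, (n_units, 2 * n_per_group))
    values[:n_true_units, n_per_group:] += effect_size * sigma
    matrix = ScoreMatrix(pd.DataFrame(values, index=unit_ids,
                                      columns=samples_a + samples_b))
    return matrix, samples_a, samples_b, unit_ids[:n_true_units]
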