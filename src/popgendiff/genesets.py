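"""Equal-weight aggregation of gene-level differences to gene-set scores.

A pathway or GO category's difference score for a feature and
population pair is the unweighted mean of its member genes' difference
values; genes with a missing value for that feature/pair are excluded
(and counted in ``n_genes_used``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .differences import DifferenceRecord
from .genotype_io import GeneSet, GeneSetCollection


@dataclass
class SetDifferenceScore:
    set_id: str
    feature: str
    pop_i: str
    pop_j: str
    value: float  # mean of member-gene difference values; NaN if none usable
    n_genes_used: int


def set_score(
    gene_values: dict[str, float],
    gene_set: GeneSet,
    feature: str = "maf",
    pop_i: str = "",
    pop_j: str = "",
) -> SetDifferenceScore:
    """Equal-weight mean of member-gene difference values."""
    vals = [
        gene_values[g]
        for g in gene_set.gene_ids
        if g in gene_values and not math.isnan(gene_values[g])
    ]
    return SetDifferenceScore(
        set_id=gene_set.set_id,
        feature=feature,
        pop_i=pop_i,
        pop_j=pop_j,
        value=float(np.mean(vals)) if vals else float("nan"),
        n_genes_used=len(vals),
    )


def score_all_sets(
    gene_records: list[DifferenceRecord], collection: GeneSetCollection
) -> list[DifferenceRecord]:
    """One set-level record per (set, feature, population pair).

    The same equal-weight mean applies to KEGG pathways and to BP/MF/CC
    GO categories; the record's entity_type is the set's category.
    """
    by_key: dict[tuple[str, str, str], dict[str, float]] = {}
    for rec in gene_records:
        by_key.setdefault((rec.feature, rec.pop_i, rec.pop_j), {})[rec.entity_id] = rec.value
    out: list[DifferenceRecord] = []
    for gene_set in collection:
        entity_type = gene_set.category if gene_set.category != "custom" else "pathway"
        for (feature, pop_i, pop_j), gene_values in sorted(by_key.items()):
            score = set_score(gene_values, gene_set, feature, pop_i, pop_j)
            out.append(
                DifferenceRecord(
                    entity_id=gene_set.set_id,
                    entity_type=entity_type,
                    feature=feature,
                    pop_i=pop_i,
                    pop_j=pop_j,
                    value=score.value,
                )
            )
    return out


def enumerate_difference_records(
    n_entities: int, n_features: int, n_populations: int
) -> int:
    """Record count: entities x features x unordered population pairs."""
    if n_populations < 2:
        raise ValueError("need >=2 populations")
    if min(n_entities, n_features) < 1:
        raise ValueError("counts must be positive")
    return n_entities * n_features * (n_populations * (n_populations - 1) // 2)
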