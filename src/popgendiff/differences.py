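"""Pairwise-population difference records, matrices and summaries.

Each gene (or gene set) yields one record per feature per unordered
population pair.  Vector-valued features (per-SNP frequencies, per-pair
r2/D') are differenced as the mean absolute difference over shared
units; scalar features as plain absolute differences; directed
transferability statistics are folded into one symmetric value per
pair.  Records assemble into symmetric matrices with reference
(boxplot) summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genotype_io import PopulationPanel

#: The 11 per-gene population-genetic features.
FEATURES: tuple[str, ...] = (
    "maf",
    "fst",
    "r2",
    "dprime",
    "block_number",
    "block_size",
    "snp_density",
    "hap_diversity",
    "tag_percent",
    "captured_percent",
    "avg_max_r2",
)

ENTITY_TYPES = ("gene", "pathway", "BP", "MF", "CC")


@dataclass(frozen=True)
class DifferenceRecord:
    entity_id: str
    entity_type: str  # gene | pathway | BP | MF | CC
    feature: str
    pop_i: str  # unordered pair stored in panel order, pop_i before pop_j
    pop_j: str
    value: float  # nonnegative, NaN = missing

    def __post_init__(self) -> None:
        if self.feature not in FEATURES:
            raise ValueError(f"unknown feature {self.feature!r}")
        if self.entity_type not in ENTITY_TYPES:
            raise ValueError(f"unknown entity type {self.entity_type!r}")
        if self.pop_i == self.pop_j:
            raise ValueError("pop_i and pop_j must differ")


@dataclass
class DifferenceMatrix:
    entity_id: str
    feature: str
    labels: list[str]
    values: np.ndarray  # symmetric, zero diagonal


@dataclass
class ReferenceSummary:
    entity_id: str
    feature: str
    all_values: np.ndarray
    boxplot: tuple[float, float, float, float, float]  # min, q1, median, q3, max
    percentile_rank: float | None = None  # of the queried pair, if any


def vector_feature_difference(values_i: dict, values_j: dict) -> float:
    """Mean absolute difference over units defined in both populations.

    Units (SNPs or SNP pairs) whose value is missing (NaN) or absent in
    either population are excluded; no shared units gives NaN.
    """
    shared = [
        k
        for k in values_i
        if k in values_j
        and not math.isnan(values_i[k])
        and not math.isnan(values_j[k])
    ]
    if not shared:
        return float("nan")
    return float(np.mean([abs(values_i[k] - values_j[k]) for k in shared]))


def scalar_feature_difference(x_i: float, x_j: float) -> float:
    """|x_i - x_j|; missing (NaN) in either population propagates."""
    if math.isnan(x_i) or math.isnan(x_j):
        return float("nan")
    return abs(x_i - x_j)


def directed_pair_difference(
    value_ab: float, value_ba: float, perfect: float = 100.0
) -> float:
    """Symmetrize a directed transferability statistic into one value.

    The difference is the mean shortfall from perfect transfer over the
    two directions, rescaled to [0, 1]:
    ((perfect - v_ab) + (perfect - v_ba)) / 2 / perfect.  ``perfect`` is
    100 for captured_percent and 1 for avg_max_r2.  If one direction is
    missing the other is used alone; both missing gives NaN.
    """
    vals = [v for v in (value_ab, value_ba) if not math.isnan(v)]
    if not vals:
        return float("nan")
    return float(np.mean([(perfect - v) / perfect for v in vals]))


def build_matrix(
    records: list[DifferenceRecord], panel: PopulationPanel
) -> DifferenceMatrix:
    """Assemble one entity+feature's records into a symmetric matrix."""
    if not records:
        raise ValueError("no records")
    entity = records[0].entity_id
    feature = records[0].feature
    labels = list(panel.populations)
    idx = {p: i for i, p in enumerate(labels)}
    values = np.zeros((len(labels), len(labels)))
    seen: dict[tuple[int, int], float] = {}
    for rec in records:
        if rec.entity_id != entity or rec.feature != feature:
            raise ValueError("records span multiple entities/features")
        i, j = sorted((idx[rec.pop_i], idx[rec.pop_j]))
        if (i, j) in seen and not np.isclose(seen[(i, j)], rec.value, equal_nan=True):
            raise ValueError(f"conflicting duplicate record for pair ({i},{j})")
        seen[(i, j)] = rec.value
        values[i, j] = values[j, i] = rec.value
    return DifferenceMatrix(entity_id=entity, feature=feature, labels=labels, values=values)


def summarize(
    matrix: DifferenceMatrix, query_pair: tuple[str, str] | None = None
) -> ReferenceSummary:
    """Boxplot five-number summary of all pairwise differences.

    Quartiles use linear interpolation (Tukey/NumPy default); the
    percentile rank of a queried pair is the fraction of values
    strictly below it, times 100.
    """
    n = len(matrix.labels)
    iu = np.triu_indices(n, k=1)
    vals = matrix.values[iu]
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        raise ValueError("no non-missing pairwise values")
    box = (
        float(vals.min()),
        float(np.percentile(vals, 25)),
        float(np.percentile(vals, 50)),
        float(np.percentile(vals, 75)),
        float(vals.max()),
    )
    rank = None
    if query_pair is not None:
        idx = {p: i for i, p in enumerate(matrix.labels)}
        q = matrix.values[idx[query_pair[0]], idx[query_pair[1]]]
        rank = float(100.0 * np.sum(vals < q) / len(vals))
    return ReferenceSummary(
        entity_id=matrix.entity_id,
        feature=matrix.feature,
        all_values=vals,
        boxplot=box,
        percentile_rank=rank,
    )
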