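"""Greedy pairwise tagSNP selection and cross-population transferability.

Tags are chosen by greedy set cover on the pairwise r-squared graph: a
SNP covers itself and every SNP with r2 >= threshold (default 0.8).
Transferability evaluates one population's tags in another: a SNP in
the target population is captured if its r2 (computed in the target
population) with at least one tag strictly exceeds the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_R2_THRESHOLD = 0.8


@dataclass
class TagSet:
    gene_id: str
    population: str
    tag_indices: list[int]
    r2_threshold: float


@dataclass
class TransferabilityResult:
    gene_id: str
    pop_from: str  # population whose tags are evaluated
    pop_to: str  # population in which capture is measured
    captured_percent: float  # in [0, 100]
    avg_max_r2: float  # in [0, 1]; NaN when nothing is captured


def _r2_lookup(pair_r2: dict[tuple[int, int], float], a: int, b: int) -> float:
    if a == b:
        return 1.0
    key = (a, b) if a < b else (b, a)
    val = pair_r2.get(key, float("nan"))
    return 0.0 if np.isnan(val) else val  # undefined pairs treated as r2 = 0


def select_tags_greedy(
    pair_r2: dict[tuple[int, int], float],
    snp_indices: np.ndarray | list[int],
    gene_id: str = "",
    population: str = "",
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> TagSet:
    """Greedy cover: repeatedly pick the SNP tagging the most uncovered SNPs.

    A SNP covers those with r2 >= threshold (itself included); ties go
    to the lower column index.  Terminates when every SNP is covered,
    so the coverage property holds by construction (and is re-checked).
    """
    snps = [int(s) for s in snp_indices]
    if len(snps) < 2:
        raise ValueError("tag selection needs >=2 SNPs")
    covers = {
        s: {t for t in snps if _r2_lookup(pair_r2, s, t) >= r2_threshold} | {s}
        for s in snps
    }
    uncovered = set(snps)
    tags: list[int] = []
    while uncovered:
        best = max(snps, key=lambda s: (len(covers[s] & uncovered), -s))
        tags.append(best)
        uncovered -= covers[best]
    assert not uncovered, "tagger coverage property violated"
    return TagSet(
        gene_id=gene_id,
        population=population,
        tag_indices=sorted(tags),
        r2_threshold=r2_threshold,
    )


def tag_percent(tagset: TagSet, n_snps: int) -> float:
    """100 * |tags| / m."""
    if n_snps < 1:
        raise ValueError("gene has no SNPs")
    return 100.0 * len(tagset.tag_indices) / n_snps


def transferability(
    tags_from: TagSet,
    target_pair_r2: dict[tuple[int, int], float],
    target_snp_indices: np.ndarray | list[int],
    gene_id: str = "",
    pop_from: str = "",
    pop_to: str = "",
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> TransferabilityResult:
    """Evaluate ``tags_from`` (population B) in a target population A.

    Capture uses strict r2 > threshold, with r2 computed in the target
    population; tags absent from the target SNP set are unusable.
    captured_percent is over all target SNPs; avg_max_r2 averages, over
    captured SNPs, the maximum r2 with any usable tag.
    """
    target = [int(s) for s in target_snp_indices]
    usable_tags = [t for t in tags_from.tag_indices if t in set(target)]
    if not usable_tags or not target:
        return TransferabilityResult(
            gene_id=gene_id,
            pop_from=pop_from,
            pop_to=pop_to,
            captured_percent=0.0,
            avg_max_r2=float("nan"),
        )
    max_r2 = []
    for s in target:
        max_r2.append(max(_r2_lookup(target_pair_r2, s, t) for t in usable_tags))
    max_r2 = np.array(max_r2)
    captured = max_r2 > r2_threshold
    pct = 100.0 * captured.sum() / len(target)
    avg = float(max_r2[captured].mean()) if captured.any() else float("nan")
    return TransferabilityResult(
        gene_id=gene_id,
        pop_from=pop_from,
        pop_to=pop_to,
        captured_percent=float(pct),
        avg_max_r2=avg,
    )
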