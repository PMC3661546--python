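"""End-to-end orchestration: genotypes in, difference records out.

For every retained gene the pipeline computes, per population, the 11
population-genetic features (reference-oriented allele frequencies,
pairwise r2 and D' maps, four-gamete block summaries, haplotype
diversity, tagSNP statistics), differences them between every
unordered population pair, optionally aggregates gene records to
gene-set scores, and writes long-format TSV output with a JSON
manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .allele_freq import gene_fst_from_table, maf_difference, orient_and_frequencies
from .differences import (
    FEATURES,
    DifferenceRecord,
    directed_pair_difference,
    scalar_feature_difference,
    vector_feature_difference,
)
from .genesets import score_all_sets
from .genotype_io import (
    GeneCatalogue,
    GeneSetCollection,
    PopulationPanel,
    QCThresholds,
    VariantTable,
    apply_qc,
    assign_snps_to_genes,
)
from .ld_haplotype import (
    DEFAULT_FOURTH_GAMETE_THRESHOLD,
    DEFAULT_PL_THRESHOLD,
    gene_ld_features,
)
from .tagging import (
    DEFAULT_R2_THRESHOLD,
    select_tags_greedy,
    tag_percent,
    transferability,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    reference_population: str | None = None  # default: first panel population
    qc: QCThresholds | None = None  # None = skip QC
    qc_mode: str = "per_population"
    r2_threshold: float = DEFAULT_R2_THRESHOLD
    fourth_gamete_threshold: float = DEFAULT_FOURTH_GAMETE_THRESHOLD
    pl_threshold: int = DEFAULT_PL_THRESHOLD
    max_pair_distance: int | None = None
    features: tuple[str, ...] = FEATURES

    def __post_init__(self) -> None:
        unknown = set(self.features) - set(FEATURES)
        if unknown:
            raise ValueError(f"unknown features: {sorted(unknown)}")


def compute_gene_records(
    vt: VariantTable,
    panel: PopulationPanel,
    catalogue: GeneCatalogue,
    config: RunConfig | None = None,
) -> list[DifferenceRecord]:
    """Per-gene difference records for every feature and population pair.

    ``catalogue`` must already have SNP assignments (see
    :func:`popgendiff.genotype_io.assign_snps_to_genes`).
    """
    cfg = config or RunConfig()
    ref_pop = cfg.reference_population or panel.populations[0]
    rows = panel.sample_indices(vt)
    pops = panel.populations
    want = set(cfg.features)
    need_ld = want & {"r2", "dprime", "block_number", "block_size", "snp_density",
                      "hap_diversity", "tag_percent", "captured_percent", "avg_max_r2"}
    need_tags = want & {"tag_percent", "captured_percent", "avg_max_r2"}
    records: list[DifferenceRecord] = []

    for gene in catalogue:
        fvs = None
        if "maf" in want:
            fv_list, _ = orient_and_frequencies(vt, panel, gene, ref_pop)
            fvs = {fv.population: fv for fv in fv_list}
        ld_by_pop = {}
        tags_by_pop = {}
        if need_ld:
            for pop in pops:
                ld_by_pop[pop] = gene_ld_features(
                    vt,
                    rows[pop],
                    gene,
                    pop,
                    fourth_gamete_threshold=cfg.fourth_gamete_threshold,
                    pl_threshold=cfg.pl_threshold,
                    max_pair_distance=cfg.max_pair_distance,
                )
        if need_tags:
            for pop in pops:
                tags_by_pop[pop] = select_tags_greedy(
                    ld_by_pop[pop].pair_r2,
                    gene.snp_indices,
                    gene_id=gene.gene_id,
                    population=pop,
                    r2_threshold=cfg.r2_threshold,
                )

        for i in range(len(pops)):
            for j in range(i + 1, len(pops)):
                pi, pj = pops[i], pops[j]
                vals: dict[str, float] = {}
                if "maf" in want:
                    vals["maf"] = maf_difference(fvs[pi], fvs[pj])
                if "fst" in want:
                    vals["fst"] = gene_fst_from_table(vt, panel, gene, pi, pj)
                if need_ld:
                    li, lj = ld_by_pop[pi], ld_by_pop[pj]
                    if "r2" in want:
                        vals["r2"] = vector_feature_difference(li.pair_r2, lj.pair_r2)
                    if "dprime" in want:
                        vals["dprime"] = vector_feature_difference(
                            li.pair_dprime, lj.pair_dprime
                        )
                    for feat, attr in (
                        ("block_number", "block_number"),
                        ("block_size", "mean_block_size"),
                        ("snp_density", "snp_density"),
                        ("hap_diversity", "haplotype_diversity"),
                    ):
                        if feat in want:
                            vals[feat] = scalar_feature_difference(
                                getattr(li, attr), getattr(lj, attr)
                            )
                if need_tags:
                    if "tag_percent" in want:
                        vals["tag_percent"] = scalar_feature_difference(
                            tag_percent(tags_by_pop[pi], gene.n_snps),
                            tag_percent(tags_by_pop[pj], gene.n_snps),
                        ) / 100.0
                    if {"captured_percent", "avg_max_r2"} & want:
                        t_ij = transferability(
                            tags_by_pop[pi],
                            ld_by_pop[pj].pair_r2,
                            gene.snp_indices,
                            gene_id=gene.gene_id,
                            pop_from=pi,
                            pop_to=pj,
                            r2_threshold=cfg.r2_threshold,
                        )
                        t_ji = transferability(
                            tags_by_pop[pj],
                            ld_by_pop[pi].pair_r2,
                            gene.snp_indices,
                            gene_id=gene.gene_id,
                            pop_from=pj,
                            pop_to=pi,
                            r2_threshold=cfg.r2_threshold,
                        )
                        if "captured_percent" in want:
                            vals["captured_percent"] = directed_pair_difference(
                                t_ij.captured_percent, t_ji.captured_percent, perfect=100.0
                            )
                        if "avg_max_r2" in want:
                            vals["avg_max_r2"] = directed_pair_difference(
                                t_ij.avg_max_r2, t_ji.avg_max_r2, perfect=1.0
                            )
                for feat in cfg.features:
                    records.append(
                        DifferenceRecord(
                            entity_id=gene.gene_id,
                            entity_type="gene",
                            feature=feat,
                            pop_i=pi,
                            pop_j=pj,
                            value=vals[feat],
                        )
                    )
    return records


def records_to_frame(records: list[DifferenceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "entity_id": [r.entity_id for r in records],
            "entity_type": [r.entity_type for r in records],
            "feature": [r.feature for r in records],
            "pop_i": [r.pop_i for r in records],
            "pop_j": [r.pop_j for r in records],
            "value": [r.value for r in records],
        }
    )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    vt: VariantTable,
    panel: PopulationPanel,
    catalogue: GeneCatalogue,
    out_dir: str,
    config: RunConfig | None = None,
    sets: GeneSetCollection | None = None,
    input_paths: dict[str, str] | None = None,
) -> dict:
    """QC, gene features, differences and set scores in one run.

    Writes ``gene_differences.tsv`` (and ``set_differences.tsv`` when
    gene sets are given) plus ``manifest.json`` recording configuration,
    input checksums and per-stage counts.  Returns the manifest dict.
    """
    cfg = config or RunConfig()
    os.makedirs(out_dir, exist_ok=True)
    t0 = time.time()
    stages: dict[str, dict] = {}

    n_in = vt.n_snps
    if cfg.qc is not None:
        vt, qc_report = apply_qc(vt, panel, cfg.qc, mode=cfg.qc_mode)
        stages["qc"] = {
            "snps_in": qc_report.n_input,
            "snps_retained": qc_report.n_retained,
            "removed_hwe": qc_report.removed_hwe,
            "removed_call_rate": qc_report.removed_call_rate,
            "removed_maf": qc_report.removed_maf,
        }
        logger.info("qc: %d -> %d SNPs", n_in, vt.n_snps)
    genes_in = len(catalogue)
    catalogue = assign_snps_to_genes(vt, catalogue, min_snps=2)
    stages["genes"] = {"genes_in": genes_in, "genes_retained": len(catalogue),
                       "genes_dropped": genes_in - len(catalogue)}

    gene_records = compute_gene_records(vt, panel, catalogue, cfg)
    gene_path = os.path.join(out_dir, "gene_differences.tsv")
    records_to_frame(gene_records).to_csv(gene_path, sep="\t", index=False)
    stages["gene_diff"] = {"records": len(gene_records)}

    outputs = {"gene_differences": gene_path}
    if sets is not None:
        set_records = score_all_sets(gene_records, sets)
        set_path = os.path.join(out_dir, "set_differences.tsv")
        records_to_frame(set_records).to_csv(set_path, sep="\t", index=False)
        stages["set_diff"] = {"sets": len(sets), "records": len(set_records)}
        outputs["set_differences"] = set_path

    manifest = {
        "version": __version__,
        "config": {
            "reference_population": cfg.reference_population or panel.populations[0],
            "qc": None
            if cfg.qc is None
            else {
                "hwe_p_min": cfg.qc.hwe_p_min,
                "call_rate_min": cfg.qc.call_rate_min,
                "maf_min": cfg.qc.maf_min,
                "mode": cfg.qc_mode,
            },
            "r2_threshold": cfg.r2_threshold,
            "fourth_gamete_threshold": cfg.fourth_gamete_threshold,
            "features": list(cfg.features),
        },
        "inputs": {k: _sha256(p) for k, p in (input_paths or {}).items()},
        "populations": panel.populations,
        "stages": stages,
        "outputs": outputs,
        "elapsed_s": round(time.time() - t0, 3),
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
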