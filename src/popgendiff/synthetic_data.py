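"""HapMap-like synthetic genotype fixtures.

Allele frequencies follow the Balding-Nichols model: an ancestral
frequency p ~ Uniform(0.05, 0.95) per SNP, and each population drawing
its frequency from Beta(p(1-F)/F, (1-p)(1-F)/F), so F controls
differentiation (F = 0 copies the ancestral frequency exactly).
Within-gene LD comes from a haplotype-pool scheme: genes are tiled by
blocks of ``block_length`` SNPs, each population draws a small pool of
haplotypes per block from its frequencies, and every diploid samples
two pool haplotypes — strong LD within blocks, equilibrium between
them.  Genotypes are then thinned to missing uniformly at random.

Defaults describe a small three-population study: 40 diploids per
population, 20 genes of 32 SNPs over 20 kb (~1.6 SNPs/kb), F = 0.05
(continental-scale differentiation), one gene-spanning LD block drawn
from a pool of 6 haplotypes (limited haplotype diversity, as in human
gene regions), and 2% missing calls.  ``haplotypes_per_block=None``
disables the pool and draws every chromosome independently from the
population frequencies — the plain Balding-Nichols genotype model, no
LD.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .genotype_io import (
    MISSING,
    GeneCatalogue,
    GeneRegion,
    GeneSet,
    GeneSetCollection,
    PopulationPanel,
    VariantTable,
)

GENE_SPACING_BP = 100_000  # distance between synthetic gene starts
GENE_SPAN_BP = 20_000  # span of each synthetic gene region
GENES_PER_CHROM = 10


@dataclass
class SimulationConfig:
    n_populations: int = 3
    samples_per_population: int = 40
    n_genes: int = 20
    snps_per_gene: int = 32
    balding_nichols_F: float | list[float] = 0.05
    block_length: int = 32
    haplotypes_per_block: int | None = 6  # None: infinite pool (no LD)
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        fs = self.f_per_population
        if any(not 0 <= f < 1 for f in fs):
            raise ValueError("balding_nichols_F must be in [0, 1)")
        if not 0 <= self.missing_rate <= 0.5:
            raise ValueError("missing_rate must be in [0, 0.5]")
        for name in (
            "n_populations",
            "samples_per_population",
            "n_genes",
            "snps_per_gene",
            "block_length",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.haplotypes_per_block is not None and self.haplotypes_per_block < 1:
            raise ValueError("haplotypes_per_block must be positive or None")

    @property
    def f_per_population(self) -> list[float]:
        f = self.balding_nichols_F
        if isinstance(f, (int, float)):
            return [float(f)] * self.n_populations
        if len(f) != self.n_populations:
            raise ValueError("need one F per population")
        return [float(x) for x in f]

    @property
    def n_snps(self) -> int:
        return self.n_genes * self.snps_per_gene

    @property
    def population_labels(self) -> list[str]:
        return [f"POP{i + 1}" for i in range(self.n_populations)]


def simulate_frequencies(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Balding-Nichols ancestral and per-population allele frequencies.

    Returns (ancestral, per_pop) with shapes (n_snps,) and
    (n_populations, n_snps).
    """
    rng = rng or np.random.default_rng(config.seed)
    p = rng.uniform(0.05, 0.95, size=config.n_snps)
    per_pop = np.empty((config.n_populations, config.n_snps))
    for i, f in enumerate(config.f_per_population):
        if f == 0:
            per_pop[i] = p
        else:
            scale = (1 - f) / f
            per_pop[i] = rng.beta(p * scale, (1 - p) * scale)
    return p, per_pop


def simulate_genotypes(
    frequencies: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[VariantTable, PopulationPanel]:
    """Sample diploid genotypes from per-population haplotype pools.

    ``frequencies`` is the (n_populations, n_snps) array from
    :func:`simulate_frequencies`.  Within every ``block_length``-SNP
    block each population draws ``haplotypes_per_block`` haplotypes
    from its frequencies; each diploid is two independent draws from
    that pool.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    n_pop, n_snps = frequencies.shape
    n_per = config.samples_per_population
    genotypes = np.empty((n_pop * n_per, n_snps), dtype=np.int8)
    starts = range(0, n_snps, config.block_length)
    for pop in range(n_pop):
        row0 = pop * n_per
        if config.haplotypes_per_block is None:
            genotypes[row0 : row0 + n_per, :] = rng.binomial(
                2, frequencies[pop], size=(n_per, n_snps)
            ).astype(np.int8)
            continue
        for s in starts:
            e = min(s + config.block_length, n_snps)
            pool = (
                rng.random((config.haplotypes_per_block, e - s)) < frequencies[pop, s:e]
            ).astype(np.int8)
            picks = rng.integers(0, config.haplotypes_per_block, size=(n_per, 2))
            genotypes[row0 : row0 + n_per, s:e] = pool[picks[:, 0]] + pool[picks[:, 1]]
    if config.missing_rate > 0:
        mask = rng.random(genotypes.shape) < config.missing_rate
        genotypes[mask] = MISSING

    chrom, pos, snp_ids = _snp_coordinates(config, rng)
    sample_ids = [
        f"{lab}_S{i + 1}" for lab in config.population_labels for i in range(n_per)
    ]
    vt = VariantTable(
        snp_ids=snp_ids,
        chrom=chrom,
        pos=pos,
        ref_allele=np.array(["A"] * n_snps, dtype=object),
        alt_allele=np.array(["G"] * n_snps, dtype=object),
        genotypes=genotypes,
        sample_ids=sample_ids,
    )
    panel = PopulationPanel(
        sample_to_population={
            s: config.population_labels[i // n_per] for i, s in enumerate(sample_ids)
        },
        populations=config.population_labels,
    )
    return vt, panel


def _snp_coordinates(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Gene-tiled coordinates: genes laid out along numbered chromosomes."""
    chrom: list[str] = []
    pos: list[int] = []
    snp_ids: list[str] = []
    for g in range(config.n_genes):
        c = f"chr{g // GENES_PER_CHROM + 1:02d}"
        start = (g % GENES_PER_CHROM) * GENE_SPACING_BP + 1_000
        offsets = np.sort(
            rng.choice(np.arange(1, GENE_SPAN_BP), size=config.snps_per_gene, replace=False)
        )
        for k, off in enumerate(offsets):
            chrom.append(c)
            pos.append(start + int(off))
            snp_ids.append(f"rs_g{g + 1}_{k + 1}")
    return np.array(chrom, dtype=object), np.array(pos, dtype=np.int64), snp_ids


def gene_catalogue(config: SimulationConfig) -> GeneCatalogue:
    """Gene regions matching the generator's tiling (0-based half-open)."""
    genes = []
    for g in range(config.n_genes):
        c = f"chr{g // GENES_PER_CHROM + 1:02d}"
        start = (g % GENES_PER_CHROM) * GENE_SPACING_BP + 1_000
        genes.append(
            GeneRegion(
                gene_id=f"GENE{g + 1}",
                chrom=c,
                start=start,
                end=start + GENE_SPAN_BP + 1,
            )
        )
    return GeneCatalogue(genes=genes)


def gene_sets(
    config: SimulationConfig,
    n_sets: int = 4,
    genes_per_set: int = 10,
    rng: np.random.Generator | None = None,
    category: str = "pathway",
) -> GeneSetCollection:
    """Random gene sets over the synthetic catalogue."""
    rng = rng or np.random.default_rng(config.seed + 2)
    all_genes = [f"GENE{g + 1}" for g in range(config.n_genes)]
    k = min(genes_per_set, len(all_genes))
    sets = [
        GeneSet(
            set_id=f"SET{i + 1}",
            set_name=f"synthetic set {i + 1}",
            gene_ids=[all_genes[j] for j in sorted(rng.choice(len(all_genes), k, replace=False))],
            category=category,
        )
        for i in range(n_sets)
    ]
    return GeneSetCollection(sets=sets)


def simulate(config: SimulationConfig) -> tuple[VariantTable, PopulationPanel, GeneCatalogue]:
    """One-call generator: frequencies, genotypes and the gene catalogue."""
    rng = np.random.default_rng(config.seed)
    _, freqs = simulate_frequencies(config, rng)
    vt, panel = simulate_genotypes(freqs, config, rng)
    return vt, panel, gene_catalogue(config)


# ---------------------------------------------------------------------------
# Fixture files
# ---------------------------------------------------------------------------


def write_vcf(vt: VariantTable, path: str) -> None:
    """Write a minimal GT-only VCF (uncompressed text)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in sorted(set(vt.chrom.tolist()), key=str):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(vt.sample_ids)
            + "\n"
        )
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j in range(vt.n_snps):
            gts = "\t".join(gt_map[int(d)] for d in vt.genotypes[:, j])
            fh.write(
                f"{vt.chrom[j]}\t{int(vt.pos[j])}\t{vt.snp_ids[j]}\t"
                f"{vt.ref_allele[j]}\t{vt.alt_allele[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_panel(panel: PopulationPanel, path: str) -> None:
    with open(path, "w") as fh:
        for s, p in panel.sample_to_population.items():
            fh.write(f"{s}\t{p}\n")


def write_bed(catalogue: GeneCatalogue, path: str) -> None:
    with open(path, "w") as fh:
        for g in catalogue:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\n")


def write_gmt(collection: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.set_id, s.set_name] + s.gene_ids) + "\n")


def write_fixtures(
    vt: VariantTable,
    panel: PopulationPanel,
    catalogue: GeneCatalogue,
    sets: GeneSetCollection | None,
    out_dir: str,
) -> dict[str, str]:
    """Emit VCF, panel TSV, BED and GMT files that round-trip losslessly."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "genotypes.vcf"),
        "panel": os.path.join(out_dir, "panel.tsv"),
        "bed": os.path.join(out_dir, "genes.bed"),
    }
    write_vcf(vt, paths["vcf"])
    write_panel(panel, paths["panel"])
    write_bed(catalogue, paths["bed"])
    if sets is not None:
        paths["gmt"] = os.path.join(out_dir, "sets.gmt")
        write_gmt(sets, paths["gmt"])
    return paths
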