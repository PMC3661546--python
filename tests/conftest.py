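import numpy as np
import pytest

from popgendiff.genotype_io import PopulationPanel, VariantTable, assign_snps_to_genes
from popgendiff.synthetic_data import SimulationConfig, gene_catalogue, simulate


@pytest.fixture(scope="session")
def small_sim():
    """A small three-population dataset with gene-spanning LD blocks."""
    cfg = SimulationConfig(
        n_populations=3,
        samples_per_population=30,
        n_genes=4,
        snps_per_gene=12,
        block_length=12,
        haplotypes_per_block=5,
        missing_rate=0.02,
        seed=7,
    )
    vt, panel, catalogue = simulate(cfg)
    catalogue = assign_snps_to_genes(vt, catalogue)
    return cfg, vt, panel, catalogue


def make_table(dosages, pos=None, chrom=None, sample_prefix="S"):
    """VariantTable from a plain samples x SNPs dosage list."""
    g = np.asarray(dosages, dtype=np.int8)
    n_samples, n_snps = g.shape
    return VariantTable(
        snp_ids=[f"snp{j + 1}" for j in range(n_snps)],
        chrom=np.array(chrom or ["1"] * n_snps, dtype=object),
        pos=np.array(pos if pos is not None else np.arange(1, n_snps + 1) * 100),
        ref_allele=np.array(["A"] * n_snps, dtype=object),
        alt_allele=np.array(["G"] * n_snps, dtype=object),
        genotypes=g,
        sample_ids=[f"{sample_prefix}{i + 1}" for i in range(n_samples)],
    )


def make_panel(assignments):
    """PopulationPanel from an ordered {sample: population} dict."""
    pops = []
    for p in assignments.values():
        if p not in pops:
            pops.append(p)
    return PopulationPanel(sample_to_population=dict(assignments), populations=pops)
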