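"""Genotype, panel, gene-region and gene-set input with quality control.

Genotypes are stored as alternate-allele dosages (0, 1, 2) in a dense
samples x SNPs matrix; missing calls are coded :data:`MISSING`.  Quality
control follows the conventional three-filter scheme (Hardy-Weinberg
exact test, call rate, minor allele frequency), applied per population:
a SNP is retained only if it passes every filter in every population.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

#: Sentinel dosage for a missing genotype call.
MISSING: int = -1

#: Default QC thresholds: HWE exact p >= 0.001, call rate >= 0.75, MAF >= 0.01.
DEFAULT_HWE_P_MIN = 0.001
DEFAULT_CALL_RATE_MIN = 0.75
DEFAULT_MAF_MIN = 0.01


class GenotypeIOError(ValueError):
    """Malformed or unusable genotype/panel/region/set input."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class VariantTable:
    """Bi-allelic SNP metadata plus a samples x SNPs dosage matrix.

    Columns are sorted by (chrom, pos); positions are 1-based; dosages
    count alternate alleles, with :data:`MISSING` for no-calls.
    """

    snp_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    genotypes: np.ndarray  # int8, shape (n_samples, n_snps)
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref_allele = np.asarray(self.ref_allele, dtype=object)
        self.alt_allele = np.asarray(self.alt_allele, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise GenotypeIOError("genotype matrix must be 2-D (samples x SNPs)")
        n_samples, n_snps = self.genotypes.shape
        if n_samples != len(self.sample_ids):
            raise GenotypeIOError("sample_ids length does not match matrix rows")
        for arr, name in [
            (self.snp_ids, "snp_ids"),
            (self.chrom, "chrom"),
            (self.pos, "pos"),
            (self.ref_allele, "ref_allele"),
            (self.alt_allele, "alt_allele"),
        ]:
            if len(arr) != n_snps:
                raise GenotypeIOError(f"{name} length does not match matrix columns")
        bad = ~np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if bad.any():
            raise GenotypeIOError("dosages must be 0, 1, 2 or missing")
        keys = list(zip(self.chrom.tolist(), self.pos.tolist()))
        if keys != sorted(keys):
            raise GenotypeIOError("SNP columns must be sorted by (chrom, pos)")
        if len(set(keys)) != len(keys):
            raise GenotypeIOError("duplicate (chrom, pos) positions")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def take_snps(self, indices: np.ndarray | list[int]) -> "VariantTable":
        """New table keeping the given SNP columns (order preserved)."""
        idx = np.asarray(indices, dtype=np.int64)
        return VariantTable(
            snp_ids=[self.snp_ids[i] for i in idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref_allele=self.ref_allele[idx],
            alt_allele=self.alt_allele[idx],
            genotypes=self.genotypes[:, idx],
            sample_ids=list(self.sample_ids),
        )

    def take_samples(self, indices: np.ndarray | list[int]) -> "VariantTable":
        idx = np.asarray(indices, dtype=np.int64)
        return VariantTable(
            snp_ids=list(self.snp_ids),
            chrom=self.chrom,
            pos=self.pos,
            ref_allele=self.ref_allele,
            alt_allele=self.alt_allele,
            genotypes=self.genotypes[idx, :],
            sample_ids=[self.sample_ids[i] for i in idx],
        )


@dataclass
class PopulationPanel:
    """Sample-to-population assignment with a stable population order."""

    sample_to_population: dict[str, str]
    populations: list[str]

    def __post_init__(self) -> None:
        if len(self.populations) < 2:
            raise GenotypeIOError("panel needs at least 2 populations")
        counts = {p: 0 for p in self.populations}
        for s, p in self.sample_to_population.items():
            if p not in counts:
                raise GenotypeIOError(f"sample {s!r} in unknown population {p!r}")
            counts[p] += 1
        small = [p for p, c in counts.items() if c < 2]
        if small:
            raise GenotypeIOError(f"populations with <2 samples: {small}")

    def members(self, population: str) -> list[str]:
        return [s for s, p in self.sample_to_population.items() if p == population]

    def sample_indices(self, vt: VariantTable) -> dict[str, np.ndarray]:
        """Row indices of ``vt.genotypes`` per population."""
        out: dict[str, list[int]] = {p: [] for p in self.populations}
        for i, s in enumerate(vt.sample_ids):
            out[self.sample_to_population[s]].append(i)
        return {p: np.asarray(ix, dtype=np.int64) for p, ix in out.items()}


@dataclass
class GeneRegion:
    gene_id: str
    chrom: str
    start: int  # 0-based, half-open
    end: int
    snp_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise GenotypeIOError(f"gene {self.gene_id}: start must be < end")
        self.snp_indices = np.asarray(self.snp_indices, dtype=np.int64)
        if np.any(np.diff(self.snp_indices) <= 0):
            raise GenotypeIOError(f"gene {self.gene_id}: snp_indices not increasing")

    @property
    def n_snps(self) -> int:
        return len(self.snp_indices)

    @property
    def span_bp(self) -> int:
        return self.end - self.start


@dataclass
class GeneCatalogue:
    genes: list[GeneRegion]

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def get(self, gene_id: str) -> GeneRegion:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass
class GeneSet:
    set_id: str
    set_name: str
    gene_ids: list[str]
    category: str = "custom"  # pathway | BP | MF | CC | custom

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise GenotypeIOError(f"set {self.set_id}: duplicate gene ids")


@dataclass
class GeneSetCollection:
    sets: list[GeneSet]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class QCThresholds:
    hwe_p_min: float = DEFAULT_HWE_P_MIN
    call_rate_min: float = DEFAULT_CALL_RATE_MIN
    maf_min: float = DEFAULT_MAF_MIN

    def __post_init__(self) -> None:
        if not 0 < self.hwe_p_min < 1:
            raise GenotypeIOError("hwe_p_min must be in (0,1)")
        if not 0 < self.call_rate_min <= 1:
            raise GenotypeIOError("call_rate_min must be in (0,1]")
        if not 0 <= self.maf_min < 0.5:
            raise GenotypeIOError("maf_min must be in [0, 0.5)")


@dataclass
class QCReport:
    n_input: int
    n_retained: int
    removed_hwe: int
    removed_call_rate: int
    removed_maf: int


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_vcf(path: str, region_filter: str | None = None) -> VariantTable:
    """Read bi-allelic SNPs from a VCF into a :class:`VariantTable`.

    Multi-allelic and non-SNP records are skipped (the skip count is
    logged).  Half-calls and missing GT fields become missing dosages.
    Duplicate (chrom, pos) among usable records is a hard error.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error paths
        raise GenotypeIOError(f"cannot read VCF {path}: {exc}") from exc
    sample_ids = list(vcf.samples)
    snp_ids: list[str] = []
    chrom: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    rows: list[np.ndarray] = []
    skipped = 0
    it = vcf(region_filter) if region_filter else vcf
    for v in it:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            skipped += 1
            continue
        dos = np.full(len(sample_ids), MISSING, dtype=np.int8)
        for i, g in enumerate(v.genotypes):
            a, b = g[0], g[1]
            if a >= 0 and b >= 0:
                dos[i] = a + b
        snp_ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        rows.append(dos)
    vcf.close()
    if skipped:
        logger.info("read_vcf: skipped %d multi-allelic/non-SNP records", skipped)
    if not rows:
        raise GenotypeIOError(f"no usable bi-allelic SNP records in {path}")
    order = sorted(range(len(pos)), key=lambda i: (chrom[i], pos[i]))
    keys = [(chrom[i], pos[i]) for i in order]
    if len(set(keys)) != len(keys):
        raise GenotypeIOError("duplicate (chrom, pos) records in VCF")
    return VariantTable(
        snp_ids=[snp_ids[i] for i in order],
        chrom=np.array([chrom[i] for i in order], dtype=object),
        pos=np.array([pos[i] for i in order], dtype=np.int64),
        ref_allele=np.array([ref[i] for i in order], dtype=object),
        alt_allele=np.array([alt[i] for i in order], dtype=object),
        genotypes=np.stack([rows[i] for i in order], axis=1),
        sample_ids=sample_ids,
    )


def read_genotype_tsv(path: str) -> VariantTable:
    """Read the plain TSV genotype dialect.

    Header row lists sample ids; each data row is
    ``snp_id chrom pos ref alt dosage...`` with ``.`` for missing.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        sample_ids = header[5:]
        snp_ids, chrom, pos, ref, alt, rows = [], [], [], [], [], []
        for ln, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5 + len(sample_ids):
                raise GenotypeIOError(f"{path}:{ln}: wrong field count")
            snp_ids.append(parts[0])
            chrom.append(parts[1])
            pos.append(int(parts[2]))
            ref.append(parts[3])
            alt.append(parts[4])
            rows.append(
                [MISSING if x == "." else int(x) for x in parts[5:]]
            )
    if not rows:
        raise GenotypeIOError(f"no SNP rows in {path}")
    order = sorted(range(len(pos)), key=lambda i: (chrom[i], pos[i]))
    return VariantTable(
        snp_ids=[snp_ids[i] for i in order],
        chrom=np.array([chrom[i] for i in order], dtype=object),
        pos=np.array([pos[i] for i in order], dtype=np.int64),
        ref_allele=np.array([ref[i] for i in order], dtype=object),
        alt_allele=np.array([alt[i] for i in order], dtype=object),
        genotypes=np.array([rows[i] for i in order], dtype=np.int8).T,
        sample_ids=sample_ids,
    )


def write_genotype_tsv(vt: VariantTable, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(["snp_id", "chrom", "pos", "ref", "alt"] + vt.sample_ids))
        fh.write("\n")
        for j in range(vt.n_snps):
            dos = [
                "." if d == MISSING else str(int(d)) for d in vt.genotypes[:, j]
            ]
            fh.write(
                "\t".join(
                    [
                        vt.snp_ids[j],
                        str(vt.chrom[j]),
                        str(int(vt.pos[j])),
                        str(vt.ref_allele[j]),
                        str(vt.alt_allele[j]),
                    ]
                    + dos
                )
            )
            fh.write("\n")


def read_population_panel(
    path: str, population_order: list[str] | None = None
) -> PopulationPanel:
    """Read a two-column TSV (sample_id, population).

    Population order is first appearance unless ``population_order``
    overrides it.  A duplicated sample id is an error.
    """
    mapping: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise GenotypeIOError(f"{path}:{ln}: expected 2 tab-separated fields")
            sample, popn = parts
            if sample in mapping:
                raise GenotypeIOError(f"{path}:{ln}: duplicate sample {sample!r}")
            mapping[sample] = popn
            if popn not in order:
                order.append(popn)
    if population_order is not None:
        if set(population_order) != set(order):
            raise GenotypeIOError("population_order does not match panel populations")
        order = list(population_order)
    return PopulationPanel(sample_to_population=mapping, populations=order)


def harmonize(vt: VariantTable, panel: PopulationPanel) -> tuple[VariantTable, PopulationPanel]:
    """Restrict table and panel to their shared samples.

    Panel samples absent from the table are dropped with a warning, and
    vice versa, so that the panel invariant (every table sample mapped
    exactly once) holds on the returned pair.
    """
    table_samples = set(vt.sample_ids)
    panel_samples = set(panel.sample_to_population)
    only_panel = sorted(panel_samples - table_samples)
    only_table = sorted(table_samples - panel_samples)
    if only_panel:
        logger.warning("dropping %d panel samples absent from genotypes", len(only_panel))
    if only_table:
        logger.warning("dropping %d genotyped samples absent from panel", len(only_table))
    shared = [s for s in vt.sample_ids if s in panel_samples]
    vt2 = vt.take_samples([vt.sample_ids.index(s) for s in shared])
    mapping = {s: panel.sample_to_population[s] for s in shared}
    pops = [p for p in panel.populations if p in set(mapping.values())]
    return vt2, PopulationPanel(sample_to_population=mapping, populations=pops)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities
    of all heterozygote counts that are no more probable than the
    observed one (Levene/Haldane conditional distribution).
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0 or int(c) != c:
            raise GenotypeIOError("genotype counts must be nonnegative integers")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise GenotypeIOError("at least one genotype required")
    nA = 2 * n_AA + n_Aa
    na = 2 * n_aa + n_Aa
    if nA == 0 or na == 0:
        return 1.0
    # Conditional probability of h hets given allele counts:
    #   P(h) = n! / (nAA! h! naa!) * 2^h * nA! na! / (2n)!
    h_values = np.arange(nA % 2, min(nA, na) + 1, 2)
    log_probs = np.array([_log_hwe_prob(n, nA, int(h)) for h in h_values])
    log_probs -= log_probs.max()
    probs = np.exp(log_probs)
    probs /= probs.sum()
    p_obs = probs[np.where(h_values == n_Aa)[0][0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _log_hwe_prob(n: int, nA: int, h: int) -> float:
    n_hom_A = (nA - h) // 2
    n_hom_a = n - n_hom_A - h
    return (
        math.lgamma(n + 1)
        - math.lgamma(n_hom_A + 1)
        - math.lgamma(h + 1)
        - math.lgamma(n_hom_a + 1)
        + h * math.log(2.0)
    )


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------


def genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    """(hom-ref, het, hom-alt) counts, ignoring missing."""
    return (
        int(np.sum(dosages == 0)),
        int(np.sum(dosages == 1)),
        int(np.sum(dosages == 2)),
    )


def apply_qc(
    vt: VariantTable,
    panel: PopulationPanel,
    thresholds: QCThresholds | None = None,
    mode: str = "per_population",
) -> tuple[VariantTable, QCReport]:
    """Filter SNPs by HWE, call rate and MAF.

    In ``per_population`` mode (default) a SNP is retained only if it
    passes all three filters in every population; ``pooled`` mode tests
    the combined sample once.
    """
    th = thresholds or QCThresholds()
    if mode not in ("per_population", "pooled"):
        raise GenotypeIOError(f"unknown QC mode {mode!r}")
    groups: list[np.ndarray]
    if mode == "per_population":
        groups = list(panel.sample_indices(vt).values())
    else:
        groups = [np.arange(vt.n_samples)]
    keep = np.ones(vt.n_snps, dtype=bool)
    fail_hwe = np.zeros(vt.n_snps, dtype=bool)
    fail_cr = np.zeros(vt.n_snps, dtype=bool)
    fail_maf = np.zeros(vt.n_snps, dtype=bool)
    for rows in groups:
        g = vt.genotypes[rows, :]
        non_missing = (g != MISSING).sum(axis=0)
        alt = np.where(g == MISSING, 0, g).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            call_rate = non_missing / len(rows)
            freq = np.where(non_missing > 0, alt / (2 * np.maximum(non_missing, 1)), 0.0)
        maf = np.minimum(freq, 1 - freq)
        fail_cr |= call_rate < th.call_rate_min
        fail_maf |= (maf < th.maf_min) | (non_missing == 0)
        for j in range(vt.n_snps):
            if non_missing[j] == 0:
                continue
            counts = genotype_counts(g[:, j])
            if hwe_exact_test(*counts) < th.hwe_p_min:
                fail_hwe[j] = True
    keep = ~(fail_hwe | fail_cr | fail_maf)
    report = QCReport(
        n_input=vt.n_snps,
        n_retained=int(keep.sum()),
        removed_hwe=int(fail_hwe.sum()),
        removed_call_rate=int(fail_cr.sum()),
        removed_maf=int(fail_maf.sum()),
    )
    return vt.take_snps(np.where(keep)[0]), report


# ---------------------------------------------------------------------------
# Gene regions and gene sets
# ---------------------------------------------------------------------------


def read_gene_regions(path_bed: str) -> GeneCatalogue:
    """Read BED3+name gene regions (0-based, half-open)."""
    genes: list[GeneRegion] = []
    with open(path_bed) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise GenotypeIOError(f"{path_bed}:{ln}: need chrom,start,end,name")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise GenotypeIOError(f"{path_bed}:{ln}: non-integer bounds") from exc
            genes.append(GeneRegion(gene_id=parts[3], chrom=parts[0], start=start, end=end))
    return GeneCatalogue(genes=genes)


def assign_snps_to_genes(
    vt: VariantTable, catalogue: GeneCatalogue, min_snps: int = 2
) -> GeneCatalogue:
    """Assign SNP columns to genes; drop genes with < ``min_snps`` SNPs.

    A SNP at 1-based position ``pos`` belongs to a region iff
    ``start <= pos - 1 < end``.
    """
    kept: list[GeneRegion] = []
    dropped = 0
    for gene in catalogue:
        on_chrom = np.where(vt.chrom == gene.chrom)[0]
        pos0 = vt.pos[on_chrom] - 1
        inside = on_chrom[(pos0 >= gene.start) & (pos0 < gene.end)]
        if len(inside) >= min_snps:
            kept.append(replace(gene, snp_indices=np.sort(inside)))
        else:
            dropped += 1
    if dropped:
        logger.info("assign_snps_to_genes: dropped %d genes with <%d SNPs", dropped, min_snps)
    return GeneCatalogue(genes=kept)


def read_gene_sets(
    path_gmt: str,
    catalogue: GeneCatalogue,
    min_genes: int = 10,
    category: str = "custom",
) -> GeneSetCollection:
    """Read GMT gene sets, prune to catalogue genes, drop small sets.

    GMT lines are ``set_id<TAB>description<TAB>gene1<TAB>gene2...``.
    Member genes absent from the catalogue are removed before the
    ``min_genes`` filter; duplicate members are de-duplicated keeping
    first occurrence.
    """
    present = set(catalogue.gene_ids)
    sets: list[GeneSet] = []
    dropped = 0
    with open(path_gmt) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GenotypeIOError(f"{path_gmt}:{ln}: need set id, description, genes")
            seen: list[str] = []
            for g in parts[2:]:
                if g and g in present and g not in seen:
                    seen.append(g)
            if len(seen) >= min_genes:
                sets.append(
                    GeneSet(set_id=parts[0], set_name=parts[1], gene_ids=seen, category=category)
                )
            else:
                dropped += 1
    if dropped:
        logger.info("read_gene_sets: dropped %d sets with <%d catalogue genes", dropped, min_genes)
    return GeneSetCollection(sets=sets)
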