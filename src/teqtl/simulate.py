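"""Synthetic cohort generator with planted cis, trans, and mediated effects.

Emulates the data shapes of a population eQTL study of TE expression:

* Genotypes for a structured cohort via the Balding-Nichols model — each
  population's allele frequency is Beta-distributed around a shared
  ancestral frequency with divergence set by Fst — with block-wise LD
  created by haplotype copying (within an LD block, each variant's allele
  copies the previous variant's with probability ``ld_rho``).
* Structural variants (L1/Alu insertions and deletions) for the net
  copy-number covariate.
* Gene models and TE loci laid out so every genomic stratum (exonic,
  intronic, nearby and distal intergenic) is realized by construction.
* Negative-binomial read counts whose log-means carry planted SNV->gene
  (cis, slope ``a``), gene->TE-subfamily (``b``) and SNV->TE direct
  effects, plus batch/sex/viral covariate loadings; mediated trans effects
  act through the latent (noise-free) gene value so the true indirect
  effect is exactly a*b on the latent scale.
* A trait-category map over the SNV universe for PheWAS-style enrichment.

Everything is reproducible from (config, seed), and ``write_cohort``
round-trips through the package's file formats.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .anno import (
    GeneModel,
    TELocus,
    build_te_family_sets,
    classify_all,
    write_gene_models_gtf,
    write_te_annotation_tsv,
)
from .expr import CountMatrix
from .geno import GenotypeMatrix, SVRecord
from .phewas import TraitMap

logger = logging.getLogger(__name__)

# default 20-subfamily panel: 10 L1 subfamilies spanning the three age
# strata, plus Alu, SVA, and other common repeat families
DEFAULT_SUBFAMILIES = [
    ("L1HS", "L1"), ("L1PA2", "L1"), ("L1PA3", "L1"), ("L1PA4", "L1"),
    ("L1PB1", "L1"), ("L1P1", "L1"), ("L1P2", "L1"),
    ("L1MA1", "L1"), ("L1ME1", "L1"), ("L1MC4", "L1"),
    ("AluY", "Alu"), ("AluSx", "Alu"), ("AluJb", "Alu"),
    ("SVA_D", "SVA"), ("MER41B", "ERV1"), ("L2a", "L2"),
    ("MIRb", "MIR"), ("HERVK-int", "ERVK"),
    ("Charlie1", "hAT-Charlie"), ("Tigger1", "TcMar-Tigger"),
]

DISEASE_CATEGORIES = [
    "cardiovascular", "cell_proliferation", "ear", "endocrine",
    "gastrointestinal", "hematologic", "immune", "integumentary",
    "musculoskeletal", "nervous_system", "pancreas", "respiratory",
    "urinary", "visual_system",
]


@dataclass
class SimConfig:
    """Study-condition knobs for one synthetic cohort."""

    n_samples: int = 200
    n_populations: int = 2
    fst: float = 0.05
    n_chrom: int = 2
    chrom_length: int = 60_000_000
    n_snvs: int = 2000
    ld_block_size: int = 10
    ld_rho: float = 0.7
    n_sv: int = 40
    n_genes: int = 200
    n_te_loci_per_region: int = 100
    subfamilies: list = field(default_factory=lambda: list(DEFAULT_SUBFAMILIES))
    nb_dispersion: float = 0.1
    library_size_log_sd: float = 0.2
    gene_log_mean: float = 5.0  # natural-log baseline expression
    gene_log_sd: float = 0.7
    te_log_mean: float = 3.5
    te_log_sd: float = 0.5
    batch_effect_sd: float = 0.2
    sex_effect_sd: float = 0.1
    viral_effect_sd: float = 0.1
    # planted effects: lists of (snv_id, gene_id, a), (gene_id, subfam, b),
    # (snv_id, subfam, c_direct); filled by plant_default_trios if empty
    planted_cis: list = field(default_factory=list)
    planted_gene_te: list = field(default_factory=list)
    planted_direct: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fst < 1:
            raise ValueError("fst must be in [0, 1)")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")
        for name in ("n_samples", "n_chrom", "n_snvs", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TruthTable:
    """Ground truth for recovery tests: planted trios and loadings."""

    trios: list  # (snv_id, gene_id, te_subfamily, a, b, c_direct)
    ancestral_freq: dict  # snv_id -> ancestral allele frequency
    covariate_loadings: dict  # feature -> {covariate: loading}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "trios": self.trios,
                    "ancestral_freq": self.ancestral_freq,
                    "covariate_loadings": self.covariate_loadings,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            trios=[tuple(t) for t in d["trios"]],
            ancestral_freq=d["ancestral_freq"],
            covariate_loadings=d["covariate_loadings"],
        )


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def _simulate_haplotypes(rng, freqs, n_hap, block_size, rho) -> np.ndarray:
    """Haplotype matrix (n_hap x m) with block-copy LD at the given freqs."""
    m = len(freqs)
    hap = np.empty((n_hap, m), dtype=np.int8)
    fresh = rng.random((n_hap, m)) < freqs[None, :]
    copy = rng.random((n_hap, m)) < rho
    for j in range(m):
        if j % block_size == 0:
            hap[:, j] = fresh[:, j]
        else:
            hap[:, j] = np.where(copy[:, j], hap[:, j - 1], fresh[:, j])
    return hap


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, list[SVRecord], np.ndarray]:
    """Generate the SNV dosage matrix, SV records, and population labels."""
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_snvs
    ancestral = rng.uniform(0.05, 0.5, size=m)
    pop_sizes = np.full(cfg.n_populations, cfg.n_samples // cfg.n_populations)
    pop_sizes[: cfg.n_samples % cfg.n_populations] += 1
    pop_labels = np.repeat(np.arange(cfg.n_populations), pop_sizes)

    # population-specific frequencies (Balding-Nichols)
    if cfg.fst > 0:
        a = ancestral * (1 - cfg.fst) / cfg.fst
        b = (1 - ancestral) * (1 - cfg.fst) / cfg.fst
        pop_freqs = rng.beta(a, b, size=(cfg.n_populations, m))
    else:
        pop_freqs = np.tile(ancestral, (cfg.n_populations, 1))

    # positions: sorted within chromosomes, SNVs split evenly across them
    per_chrom = np.full(cfg.n_chrom, m // cfg.n_chrom)
    per_chrom[: m % cfg.n_chrom] += 1
    chroms, positions = [], []
    for c, count in enumerate(per_chrom):
        pos = np.sort(rng.choice(cfg.chrom_length, size=count, replace=False)) + 1
        chroms.extend([f"chr{c + 1}"] * count)
        positions.extend(pos.tolist())

    dosage = np.empty((cfg.n_samples, m), dtype=np.int8)
    row = 0
    for p, size in enumerate(pop_sizes):
        h1 = _simulate_haplotypes(rng, pop_freqs[p], size, cfg.ld_block_size, cfg.ld_rho)
        h2 = _simulate_haplotypes(rng, pop_freqs[p], size, cfg.ld_block_size, cfg.ld_rho)
        dosage[row : row + size] = h1 + h2
        row += size

    alleles = np.array(["A", "C", "G", "T"])
    refs = alleles[rng.integers(0, 4, size=m)]
    alts = np.array(
        [rng.choice([a for a in alleles if a != r]) for r in refs]
    )
    variants = pd.DataFrame(
        {
            "id": [f"rs{100000 + i}" for i in range(m)],
            "chrom": chroms,
            "pos": positions,
            "ref": refs,
            "alt": alts,
            "maf": np.nan,
            "hwe_p": np.nan,
        }
    )
    g = GenotypeMatrix(
        samples=[f"S{i:04d}" for i in range(cfg.n_samples)],
        variants=variants,
        dosage=dosage,
    )

    sv_classes = ["L1_insertion", "L1_deletion", "Alu_insertion", "Alu_deletion", "other"]
    svs = []
    for i in range(cfg.n_sv):
        freq = rng.uniform(0.05, 0.5)
        svs.append(
            SVRecord(
                id=f"sv{i:03d}",
                sv_class=sv_classes[i % len(sv_classes)],
                dosage=rng.binomial(2, freq, size=cfg.n_samples).astype(np.int8),
            )
        )
    truth_freq = dict(zip(variants["id"], ancestral.tolist()))
    g._ancestral_freq = truth_freq  # stashed for the truth table
    return g, svs, pop_labels


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------


def simulate_annotations(cfg: SimConfig) -> tuple[list[GeneModel], list[TELocus]]:
    """Place non-overlapping genes and TE loci realizing all four strata.

    Each gene occupies a fixed slot on its chromosome with two exons and an
    intron; TE loci are planted inside exons (exonic), inside introns
    (intronic), just downstream of gene ends (nearby intergenic) and at
    slot midpoints far from genes (distal intergenic). Placement is
    verified by round-tripping through the region classifier.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    genes_per_chrom = np.full(cfg.n_chrom, cfg.n_genes // cfg.n_chrom)
    genes_per_chrom[: cfg.n_genes % cfg.n_chrom] += 1
    genes: list[GeneModel] = []
    slots: list[tuple[str, int, GeneModel]] = []
    gi = 0
    for c in range(cfg.n_chrom):
        chrom = f"chr{c + 1}"
        n = int(genes_per_chrom[c])
        slot = cfg.chrom_length // max(n, 1)
        if slot < 60_000:
            raise ValueError("chrom_length too small for requested gene count")
        for k in range(n):
            start = k * slot + 20_000
            gene_len = int(rng.integers(15_000, 30_000))
            end = start + gene_len
            exon1 = (start, start + 2_000)
            exon2 = (end - 2_000, end)
            gene = GeneModel(f"GENE{gi:04d}", chrom, start, end, [exon1, exon2])
            genes.append(gene)
            slots.append((chrom, k * slot, gene))
            gi += 1

    subfams = [s for s, _ in cfg.subfamilies]
    fams = dict(cfg.subfamilies)
    loci: list[TELocus] = []
    li = 0

    def add_locus(chrom, start, end):
        nonlocal li
        sub = subfams[li % len(subfams)]
        loci.append(
            TELocus(f"TE{li:05d}", chrom, start, end, sub, fams[sub], "retro")
        )
        li += 1

    n_per = cfg.n_te_loci_per_region
    for i in range(n_per):  # exonic: inside exon 1
        chrom, _, gene = slots[i % len(slots)]
        s = gene.exons[0][0] + 100
        add_locus(chrom, s, s + 400)
    for i in range(n_per):  # intronic: between the exons
        chrom, _, gene = slots[i % len(slots)]
        s = gene.exons[0][1] + 2_000
        add_locus(chrom, s, s + 400)
    for i in range(n_per):  # nearby intergenic: 1-4 kb past the gene end
        chrom, _, gene = slots[i % len(slots)]
        s = gene.end + 1_000 + (i % 3) * 1_000
        add_locus(chrom, s, s + 400)
    for i in range(n_per):  # distal intergenic: deep in the slot gap
        chrom, slot_start, gene = slots[i % len(slots)]
        s = gene.end + 20_000 + (i % 5) * 2_000
        add_locus(chrom, s, s + 400)

    classify_all(loci, genes)
    expected = (
        ["exonic"] * n_per + ["intronic"] * n_per
        + ["nearby_intergenic"] * n_per + ["distal_intergenic"] * n_per
    )
    mislabeled = [
        (t.locus_id, t.region, want)
        for t, want in zip(loci, expected)
        if t.region != want
    ]
    if mislabeled:
        raise RuntimeError(f"infeasible TE placement: {mislabeled[:3]}")
    return genes, loci


def plant_default_trios(
    cfg: SimConfig, g: GenotypeMatrix, genes: list[GeneModel], n_trios: int = 3,
    a: float = 0.6, b: float = 0.6, c_direct: float = 0.0,
) -> SimConfig:
    """Fill the planted-effect lists with ``n_trios`` mediated trios.

    Each trio pairs a common SNV (MAF >= 0.2) with the nearest gene within
    the cis window and one young-L1 subfamily; effects default to the
    recovery-test sizes a = b = 0.6 on the latent log scale.
    """
    maf = np.minimum(g.dosage.mean(axis=0) / 2, 1 - g.dosage.mean(axis=0) / 2)
    l1_subs = [s for s, f in cfg.subfamilies if f == "L1"]
    snv_chrom = g.variants["chrom"].to_numpy()
    snv_pos = g.variants["pos"].to_numpy()
    snv_id = g.variants["id"].to_numpy()
    # eligible (distance, snv, gene) pairs within the cis window
    pairs = []
    for gene in genes:
        mid = (gene.start + gene.end) // 2
        ok = (snv_chrom == gene.chrom) & (maf >= 0.2)
        dist = np.abs(snv_pos - mid)
        for j in np.flatnonzero(ok & (dist <= 900_000)):
            pairs.append((int(dist[j]), str(snv_id[j]), gene.gene_id))
    pairs.sort()
    planted_cis, planted_b, planted_direct = [], [], []
    used_snvs: set[str] = set()
    used_genes: set[str] = set()
    for k in range(n_trios):
        pick = next(
            (p for p in pairs if p[1] not in used_snvs and p[2] not in used_genes),
            None,
        )
        if pick is None:
            raise RuntimeError("not enough eligible SNV-gene pairs to plant trios")
        _, snv, gene_id = pick
        sub = l1_subs[k % len(l1_subs)]
        planted_cis.append((snv, gene_id, a))
        planted_b.append((gene_id, sub, b))
        if c_direct:
            planted_direct.append((snv, sub, c_direct))
        used_snvs.add(snv)
        used_genes.add(gene_id)
    return dataclasses.replace(
        cfg,
        planted_cis=planted_cis,
        planted_gene_te=planted_b,
        planted_direct=planted_direct,
    )


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


def _nb_draw(rng, mean, dispersion):
    """Negative binomial with mean/dispersion parameterization (gamma-Poisson)."""
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def simulate_covariate_labels(cfg: SimConfig, pop_labels: np.ndarray) -> pd.DataFrame:
    rng = np.random.default_rng(cfg.seed + 2)
    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    return pd.DataFrame(
        {
            "lab": rng.choice(["lab1", "lab2"], size=cfg.n_samples),
            "sex": rng.choice(["female", "male"], size=cfg.n_samples),
            "population": [f"pop{p + 1}" for p in pop_labels],
        },
        index=pd.Index(samples, name="sample"),
    )


def simulate_counts(
    cfg: SimConfig,
    g: GenotypeMatrix,
    genes: list[GeneModel],
    loci: list[TELocus],
    covariates: pd.DataFrame,
) -> tuple[CountMatrix, TruthTable]:
    """NB counts for genes, TE loci, and the viral feature, plus ground truth.

    Latent natural-log means carry planted effects and covariate loadings;
    gene->TE effects propagate through the latent (noise-free) gene value,
    centered, so the true indirect effect of a mediated trio is a*b.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    n = cfg.n_samples
    gene_ids = [gn.gene_id for gn in genes]
    locus_ids = [t.locus_id for t in loci]
    sub_of = {t.locus_id: t.subfamily for t in loci}

    for snv, gene, _ in cfg.planted_cis:
        if gene not in gene_ids:
            raise KeyError(f"planted cis effect references absent gene {gene}")
        g.variant_index(snv)  # raises on absent SNV
    subfam_names = {s for s, _ in cfg.subfamilies}
    for gene, sub, _ in cfg.planted_gene_te:
        if gene not in gene_ids or sub not in subfam_names:
            raise KeyError(f"planted gene->TE effect references absent {gene}/{sub}")
    for snv, sub, _ in cfg.planted_direct:
        g.variant_index(snv)
        if sub not in subfam_names:
            raise KeyError(f"planted direct effect references absent subfamily {sub}")

    lab_x = (covariates["lab"] == "lab2").to_numpy(dtype=float)
    sex_x = (covariates["sex"] == "male").to_numpy(dtype=float)
    viral_latent = rng.normal(0.0, 1.0, size=n)  # standardized viral load

    loadings: dict[str, dict] = {}
    a_by_gene: dict[str, list] = {}
    for snv, gene, a in cfg.planted_cis:
        a_by_gene.setdefault(gene, []).append((snv, a))

    gene_latent = np.empty((len(gene_ids), n))
    for i, gid in enumerate(gene_ids):
        base = rng.normal(cfg.gene_log_mean, cfg.gene_log_sd)
        lab_beta = rng.normal(0, cfg.batch_effect_sd)
        sex_beta = rng.normal(0, cfg.sex_effect_sd)
        lat = base + lab_beta * lab_x + sex_beta * sex_x
        for snv, a in a_by_gene.get(gid, []):
            dose = g.dosage_of(snv).astype(float)
            lat = lat + a * (dose - dose.mean())
        gene_latent[i] = lat
        loadings[gid] = {"lab": lab_beta, "sex": sex_beta}

    b_by_sub: dict[str, list] = {}
    for gene, sub, b in cfg.planted_gene_te:
        b_by_sub.setdefault(sub, []).append((gene, b))
    c_by_sub: dict[str, list] = {}
    for snv, sub, cdir in cfg.planted_direct:
        c_by_sub.setdefault(sub, []).append((snv, cdir))
    gene_index = {gid: i for i, gid in enumerate(gene_ids)}

    locus_latent = np.empty((len(locus_ids), n))
    for i, lid in enumerate(locus_ids):
        sub = sub_of[lid]
        base = rng.normal(cfg.te_log_mean, cfg.te_log_sd)
        lab_beta = rng.normal(0, cfg.batch_effect_sd)
        viral_beta = rng.normal(0, cfg.viral_effect_sd)
        lat = base + lab_beta * lab_x + viral_beta * viral_latent
        for gene, b in b_by_sub.get(sub, []):
            gl = gene_latent[gene_index[gene]]
            lat = lat + b * (gl - gl.mean())
        for snv, cdir in c_by_sub.get(sub, []):
            dose = g.dosage_of(snv).astype(float)
            lat = lat + cdir * (dose - dose.mean())
        locus_latent[i] = lat
        loadings[lid] = {"lab": lab_beta, "viral": viral_beta}

    viral_row = cfg.gene_log_mean + 0.8 * viral_latent

    lib_factor = np.exp(rng.normal(0.0, cfg.library_size_log_sd, size=n))
    latent = np.vstack([gene_latent, locus_latent, viral_row[None, :]])
    mean = np.exp(latent) * lib_factor[None, :]
    counts = _nb_draw(rng, mean, cfg.nb_dispersion)

    features = gene_ids + locus_ids + ["EBV"]
    kinds = pd.Series(
        ["gene"] * len(gene_ids) + ["te_locus"] * len(locus_ids) + ["viral"],
        index=features,
    )
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(features, name="feature"),
                            columns=g.samples),
        kinds=kinds,
    )

    a_of = {(snv, gene): a for snv, gene, a in cfg.planted_cis}
    trios = []
    for gene, sub, b in cfg.planted_gene_te:
        for (snv, gn), a in a_of.items():
            if gn == gene:
                cdir = dict(
                    ((s, sb), cv) for s, sb, cv in cfg.planted_direct
                ).get((snv, sub), 0.0)
                trios.append((snv, gene, sub, a, b, cdir))
    truth = TruthTable(
        trios=trios,
        ancestral_freq=getattr(g, "_ancestral_freq", {}),
        covariate_loadings=loadings,
    )
    return cm, truth


def simulate_trait_map(
    cfg: SimConfig,
    snv_ids: list,
    enriched_snvs=None,
    enriched_categories=("immune", "cell_proliferation"),
    base_rate: float = 0.05,
    enriched_rate: float = 0.35,
) -> TraitMap:
    """Random SNV -> disease-category map, optionally enriching a hit set.

    Every SNV maps to each of the 14 categories independently at
    ``base_rate``; SNVs in ``enriched_snvs`` map to the enriched categories
    at ``enriched_rate`` instead.
    """
    rng = np.random.default_rng(cfg.seed + 4)
    enriched_snvs = set(enriched_snvs or ())
    mapping: dict[str, set] = {}
    for snv in snv_ids:
        cats = set()
        for cat in DISEASE_CATEGORIES:
            rate = (
                enriched_rate
                if snv in enriched_snvs and cat in enriched_categories
                else base_rate
            )
            if rng.random() < rate:
                cats.add(cat)
        if cats:
            mapping[snv] = cats
    return TraitMap(mapping=mapping, universe=set(snv_ids))


# ---------------------------------------------------------------------------
# Cohort assembly and on-disk round trip
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    cfg: SimConfig
    genotypes: GenotypeMatrix
    svs: list
    genes: list
    te_loci: list
    counts: CountMatrix
    covariate_labels: pd.DataFrame
    truth: TruthTable
    trait_map: TraitMap


def simulate_cohort(cfg: SimConfig, plant_defaults: bool = True) -> Cohort:
    """Full cohort generation in one call; see the module docstring."""
    g, svs, pop_labels = simulate_genotypes(cfg)
    genes, loci = simulate_annotations(cfg)
    if plant_defaults and not cfg.planted_cis and not cfg.planted_gene_te:
        cfg = plant_default_trios(cfg, g, genes)
    covariates = simulate_covariate_labels(cfg, pop_labels)
    counts, truth = simulate_counts(cfg, g, genes, loci, covariates)
    trait_map = simulate_trait_map(cfg, list(g.variants["id"]))
    return Cohort(
        cfg=cfg, genotypes=g, svs=svs, genes=genes, te_loci=loci,
        counts=counts, covariate_labels=covariates, truth=truth,
        trait_map=trait_map,
    )


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Minimal but standard-conforming VCF (GT format) for the cohort."""
    chrom_order = list(dict.fromkeys(g.variants["chrom"]))
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=teqtl-simulate\n")
        for chrom in chrom_order:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples) + "\n"
        )
        for j, row in g.variants.iterrows():
            gts = "\t".join(gt_code[int(x)] for x in g.dosage[:, j])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_sv_tsv(svs: list, samples: list, path) -> None:
    df = pd.DataFrame(
        [[sv.id, sv.sv_class, *sv.dosage.tolist()] for sv in svs],
        columns=["id", "sv_class", *samples],
    )
    df.to_csv(path, sep="\t", index=False)


def write_cohort(cohort: Cohort, out_dir) -> dict:
    """Write every cohort component; returns the path map.

    Formats: VCF + dosage/variant TSVs (genotypes), SV TSV, counts TSV,
    gene GTF, TE annotation TSV, covariate TSV, family-set GMT, trait-map
    TSV, truth JSON. Re-reading these reproduces the in-memory objects.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "dosage": out / "dosage.tsv",
        "variant_meta": out / "variants.tsv",
        "sv": out / "svs.tsv",
        "counts": out / "counts.tsv",
        "gtf": out / "genes.gtf",
        "te_annotation": out / "te_loci.tsv",
        "covariates": out / "covariates.tsv",
        "family_gmt": out / "te_families.gmt",
        "trait_map": out / "trait_map.tsv",
        "truth": out / "truth.json",
    }
    write_vcf(cohort.genotypes, paths["vcf"])
    cohort.genotypes.to_dosage_tsv(paths["dosage"])
    cohort.genotypes.to_variant_tsv(paths["variant_meta"])
    write_sv_tsv(cohort.svs, cohort.genotypes.samples, paths["sv"])
    cohort.counts.to_tsv(paths["counts"])
    write_gene_models_gtf(cohort.genes, paths["gtf"])
    write_te_annotation_tsv(cohort.te_loci, paths["te_annotation"])
    cohort.covariate_labels.to_csv(paths["covariates"], sep="\t")
    build_te_family_sets(cohort.te_loci).write_gmt(paths["family_gmt"])
    cohort.trait_map.write_tsv(paths["trait_map"])
    cohort.truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
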