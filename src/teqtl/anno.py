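"""Gene and TE annotation: region stratification, aggregation, gene sets.

TE loci are classified against gene models into four genomic strata —
exonic, intronic, nearby intergenic (within 5 kb of a gene) and distal
intergenic (> 5 kb from any gene) — with precedence exonic > intronic >
nearby > distal, so a locus touching an exon anywhere is exonic. Locus
counts aggregate to the subfamily level, optionally per stratum; subfamily
IDs roll up into family gene sets and L1 subfamilies into evolutionary-age
strata (L1M old, L1P intermediate, L1PA/L1HS young).

Intervals are 1-based inclusive (GTF convention) throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .expr import CountMatrix

logger = logging.getLogger(__name__)

REGIONS = ("exonic", "intronic", "nearby_intergenic", "distal_intergenic")


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    exons: list = field(default_factory=list)  # list of (start, end)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        for s, e in self.exons:
            if not (self.start <= s <= e <= self.end):
                raise ValueError(f"gene {self.gene_id}: exon outside gene span")


@dataclass
class TELocus:
    locus_id: str
    chrom: str
    start: int
    end: int
    subfamily: str
    family: str
    te_class: str = "Unknown"
    region: str = "unassigned"


@dataclass
class GeneSetCollection:
    """Named feature-ID sets with a collection-level kind label."""

    sets: dict  # name -> set of feature IDs
    kind: str  # te_family | l1_age | region_stratified | pathway

    def __post_init__(self) -> None:
        empty = [k for k, v in self.sets.items() if not v]
        if empty:
            raise ValueError(f"empty gene sets: {empty}")

    def write_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name, members in self.sets.items():
                fh.write("\t".join([name, self.kind, *sorted(members)]) + "\n")

    @classmethod
    def read_gmt(cls, path, kind: str = "pathway") -> "GeneSetCollection":
        sets = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                sets[parts[0]] = set(parts[2:])
        return cls(sets=sets, kind=kind)


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------


def read_gene_models_gtf(path) -> list[GeneModel]:
    """Load gene and exon features from a GTF into GeneModel objects."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes = {}
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("gene_id", [feat.id])[0]
        genes[gid] = GeneModel(gid, feat.seqid, feat.start, feat.end, [])
    for feat in db.features_of_type("exon"):
        gid = feat.attributes.get("gene_id", [None])[0]
        if gid in genes:
            genes[gid].exons.append((feat.start, feat.end))
    return list(genes.values())


def read_te_annotation_tsv(path) -> list[TELocus]:
    """TE loci from a TSV with locus_id, chrom, start, end, subfamily, family[, te_class]."""
    df = pd.read_csv(path, sep="\t")
    return [
        TELocus(
            str(r.locus_id), str(r.chrom), int(r.start), int(r.end),
            str(r.subfamily), str(r.family),
            str(getattr(r, "te_class", "Unknown")),
        )
        for r in df.itertuples(index=False)
    ]


def write_te_annotation_tsv(loci: list[TELocus], path) -> None:
    pd.DataFrame(
        [
            (t.locus_id, t.chrom, t.start, t.end, t.subfamily, t.family, t.te_class)
            for t in loci
        ],
        columns=["locus_id", "chrom", "start", "end", "subfamily", "family", "te_class"],
    ).to_csv(path, sep="\t", index=False)


def write_gene_models_gtf(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\tteqtl\tgene\t{g.start}\t{g.end}\t.\t+\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                fh.write(f"{g.chrom}\tteqtl\texon\t{s}\t{e}\t.\t+\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# Region classification
# ---------------------------------------------------------------------------


def _overlaps(a_start, a_end, b_start, b_end) -> bool:
    return a_start <= b_end and b_start <= a_end


def classify_te_locus_region(
    te: TELocus, genes: list[GeneModel], near_bp: int = 5000
) -> str:
    """Assign one of the four genomic strata to a TE locus.

    Exonic if the locus overlaps >= 1 bp of any exon; else intronic if it
    overlaps any gene body; else nearby_intergenic if its nearest gene
    boundary is within ``near_bp``; else distal_intergenic. Distance is
    measured edge-to-edge, strand-ignored.
    """
    same_chrom = [g for g in genes if g.chrom == te.chrom]
    in_gene = False
    min_dist = np.inf
    for g in same_chrom:
        for s, e in g.exons:
            if _overlaps(te.start, te.end, s, e):
                return "exonic"
        if _overlaps(te.start, te.end, g.start, g.end):
            in_gene = True
        else:
            dist = g.start - te.end if g.start > te.end else te.start - g.end
            min_dist = min(min_dist, dist)
    if in_gene:
        return "intronic"
    if min_dist <= near_bp:
        return "nearby_intergenic"
    return "distal_intergenic"


def classify_all(
    loci: list[TELocus], genes: list[GeneModel], near_bp: int = 5000
) -> list[TELocus]:
    """Classify every locus in place (returns the same list for chaining)."""
    for te in loci:
        te.region = classify_te_locus_region(te, genes, near_bp)
    return loci


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def aggregate_te_counts(
    loci_counts: CountMatrix, annotation: list[TELocus], by_region: bool = False
) -> CountMatrix:
    """Sum TE locus counts to subfamily (or subfamily-per-stratum) features.

    With ``by_region`` the output features are ``subfamily:region`` pairs
    whose per-sample totals partition the unstratified subfamily totals.
    """
    ann = {t.locus_id: t for t in annotation}
    missing = [f for f in loci_counts.features if f not in ann]
    if missing:
        raise KeyError(f"loci without annotation: {missing[:5]}")
    if by_region:
        keys = [f"{ann[f].subfamily}:{ann[f].region}" for f in loci_counts.features]
    else:
        keys = [ann[f].subfamily for f in loci_counts.features]
    agg = loci_counts.counts.groupby(pd.Index(keys, name="feature"), sort=True).sum()
    kinds = pd.Series("te_subfamily", index=agg.index)
    return CountMatrix(counts=agg, kinds=kinds, library_size=loci_counts.library_size)


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------


def build_te_family_sets(annotation: list[TELocus]) -> GeneSetCollection:
    """One gene set per TE family, containing its subfamily IDs."""
    sets: dict[str, set] = {}
    for t in annotation:
        sets.setdefault(t.family, set()).add(t.subfamily)
    return GeneSetCollection(sets=sets, kind="te_family")


L1_AGE_LABELS = ("L1M_old", "L1P_intermediate", "L1PA_young")


def classify_l1_age(subfamily: str) -> str:
    """Age stratum for one L1 subfamily name.

    L1PA* and L1HS are the youngest primate-specific lineage, L1M* the
    oldest mammalian-wide subfamilies, remaining L1P* intermediate. L1HS
    lands in the young bucket by definition despite its prefix.
    """
    if not subfamily.startswith("L1"):
        raise ValueError(f"not an L1 subfamily: {subfamily!r}")
    if subfamily.startswith("L1PA") or subfamily == "L1HS":
        return "L1PA_young"
    if subfamily.startswith("L1M"):
        return "L1M_old"
    if subfamily.startswith("L1P"):
        return "L1P_intermediate"
    return "unclassified"


def build_l1_age_sets(l1_subfamilies: list[str]) -> GeneSetCollection:
    """Partition L1 subfamily names into evolutionary-age gene sets."""
    sets: dict[str, set] = {}
    for name in l1_subfamilies:
        bucket = classify_l1_age(name)
        if bucket == "unclassified":
            logger.warning("L1 subfamily %s matches no age rule", name)
        sets.setdefault(bucket, set()).add(name)
    return GeneSetCollection(sets=sets, kind="l1_age")


# ---------------------------------------------------------------------------
# L1 density near SNVs
# ---------------------------------------------------------------------------


def l1_density_near_snvs(
    snv_positions: pd.DataFrame, annotation: list[TELocus], flank_bp: int = 5000
) -> np.ndarray:
    """Count L1 loci overlapping +/- ``flank_bp`` around each SNV.

    ``snv_positions`` needs columns ``chrom`` and ``pos``; only annotation
    entries with family == "L1" are counted. The window is two-sided and an
    overlap of any part of the locus counts.
    """
    l1 = [t for t in annotation if t.family == "L1"]
    by_chrom: dict[str, list[TELocus]] = {}
    for t in l1:
        by_chrom.setdefault(t.chrom, []).append(t)
    counts = np.zeros(len(snv_positions), dtype=int)
    for i, (chrom, pos) in enumerate(
        zip(snv_positions["chrom"].to_numpy(), snv_positions["pos"].to_numpy())
    ):
        lo, hi = pos - flank_bp, pos + flank_bp
        counts[i] = sum(
            1 for t in by_chrom.get(chrom, []) if _overlaps(lo, hi, t.start, t.end)
        )
    return counts


def compare_l1_density(
    index_counts: np.ndarray, background_counts: np.ndarray
) -> float:
    """Two-sided rank-sum p for index vs background L1-density counts."""
    if len(background_counts) == 0:
        raise ValueError("empty background set")
    return float(
        mannwhitneyu(index_counts, background_counts, alternative="two-sided").pvalue
    )
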