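"""Genotype ingestion, QC, and linkage-disequilibrium utilities.

Handles sample x variant additive dosage matrices (counts of the ALT
allele, values in {0, 1, 2}), per-variant QC on minor-allele frequency and
Hardy-Weinberg equilibrium, LD pruning and clumping, genotype principal
components for population structure, and a net L1/Alu copy-number score
derived from structural-variant dosages.

Coordinates are 1-based inclusive (VCF convention) throughout. Missing
genotypes are rejected at load unless mean-imputation is explicitly
requested; downstream analyses assume complete dosage matrices.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt", "maf", "hwe_p"]

SV_CLASSES = frozenset(
    {"L1_insertion", "L1_deletion", "Alu_insertion", "Alu_deletion", "other"}
)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Complete sample x variant dosage matrix with per-variant metadata.

    Attributes
    ----------
    samples : list of str
        Ordered sample identifiers (rows of ``dosage``).
    variants : pandas.DataFrame
        One row per variant with columns ``id, chrom, pos, ref, alt`` and,
        after QC annotation, ``maf`` and ``hwe_p``. Row order matches the
        columns of ``dosage``.
    dosage : numpy.ndarray
        ``(n_samples, n_variants)`` array of ALT-allele counts in {0,1,2}.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, variant_id: str) -> int:
        idx = np.flatnonzero(self.variants["id"].to_numpy() == variant_id)
        if idx.size == 0:
            raise KeyError(f"unknown variant {variant_id!r}")
        return int(idx[0])

    def dosage_of(self, variant_id: str) -> np.ndarray:
        return self.dosage[:, self.variant_index(variant_id)]

    def subset_variants(self, mask_or_indices) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[:, idx],
        )

    def to_dosage_tsv(self, path) -> None:
        """Write sample x variant dosages (first column = sample ID)."""
        df = pd.DataFrame(
            self.dosage, index=pd.Index(self.samples, name="sample"),
            columns=self.variants["id"].to_numpy(),
        )
        df.to_csv(path, sep="\t")

    def to_variant_tsv(self, path) -> None:
        self.variants.to_csv(path, sep="\t", index=False)


@dataclass
class SVRecord:
    """One structural variant with per-sample dosages.

    ``sv_class`` labels L1/Alu insertions and deletions used for the net
    copy-number covariate; anything else is ``other`` and ignored there.
    """

    id: str
    sv_class: str
    dosage: np.ndarray

    def __post_init__(self) -> None:
        if self.sv_class not in SV_CLASSES:
            raise ValueError(
                f"sv_class {self.sv_class!r} not in {sorted(SV_CLASSES)}"
            )
        self.dosage = np.asarray(self.dosage)


@dataclass
class ClumpAssignment:
    """An LD clump: the index SNV, its members (index included), and index p."""

    index_snv: str
    members: list[str]
    index_p: float


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_vcf(path, impute_missing: bool = False) -> GenotypeMatrix:
    """Load biallelic SNVs with GT format from a VCF into a GenotypeMatrix.

    Multi-allelic records are skipped with a warning. Missing genotypes are
    an error unless ``impute_missing`` replaces them with the variant mean
    rounded to the nearest dosage.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows = []
    columns = []
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning("skipping non-biallelic variant %s", var.ID or var.POS)
            continue
        gts = np.asarray(var.gt_types, dtype=float)  # 0/1/2, 3 = missing
        missing = gts == 3
        if missing.any():
            if not impute_missing:
                raise ValueError(
                    f"variant {var.ID or var.POS} has missing genotypes; "
                    "rerun with impute_missing=True or filter upstream"
                )
            gts[missing] = np.round(gts[~missing].mean())
        vid = var.ID if var.ID is not None else f"{var.CHROM}:{var.POS}"
        rows.append((vid, var.CHROM, var.POS, var.REF, var.ALT[0]))
        columns.append(gts.astype(np.int8))
    variants = pd.DataFrame(rows, columns=["id", "chrom", "pos", "ref", "alt"])
    variants["maf"] = np.nan
    variants["hwe_p"] = np.nan
    dosage = (
        np.column_stack(columns)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)


def read_dosage_tsv(dosage_path, variant_meta_path, impute_missing: bool = False) -> GenotypeMatrix:
    """Load a sample x variant 0/1/2 TSV plus its variant-metadata sidecar."""
    df = pd.read_csv(dosage_path, sep="\t", index_col=0)
    if df.isna().any().any():
        if not impute_missing:
            raise ValueError("dosage TSV contains missing entries")
        df = df.apply(lambda col: col.fillna(np.round(col.mean())))
    meta = pd.read_csv(variant_meta_path, sep="\t")
    meta = meta.set_index("id").loc[list(df.columns)].reset_index()
    for col in ("maf", "hwe_p"):
        if col not in meta.columns:
            meta[col] = np.nan
    return GenotypeMatrix(
        samples=list(df.index.astype(str)),
        variants=meta[[c for c in VARIANT_COLUMNS if c in meta.columns]],
        dosage=df.to_numpy(dtype=np.int8),
    )


def read_sv_tsv(path) -> list[SVRecord]:
    """Load SV records: columns id, sv_class, then per-sample dosages."""
    df = pd.read_csv(path, sep="\t")
    sample_cols = [c for c in df.columns if c not in ("id", "sv_class")]
    return [
        SVRecord(row["id"], row["sv_class"], row[sample_cols].to_numpy(dtype=np.int8))
        for _, row in df.iterrows()
    ]


def write_clumps_tsv(clumps: list[ClumpAssignment], p_by_variant: dict, path) -> None:
    rows = [
        (c.index_snv, member, p_by_variant[member])
        for c in clumps
        for member in c.members
    ]
    pd.DataFrame(rows, columns=["index_snv", "member", "member_p"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg equilibrium p-value.

    Conditional on the observed allele counts, sums the probabilities of
    every heterozygote configuration whose conditional probability does not
    exceed that of the observed configuration (Wigginton-style exact test).

    Parameters are genotype counts; returns a p-value in (0, 1].
    """
    for c in (n_hom_ref, n_het, n_hom_alt):
        if c < 0:
            raise ValueError("genotype counts must be nonnegative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("empty genotype vector")
    n_alt = 2 * n_hom_alt + n_het
    n_ref = 2 * n_hom_ref + n_het
    rare = min(n_alt, n_ref)
    if rare == 0:
        return 1.0
    # All het counts with the same parity as the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    # log P(het = h | allele counts) up to a shared constant:
    # P ∝ n! / (hom_r! het! hom_c!) * 2^het   (conditional hypergeometric)
    logp = (
        hets * np.log(2.0)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    observed = probs[hets == n_het][0]
    # sum configurations no more likely than observed (small tolerance for
    # floating-point ties with the observed probability)
    return float(min(1.0, probs[probs <= observed * (1 + 1e-12)].sum()))


def _maf_from_dosage(column: np.ndarray) -> float:
    freq = column.mean() / 2.0
    return float(min(freq, 1.0 - freq))


def annotate_qc(g: GenotypeMatrix) -> GenotypeMatrix:
    """Annotate per-variant MAF and HWE exact p on a copy of ``g``."""
    variants = g.variants.copy()
    mafs = np.empty(g.n_variants)
    hwes = np.empty(g.n_variants)
    for j in range(g.n_variants):
        col = g.dosage[:, j]
        mafs[j] = _maf_from_dosage(col)
        n_hom_ref = int((col == 0).sum())
        n_het = int((col == 1).sum())
        n_hom_alt = int((col == 2).sum())
        hwes[j] = hwe_exact_test(n_hom_ref, n_het, n_hom_alt)
    variants["maf"] = mafs
    variants["hwe_p"] = hwes
    return GenotypeMatrix(samples=list(g.samples), variants=variants, dosage=g.dosage)


def qc_filter_variants(
    g: GenotypeMatrix, maf_min: float = 0.01, hwe_p_min: float = 1e-6
) -> GenotypeMatrix:
    """Retain biallelic variants with MAF >= maf_min and HWE p >= hwe_p_min.

    Survivors carry their computed ``maf`` and ``hwe_p`` annotations.
    Removing every variant is a warning, not an error.
    """
    annotated = annotate_qc(g)
    keep = (annotated.variants["maf"].to_numpy() >= maf_min) & (
        annotated.variants["hwe_p"].to_numpy() >= hwe_p_min
    )
    if not keep.any():
        warnings.warn("QC removed all variants", stacklevel=2)
    return annotated.subset_variants(keep)


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------


def ld_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation between two dosage vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("dosage vectors must share length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _pairwise_r2(dosage: np.ndarray) -> np.ndarray:
    """r^2 matrix over dosage columns; constant columns yield 0 off-diagonal."""
    x = dosage.astype(float)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    x = x / sd_safe
    r = (x.T @ x) / x.shape[0]
    r[sd == 0, :] = 0.0
    r[:, sd == 0] = 0.0
    return r * r


def prune_ld(
    g: GenotypeMatrix,
    window: int = 50,
    step: int = 10,
    r2_max: float = 0.1,
) -> GenotypeMatrix:
    """Sliding-window greedy LD pruning of a position-sorted panel.

    Within each window of ``window`` variants, while any retained pair has
    r^2 > ``r2_max``, the pair member with the lower MAF is removed (ties go
    to the later position); the window then advances by ``step`` variants.
    Deterministic for a fixed input.
    """
    pos = g.variants[["chrom", "pos"]]
    order_ok = (
        pos.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
        == np.arange(len(pos))
    ).all()
    if not order_ok:
        raise ValueError("variants must be sorted by (chrom, pos) before pruning")

    annotated = g if not g.variants["maf"].isna().any() else annotate_qc(g)
    maf = annotated.variants["maf"].to_numpy()
    chrom = annotated.variants["chrom"].to_numpy()
    m = annotated.n_variants
    alive = np.ones(m, dtype=bool)

    start = 0
    while start < m:
        idx = np.arange(start, min(start + window, m))
        idx = idx[alive[idx]]
        # restrict pairs to the same chromosome
        changed = True
        while changed:
            changed = False
            live = idx[alive[idx]]
            if live.size >= 2:
                r2 = _pairwise_r2(annotated.dosage[:, live])
                for ai in range(live.size):
                    hit = False
                    for bi in range(ai + 1, live.size):
                        i, j = live[ai], live[bi]
                        if chrom[i] != chrom[j]:
                            continue
                        if r2[ai, bi] > r2_max:
                            # remove lower-MAF member; tie -> later position
                            victim = i if maf[i] < maf[j] else j
                            if maf[i] == maf[j]:
                                victim = j
                            alive[victim] = False
                            changed = True
                            hit = True
                            break
                    if hit:
                        break
        start += step
    return annotated.subset_variants(alive)


def clump_by_pvalue(
    p: dict,
    g: GenotypeMatrix,
    window_bp: int = 500_000,
    r2_min: float = 0.1,
) -> list[ClumpAssignment]:
    """Greedy p-value clumping: each clump is led by its most significant SNV.

    Repeatedly takes the unassigned variant with the smallest p as an index
    and absorbs every unassigned variant on the same chromosome within
    ``window_bp`` of it with r^2 > ``r2_min``. Ties in p break by
    (chrom, pos). Returns one ClumpAssignment per index SNV; together the
    clumps partition the variants in ``p``.
    """
    ids = list(p.keys())
    missing = [v for v in ids if (g.variants["id"] == v).sum() == 0]
    if missing:
        raise KeyError(f"variants not in genotype matrix: {missing}")
    meta = g.variants.set_index("id")
    info = pd.DataFrame(
        {
            "p": [p[v] for v in ids],
            "chrom": meta.loc[ids, "chrom"].to_numpy(),
            "pos": meta.loc[ids, "pos"].to_numpy(),
        },
        index=ids,
    ).sort_values(["p", "chrom", "pos"], kind="stable")

    unassigned = dict.fromkeys(info.index)  # insertion-ordered set
    dos = {v: g.dosage_of(v).astype(float) for v in ids}
    clumps: list[ClumpAssignment] = []
    while unassigned:
        index_snv = next(iter(unassigned))
        del unassigned[index_snv]
        ichrom = info.at[index_snv, "chrom"]
        ipos = info.at[index_snv, "pos"]
        members = [index_snv]
        for v in list(unassigned):
            if info.at[v, "chrom"] != ichrom:
                continue
            if abs(int(info.at[v, "pos"]) - int(ipos)) > window_bp:
                continue
            a, b = dos[index_snv], dos[v]
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue
            if ld_r2(a, b) > r2_min:
                members.append(v)
                del unassigned[v]
        clumps.append(
            ClumpAssignment(
                index_snv=index_snv,
                members=members,
                index_p=float(info.at[index_snv, "p"]),
            )
        )
    return clumps


# ---------------------------------------------------------------------------
# Genotype PCA
# ---------------------------------------------------------------------------


def genotype_pca(g: GenotypeMatrix, n_pcs: int) -> pd.DataFrame:
    """Principal components of the column-standardized dosage matrix.

    Zero-variance variants are dropped (with a logged warning) before
    standardization. Components are ordered by explained variance and each
    is oriented so its largest-magnitude variant loading is positive.
    Returns a sample x PC score table with columns PC1..PCk.
    """
    if g.n_samples < 2 or g.n_variants < 2:
        raise ValueError("PCA needs >= 2 samples and >= 2 variants")
    x = g.dosage.astype(float)
    sd = x.std(axis=0)
    if (sd == 0).any():
        logger.warning("dropping %d zero-variance variants before PCA", (sd == 0).sum())
    x = x[:, sd > 0]
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    if n_pcs > min(x.shape):
        raise ValueError(
            f"n_pcs={n_pcs} exceeds min(samples, variants)={min(x.shape)}"
        )
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :n_pcs] * s[:n_pcs]
    # orient: largest-|loading| variant positive
    for k in range(n_pcs):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            scores[:, k] *= -1
    return pd.DataFrame(
        scores,
        index=pd.Index(g.samples, name="sample"),
        columns=[f"PC{k + 1}" for k in range(n_pcs)],
    )


# ---------------------------------------------------------------------------
# Structural-variant copy-number covariate
# ---------------------------------------------------------------------------


def net_te_copy_number(svs: list[SVRecord]) -> np.ndarray:
    """Net L1/Alu copy-number score per sample.

    Sum of dosages over L1 and Alu insertions minus the sum over L1 and Alu
    deletions; SVs of class ``other`` do not contribute.
    """
    if not svs:
        raise ValueError("no SV records supplied")
    n = len(svs[0].dosage)
    score = np.zeros(n, dtype=int)
    for sv in svs:
        if len(sv.dosage) != n:
            raise ValueError(f"SV {sv.id} has a different sample universe")
        if sv.sv_class in ("L1_insertion", "Alu_insertion"):
            score += sv.dosage
        elif sv.sv_class in ("L1_deletion", "Alu_deletion"):
            score -= sv.dosage
    return score
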