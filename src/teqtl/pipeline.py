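"""End-to-end orchestration of the TE-regulator scan.

Stages: genotype QC -> LD pruning and genotype PCA -> expression
preparation (TE locus aggregation, low-expression filter, VST,
covariate residualization, INT) -> cis and trans eQTL scans with BH and
permutation-averaged empirical FDR -> three-part trio integration ->
clumping and tier assignment -> mediation -> genotype-stratified DGE and
TE-family GSEA -> optional trait-category enrichment. Each stage's counts
land in the run report; all randomness flows from one seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import anno, assoc, enrich, expr, geno, mediate, phewas, trio
from .simulate import Cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every numeric knob of the scan, defaulting to the standard values."""

    alpha: float = 0.05
    maf_min: float = 0.01
    hwe_p_min: float = 1e-6
    cpm_reads: float = 10.0  # reads in the median library defining cpm_min
    cpm_min_fraction: float = 0.9
    cis_window_bp: int = 1_000_000
    clump_window_bp: int = 500_000
    clump_r2: float = 0.1
    prune_window: int = 50
    prune_step: int = 10
    prune_r2: float = 0.1
    flank_bp: int = 5_000
    n_genotype_pcs: int = 2
    n_sv_pcs: int = 3
    n_hidden_factors: int = 0
    n_perm_scan: int = 20
    n_perm_mediation: int = 10_000
    phewas_n_combos: int = 500
    run_dge_gsea: bool = True
    run_phewas: bool = True
    gsea_n_perm: int = 500
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: PipelineConfig
    genotypes: geno.GenotypeMatrix
    expression: expr.ExpressionMatrix  # inverse-normal, genes + TE subfamilies
    covariates: pd.DataFrame
    cis: pd.DataFrame
    trans: pd.DataFrame
    trans_threshold: assoc.ThresholdSpec
    trios: pd.DataFrame
    orphans: pd.DataFrame
    clumps: list
    mediation: pd.DataFrame
    dge: pd.DataFrame | None
    gsea: pd.DataFrame | None
    phewas: pd.DataFrame | None
    report: dict


def prepare_genotypes(cohort: Cohort, cfg: PipelineConfig):
    g_qc = geno.qc_filter_variants(
        cohort.genotypes, maf_min=cfg.maf_min, hwe_p_min=cfg.hwe_p_min
    )
    pruned = geno.prune_ld(
        g_qc, window=cfg.prune_window, step=cfg.prune_step, r2_max=cfg.prune_r2
    )
    pcs = geno.genotype_pca(pruned, cfg.n_genotype_pcs)
    net_cn = geno.net_te_copy_number(cohort.svs)
    return g_qc, pruned, pcs, net_cn


def prepare_expression(cohort: Cohort, cfg: PipelineConfig, pcs: pd.DataFrame, net_cn):
    """Aggregate, filter, transform, residualize, INT; returns the INT matrix."""
    counts = cohort.counts
    te_locus = counts.of_kind("te_locus")
    subfam = anno.aggregate_te_counts(te_locus, cohort.te_loci)
    gene_counts = counts.of_kind("gene")
    viral_counts = counts.of_kind("viral")
    combined = expr.CountMatrix(
        counts=pd.concat(
            [gene_counts.counts, subfam.counts, viral_counts.counts]
        ),
        kinds=pd.concat([gene_counts.kinds, subfam.kinds, viral_counts.kinds]),
        library_size=counts.library_size,
    )
    cpm_min = expr.cpm_for_reads(cfg.cpm_reads, combined.library_size)
    filtered = expr.filter_low_expression(
        combined, cpm_min, min_fraction=cfg.cpm_min_fraction
    )
    transformed = expr.vst_transform(filtered)

    viral_ids = [f for f in filtered.features if filtered.kinds[f] == "viral"]
    cov = cohort.covariate_labels.copy()
    if cov["population"].nunique() < 2:
        cov = cov.drop(columns=["population"])
    cov = cov.join(pcs)
    cov["net_te_cn"] = np.asarray(net_cn, dtype=float)
    for vid in viral_ids:
        cov[f"viral_{vid}"] = transformed.values.loc[vid].to_numpy()

    analysis = expr.ExpressionMatrix(
        values=transformed.values.drop(index=viral_ids),
        kinds=transformed.kinds.drop(index=viral_ids),
        state="transformed",
        provenance=list(transformed.provenance),
    )
    resid = expr.residualize_covariates(analysis, cov)
    if cfg.n_hidden_factors > 0:
        hidden = expr.estimate_hidden_factors(resid, cfg.n_hidden_factors)
        resid = expr.residualize_covariates(
            expr.ExpressionMatrix(
                values=resid.values, kinds=resid.kinds, state="transformed",
                provenance=list(resid.provenance),
            ),
            hidden,
        )
    int_matrix = expr.inverse_normal_transform(resid)
    return int_matrix, cov, filtered


def run_pipeline(
    cohort: Cohort, cfg: PipelineConfig | None = None, out_dir=None
) -> PipelineResult:
    """Execute the full scan on a cohort; optionally write all tables."""
    cfg = cfg or PipelineConfig()
    report: dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_samples": cohort.genotypes.n_samples,
        "n_variants_input": cohort.genotypes.n_variants,
    }

    stage = "genotype_qc"
    try:
        g_qc, pruned, pcs, net_cn = prepare_genotypes(cohort, cfg)
        report["n_variants_qc"] = g_qc.n_variants
        report["n_variants_pruned"] = pruned.n_variants

        stage = "expression_prep"
        e_int, covariates, filtered_counts = prepare_expression(
            cohort, cfg, pcs, net_cn
        )
        report["n_features_expressed"] = len(e_int.values)

        stage = "cis_scan"
        e_genes = e_int.of_kind("gene")
        cis = assoc.cis_scan(g_qc, e_genes, cohort.genes, cfg.cis_window_bp)
        report["n_cis_tests"] = len(cis)
        report["n_cis_significant"] = int((cis["fdr_bh"] < cfg.alpha).sum())

        stage = "trans_scan"
        e_te = e_int.of_kind("te_subfamily")
        trans, tspec, _ = assoc.trans_scan_with_empirical_fdr(
            g_qc, e_te, n_permutations=cfg.n_perm_scan, alpha=cfg.alpha,
            seed=cfg.seed,
        )
        report["n_trans_tests"] = len(trans)
        report["trans_p_bh"] = tspec.p_bh
        report["trans_p_emp"] = tspec.p_emp
        report["trans_p_final"] = tspec.p_final
        report["n_trans_significant"] = int(
            ((trans["fdr_bh"] < cfg.alpha) & (trans["p"] <= tspec.p_final)).sum()
        )

        stage = "trio_integration"
        tables = trio.integrate_trios(
            cis, trans, e_int, alpha=cfg.alpha, trans_threshold=tspec
        )
        trios = tables.trios
        report["n_trios"] = len(trios)
        report["n_orphan_snvs"] = int(tables.orphans["snv_id"].nunique())

        stage = "clumping"
        clumps: list = []
        if len(trios):
            trio_snvs = sorted(set(trios["snv_id"]))
            best_p = (
                trans[trans["snv_id"].isin(trio_snvs)]
                .groupby("snv_id")["p"].min().to_dict()
            )
            clumps = geno.clump_by_pvalue(
                best_p, g_qc, window_bp=cfg.clump_window_bp, r2_min=cfg.clump_r2
            )
            trios = trio.assign_tiers(trios, clumps)
        report["n_clumps"] = len(clumps)
        report["n_tier1_genes"] = (
            int(trios[trios["tier"] == 1]["gene_id"].nunique()) if len(trios) else 0
        )

        stage = "mediation"
        mediation = pd.DataFrame(columns=mediate.MEDIATION_COLUMNS)
        if len(trios):
            dosage_by_snv = {
                s: g_qc.dosage_of(s) for s in set(trios["snv_id"])
            }
            mediation = mediate.run_mediation(
                trios, dosage_by_snv, e_int.values,
                n_perm=cfg.n_perm_mediation, alpha=cfg.alpha, seed=cfg.seed + 1,
            )
        report["n_mediation_significant"] = int(mediation["significant"].sum()) if len(mediation) else 0

        stage = "dge_gsea"
        dge = gsea = None
        if cfg.run_dge_gsea and len(trios):
            top_snv = (
                trans[trans["snv_id"].isin(set(trios["snv_id"]))]
                .sort_values("p").iloc[0]["snv_id"]
            )
            dge_cov = covariates[[c for c in covariates.columns
                                  if not c.startswith("viral_")]]
            scan_counts = expr.CountMatrix(
                counts=filtered_counts.counts[
                    filtered_counts.kinds.isin(["gene", "te_subfamily"])
                ],
                kinds=filtered_counts.kinds[
                    filtered_counts.kinds.isin(["gene", "te_subfamily"])
                ],
                library_size=filtered_counts.library_size,
            )
            dge = enrich.stratified_dge(
                scan_counts, g_qc.dosage_of(top_snv).astype(float), dge_cov
            )
            ranked = enrich.ranked_list_from_dge(dge)
            family_sets = anno.build_te_family_sets(cohort.te_loci).sets
            gsea = enrich.gsea_run(
                ranked, family_sets, n_perm=cfg.gsea_n_perm, seed=cfg.seed + 2
            )
            report["dge_snv"] = top_snv
            report["n_gsea_sets_significant"] = int((gsea["fdr"] < cfg.alpha).sum())

        stage = "phewas"
        phew = None
        if cfg.run_phewas and len(trios):
            observed = sorted(set(trios["snv_id"]))
            phew = phewas.category_enrichment(
                observed, cohort.trait_map, n_combos=cfg.phewas_n_combos,
                seed=cfg.seed + 3,
            )
            report["n_phewas_categories_significant"] = int(phew["significant"].sum())
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    result = PipelineResult(
        config=cfg, genotypes=g_qc, expression=e_int, covariates=covariates,
        cis=cis, trans=trans, trans_threshold=tspec, trios=trios,
        orphans=tables.orphans, clumps=clumps, mediation=mediation,
        dge=dge, gsea=gsea, phewas=phew, report=report,
    )
    if out_dir is not None:
        write_results(result, out_dir)
    return result


def write_results(result: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": result.report["config_hash"]}
    result.cis.to_csv(out / "cis_eqtl.tsv", sep="\t", index=False)
    result.trans.to_csv(out / "trans_eqtl.tsv", sep="\t", index=False)
    result.trios.to_csv(out / "trios.tsv", sep="\t", index=False)
    result.orphans.to_csv(out / "orphan_snvs.tsv", sep="\t", index=False)
    result.mediation.to_csv(out / "mediation.tsv", sep="\t", index=False)
    if result.dge is not None:
        result.dge.to_csv(out / "dge.tsv", sep="\t", index=False)
    if result.gsea is not None:
        result.gsea.to_csv(out / "gsea.tsv", sep="\t", index=False)
    if result.phewas is not None:
        result.phewas.to_csv(out / "phewas.tsv", sep="\t", index=False)
    if result.clumps:
        p_map = {
            m: c.index_p for c in result.clumps for m in c.members
        }
        best_p = (
            result.trans.groupby("snv_id")["p"].min().to_dict()
        )
        rows = [
            (c.index_snv, m, best_p.get(m, np.nan))
            for c in result.clumps for m in c.members
        ]
        pd.DataFrame(rows, columns=["index_snv", "member", "member_p"]).to_csv(
            out / "clumps.tsv", sep="\t", index=False
        )
    with open(out / "report.json", "w") as fh:
        json.dump({**stamp, **result.report}, fh, indent=1, default=str)
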