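"""SNV-gene-TE trio integration and LD-clump tiering.

A trio is an SNV that is simultaneously a cis-eQTL for a gene and a
trans-eQTL for a TE subfamily, where the gene's and subfamily's expression
are themselves associated by linear regression — all three at FDR < 0.05
(strict). SNVs significant in the trans scan but lacking any cis gene are
"orphans" and are reported separately rather than dropped. Trio SNVs are
clumped by trans-eQTL p-value; genes linked to a clump's index SNV are
tier-1 candidates, genes linked only to non-index clump members tier-2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc import ThresholdSpec, bh_fdr, marginal_regression
from .expr import ExpressionMatrix
from .geno import ClumpAssignment

logger = logging.getLogger(__name__)

TRIO_COLUMNS = [
    "snv_id", "gene_id", "te_subfamily",
    "fdr_cis", "fdr_trans", "fdr_regression", "tier", "is_index_snv",
]


@dataclass
class TrioTables:
    """Integration output: emitted trios plus the orphan-SNV table."""

    trios: pd.DataFrame  # TRIO_COLUMNS
    orphans: pd.DataFrame  # snv_id, te_subfamily, fdr_trans

    def write(self, trio_path, orphan_path) -> None:
        self.trios.to_csv(trio_path, sep="\t", index=False)
        self.orphans.to_csv(orphan_path, sep="\t", index=False)


def gene_te_regression(e_gene: np.ndarray, e_te: np.ndarray) -> tuple[float, float]:
    """OLS of TE subfamily expression on gene expression; (slope, p).

    For the bivariate case the slope's t test is direction-symmetric, so
    regressing TE on gene or gene on TE gives the same p.
    """
    if np.ptp(np.asarray(e_gene, float)) == 0:
        return 0.0, 1.0
    res = marginal_regression(e_gene, e_te)
    return res["beta"], res["p"]


def integrate_trios(
    cis: pd.DataFrame,
    trans: pd.DataFrame,
    e: ExpressionMatrix,
    alpha: float = 0.05,
    trans_threshold: ThresholdSpec | None = None,
) -> TrioTables:
    """Three-part integration of cis and trans scans with expression regression.

    SNVs significant in both scans (FDR < alpha strictly; trans calls also
    require p <= the stricter-of-two threshold when one is supplied) seed
    candidate (SNV, gene, TE) triples. Each unique (gene, TE) pair is tested
    by linear regression, BH-adjusted across all candidate pairs, and trios
    with all three FDRs < alpha are emitted. Trans-significant SNVs with no
    cis gene appear in the orphan table.
    """
    cis_sig = cis[cis["fdr_bh"] < alpha]
    trans_sig = trans[trans["fdr_bh"] < alpha]
    if trans_threshold is not None:
        trans_sig = trans_sig[trans_sig["p"] <= trans_threshold.p_final]

    cis_by_snv = cis_sig.groupby("snv_id")
    trans_by_snv = trans_sig.groupby("snv_id")
    cis_snvs = set(cis_by_snv.groups)
    trans_snvs = set(trans_by_snv.groups)

    orphans = trans_sig[~trans_sig["snv_id"].isin(cis_snvs)][
        ["snv_id", "feature_id", "fdr_bh"]
    ].rename(columns={"feature_id": "te_subfamily", "fdr_bh": "fdr_trans"})
    orphans = orphans.reset_index(drop=True)

    shared = sorted(cis_snvs & trans_snvs)
    candidates = []
    for snv in shared:
        for _, crow in cis_by_snv.get_group(snv).iterrows():
            for _, trow in trans_by_snv.get_group(snv).iterrows():
                candidates.append(
                    (snv, crow["feature_id"], trow["feature_id"],
                     crow["fdr_bh"], trow["fdr_bh"])
                )
    if not candidates:
        return TrioTables(
            trios=pd.DataFrame(columns=TRIO_COLUMNS), orphans=orphans
        )

    cand = pd.DataFrame(
        candidates,
        columns=["snv_id", "gene_id", "te_subfamily", "fdr_cis", "fdr_trans"],
    )
    missing = set(cand["gene_id"]).union(cand["te_subfamily"]) - set(e.values.index)
    if missing:
        raise KeyError(f"expression matrix lacks features: {sorted(missing)[:5]}")

    pairs = cand[["gene_id", "te_subfamily"]].drop_duplicates()
    pair_p = {}
    for gene, te in pairs.itertuples(index=False):
        _, p = gene_te_regression(
            e.values.loc[gene].to_numpy(), e.values.loc[te].to_numpy()
        )
        pair_p[(gene, te)] = p
    keys = list(pair_p)
    fdr = dict(zip(keys, bh_fdr([pair_p[k] for k in keys])))
    cand["fdr_regression"] = [
        fdr[(g, t)] for g, t in cand[["gene_id", "te_subfamily"]].itertuples(index=False)
    ]
    out = cand[
        (cand["fdr_cis"] < alpha)
        & (cand["fdr_trans"] < alpha)
        & (cand["fdr_regression"] < alpha)
    ].copy()
    out["tier"] = "none"
    out["is_index_snv"] = False
    return TrioTables(
        trios=out[TRIO_COLUMNS].reset_index(drop=True), orphans=orphans
    )


def assign_tiers(trios: pd.DataFrame, clumps: list[ClumpAssignment]) -> pd.DataFrame:
    """Label trios tier 1 (index SNV) or tier 2 (clumped, non-index) per gene.

    A gene is tier 1 if any of its trios uses a clump's index SNV; genes
    linked only through non-index members are tier 2. Trio SNVs absent from
    every clump are an error.
    """
    index_snvs = {c.index_snv for c in clumps}
    member_snvs = {m for c in clumps for m in c.members}
    orphan = set(trios["snv_id"]) - member_snvs
    if orphan:
        raise KeyError(f"trio SNVs not in any clump: {sorted(orphan)}")
    out = trios.copy()
    out["is_index_snv"] = out["snv_id"].isin(index_snvs)
    gene_tier = {
        gene: 1 if grp["is_index_snv"].any() else 2
        for gene, grp in out.groupby("gene_id")
    }
    out["tier"] = out["gene_id"].map(gene_tier)
    return out
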