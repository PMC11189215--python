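"""Differential expression and gene-set enrichment.

Genotype- or condition-stratified differential expression fits, per
feature, an OLS of log2 median-of-ratios-normalized counts on the group
term (additive 0/1/2 dosage or a 0/1 contrast) plus covariates; the group
coefficient is the log2 fold change and coefficient/SE the Wald-type
statistic used to build a combined ranked list of genes and TE
subfamilies.

Set-level enrichment follows the weighted Kolmogorov-Smirnov running-sum
paradigm: walking down the ranked list, set members increment the sum by
|stat|^w normalized over member stats, non-members decrement by
1/(N - N_hits); the enrichment score is the signed maximum deviation. The
null is feature-label permutation (random same-size sets), the NES divides
the ES by the mean |null ES| of matching sign, and p comes from the
matching-sign null tail with the add-one rule.

Also here: the one-sample Wilcoxon test for whole-TE-family log2FC shifts,
Fisher's method for combining p-values, and the meta-ranking of gene sets
shared across analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import bh_fdr
from .expr import CountMatrix, build_design, size_factors_median_ratio

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Stratified differential expression (OLS Wald on transformed counts)
# ---------------------------------------------------------------------------


def stratified_dge(
    c: CountMatrix, group: np.ndarray, cov: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-feature differential expression against a numeric group term.

    Returns feature_id, log2fc (group coefficient on the log2 scale),
    wald_stat, p and BH fdr. The group vector is 0/1/2 dosage or a 0/1
    condition contrast; covariates are one-hot expanded with intercept.
    """
    group = np.asarray(group, dtype=float)
    if np.ptp(group) == 0:
        raise ValueError("group term is constant")
    factors = size_factors_median_ratio(c)
    y = np.log2(c.counts / factors + 1.0).to_numpy().T  # samples x features
    if cov is not None:
        design = build_design(cov.loc[c.samples])
    else:
        design = pd.DataFrame({"intercept": np.ones(len(c.samples))}, index=c.samples)
    x = np.column_stack([group, design.to_numpy()])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError("rank-deficient design (group collinear with covariates?)")
    n, k = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    coef = xtx_inv @ x.T @ y  # k x features
    resid = y - x @ coef
    df = n - k
    sigma2 = (resid * resid).sum(axis=0) / df
    se = np.sqrt(xtx_inv[0, 0] * sigma2)
    log2fc = coef[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, log2fc / se, 0.0)
    p = np.clip(2.0 * stats.t.sf(np.abs(wald), df), np.finfo(float).tiny, 1.0)
    out = pd.DataFrame(
        {
            "feature_id": c.features,
            "log2fc": log2fc,
            "wald_stat": wald,
            "p": p,
        }
    )
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out


def ranked_list_from_dge(dge: pd.DataFrame) -> pd.DataFrame:
    """Descending Wald-statistic ranking; ties broken by feature ID."""
    return dge.sort_values(
        ["wald_stat", "feature_id"], ascending=[False, True], kind="stable"
    )[["feature_id", "wald_stat"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# GSEA
# ---------------------------------------------------------------------------


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p: float
    fdr: float
    leading_edge: list


def gsea_es(
    ranked: pd.DataFrame, members: set, weight_exp: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score and its running-sum profile.

    ``ranked`` has columns feature_id, stat (already ordered). Hits add
    |stat|^weight_exp normalized by the hit total; misses subtract
    1/(N - N_hits). Returns (signed max-deviation ES, running profile).
    """
    features = ranked["feature_id"].to_numpy()
    statv = ranked.iloc[:, 1].to_numpy(dtype=float)
    hit = np.isin(features, list(members))
    n = len(features)
    n_hits = int(hit.sum())
    if n_hits == 0 or n_hits == n:
        raise ValueError("gene set covers none or all of the ranked list")
    w = np.abs(statv) ** weight_exp
    hit_total = w[hit].sum()
    if hit_total == 0:
        # all member stats zero: fall back to equal hit increments
        increments = np.where(hit, 1.0 / n_hits, 0.0)
    else:
        increments = np.where(hit, w / hit_total, 0.0)
    decrement = 1.0 / (n - n_hits)
    running = np.cumsum(increments - np.where(hit, 0.0, decrement))
    extremum = np.argmax(np.abs(running))
    return float(running[extremum]), running


def _leading_edge(ranked: pd.DataFrame, members: set, running: np.ndarray) -> list:
    extremum = int(np.argmax(np.abs(running)))
    features = ranked["feature_id"].to_numpy()
    if running[extremum] >= 0:
        window = features[: extremum + 1]
    else:
        window = features[extremum:]
    return [f for f in window if f in members]


def gsea_run(
    ranked: pd.DataFrame,
    sets: dict,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exp: float = 1.0,
    min_size: int = 3,
) -> pd.DataFrame:
    """GSEA over a collection of sets with a feature-label permutation null.

    For each set, random same-size feature sets supply the null ES
    distribution; NES = ES / mean(|null ES| of matching sign), and the
    p-value is the matching-sign tail fraction with the add-one rule. BH
    FDR is applied across sets. Fixed seed gives bit-identical output.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d is low; null tails will be coarse", n_perm)
    rng = np.random.default_rng(seed)
    universe = ranked["feature_id"].to_numpy()
    results = []
    for name in sorted(sets):
        members = set(sets[name]) & set(universe)
        if len(members) < min_size or len(members) >= len(universe):
            logger.info("skipping set %s (size %d in universe)", name, len(members))
            continue
        es, running = gsea_es(ranked, members, weight_exp)
        size = len(members)
        null = np.empty(n_perm)
        for b in range(n_perm):
            rand = set(rng.choice(universe, size=size, replace=False))
            null[b], _ = gsea_es(ranked, rand, weight_exp)
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        # add-one p over all permutations; only matching-sign exceedances count
        if same_sign.size == 0:
            nes = 0.0
            p = 1.0 / (n_perm + 1)
        else:
            nes = es / np.abs(same_sign).mean()
            p = (1 + (np.abs(same_sign) >= abs(es)).sum()) / (n_perm + 1)
        results.append(
            GseaResult(
                set_name=name, es=es, nes=float(nes), p=float(p), fdr=np.nan,
                leading_edge=_leading_edge(ranked, members, running),
            )
        )
    if not results:
        return pd.DataFrame(
            columns=["set_name", "es", "nes", "p", "fdr", "leading_edge"]
        )
    out = pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "p": [r.p for r in results],
        }
    )
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    out["leading_edge"] = [r.leading_edge for r in results]
    return out


# ---------------------------------------------------------------------------
# One-sample Wilcoxon family shift
# ---------------------------------------------------------------------------


def family_wilcoxon(log2fc_by_family: dict) -> pd.DataFrame:
    """Per-family one-sample Wilcoxon signed-rank test of log2FC against 0.

    Zeros are dropped (Wilcoxon convention); exact p for n <= 25, normal
    approximation above. BH FDR across families.
    """
    rows = []
    for family in sorted(log2fc_by_family):
        x = np.asarray(log2fc_by_family[family], dtype=float)
        nonzero = x[x != 0]
        if nonzero.size == 0:
            raise ValueError(f"family {family!r}: no nonzero changes")
        if nonzero.size < 2:
            raise ValueError(f"family {family!r}: fewer than 2 nonzero changes")
        has_ties = np.unique(np.abs(nonzero)).size < nonzero.size
        method = "exact" if nonzero.size <= 25 and not has_ties else "approx"
        res = stats.wilcoxon(
            nonzero, alternative="two-sided", method=method,
            correction=(method == "approx"),
        )
        rows.append(
            (family, float(np.median(x)), float(res.statistic), float(res.pvalue))
        )
    out = pd.DataFrame(rows, columns=["family", "median_log2fc", "wilcoxon_V", "p"])
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Fisher's method and shared-set meta-ranking
# ---------------------------------------------------------------------------


def fisher_combine(p_list) -> dict:
    """Fisher's method: chi2 = -2 sum(ln p), df = 2k, upper-tail p."""
    p = np.asarray(p_list, dtype=float)
    if p.size == 0 or (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return {"chi2": chi2, "df": df, "p_combined": float(stats.chi2.sf(chi2, df))}


def shared_set_meta_rank(
    analyses: list[pd.DataFrame],
    sign_pattern: list[int],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank gene sets shared (significant, correctly signed) across analyses.

    A set qualifies if in every analysis it has fdr < alpha and
    sign(nes) equal to that analysis's required sign (+1/-1). Qualifying
    sets are ranked by the Fisher-combined p over their per-analysis
    p-values.
    """
    if len(analyses) < 2:
        raise ValueError("meta-ranking needs >= 2 analyses")
    if len(sign_pattern) != len(analyses):
        raise ValueError("one required sign per analysis")
    eligible = None
    for res, sign in zip(analyses, sign_pattern):
        ok = set(
            res[(res["fdr"] < alpha) & (np.sign(res["nes"]) == sign)]["set_name"]
        )
        eligible = ok if eligible is None else (eligible & ok)
    if not eligible:
        logger.info("no gene set is shared across all analyses")
        return pd.DataFrame(columns=["set_name", "chi2", "p_combined"])
    rows = []
    for name in sorted(eligible):
        ps = [
            float(res.loc[res["set_name"] == name, "p"].iloc[0]) for res in analyses
        ]
        comb = fisher_combine(ps)
        rows.append((name, comb["chi2"], comb["p_combined"]))
    out = pd.DataFrame(rows, columns=["set_name", "chi2", "p_combined"])
    return out.sort_values("p_combined", kind="stable").reset_index(drop=True)
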