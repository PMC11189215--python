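"""Association scans: cis-eQTL, trans-eQTL, BH FDR, empirical FDR.

The scan model is bivariate OLS of inverse-normal expression on additive
SNV dosage (covariates having been regressed out beforehand), with a
two-sided t test on the slope at n - 2 degrees of freedom. Cis pairs are
SNV-gene combinations within a genomic window of the gene's nearest
boundary; the trans scan tests every SNV against every aggregated TE
subfamily.

Significance uses the stricter of two thresholds: the p-value at
Benjamini-Hochberg FDR < alpha, and the p-value at permutation-averaged
empirical FDR < alpha, where the null p-values come from rescanning
expression matrices whose sample labels were scrambled. The empirical FDR
at a real p-value p_i is the average number of null points with p <= p_i
across permutations, divided by the number of real points with p <= p_i.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .anno import GeneModel
from .expr import ExpressionMatrix
from .geno import GenotypeMatrix

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["snv_id", "feature_id", "beta", "se", "t_stat", "p", "fdr_bh"]

_TINY_P = np.finfo(float).tiny


@dataclass
class ThresholdSpec:
    """The stricter-of-two significance rule for a scan.

    ``p_bh`` is the largest p with BH FDR < alpha, ``p_emp`` the largest p
    with average empirical FDR < alpha; calls use ``p_final`` = min of the
    two.
    """

    p_bh: float
    p_emp: float
    alpha: float = 0.05
    n_permutations: int = 0

    @property
    def p_final(self) -> float:
        return min(self.p_bh, self.p_emp)


# ---------------------------------------------------------------------------
# Core regression
# ---------------------------------------------------------------------------


def marginal_regression(dosage: np.ndarray, expression: np.ndarray) -> dict:
    """OLS of expression on dosage with intercept; two-sided slope test.

    Returns a dict with beta, se, t_stat and p (df = n - 2). Constant
    expression yields beta 0, p 1; constant dosage is an error.
    """
    d = np.asarray(dosage, dtype=float)
    y = np.asarray(expression, dtype=float)
    if d.shape != y.shape or d.size < 4:
        raise ValueError("vectors must share length >= 4")
    if np.ptp(d) == 0:
        raise ValueError("constant dosage vector")
    if np.ptp(y) == 0:
        return {"beta": 0.0, "se": np.nan, "t_stat": 0.0, "p": 1.0}
    n = d.size
    dc = d - d.mean()
    yc = y - y.mean()
    sxx = dc @ dc
    beta = (dc @ yc) / sxx
    resid = yc - beta * dc
    df = n - 2
    sigma2 = (resid @ resid) / df
    se = np.sqrt(sigma2 / sxx)
    if se == 0:
        t = np.inf if beta > 0 else -np.inf
        p = _TINY_P
    else:
        t = beta / se
        p = 2.0 * stats.t.sf(abs(t), df)
    return {"beta": float(beta), "se": float(se), "t_stat": float(t), "p": float(max(p, _TINY_P))}


def _scan_stats(dosage: np.ndarray, expr: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorized slope/SE/t/p for all dosage columns x expression rows.

    ``dosage``: samples x m; ``expr``: k x samples. Returns (beta, se, t, p)
    arrays of shape (m, k).
    """
    n = dosage.shape[0]
    df = n - 2
    dc = dosage - dosage.mean(axis=0, keepdims=True)
    yc = expr - expr.mean(axis=1, keepdims=True)
    sxx = (dc * dc).sum(axis=0)  # m
    syy = (yc * yc).sum(axis=1)  # k
    sxy = dc.T @ yc.T  # m x k
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx[:, None]
        r2 = (sxy * sxy) / (sxx[:, None] * syy[None, :])
        r2 = np.clip(r2, 0.0, 1.0)
        se = np.sqrt(syy[None, :] * (1.0 - r2) / (df * sxx[:, None]))
        t = np.where(se > 0, beta / se, np.sign(beta) * np.inf)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    constant = np.broadcast_to(syy[None, :] == 0, beta.shape)
    beta = np.where(constant, 0.0, beta)
    t = np.where(constant, 0.0, t)
    p = np.where(constant, 1.0, p)
    p = np.clip(p, _TINY_P, 1.0)
    return beta, se, t, p


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bh_threshold(p, alpha: float = 0.05) -> float:
    """Largest p called significant at BH FDR < alpha (0 if none)."""
    p = np.asarray(p, dtype=float)
    adj = bh_fdr(p)
    passing = p[adj < alpha]
    return float(passing.max()) if passing.size else 0.0


# ---------------------------------------------------------------------------
# Empirical (permutation-averaged) FDR
# ---------------------------------------------------------------------------


class EmpiricalFDR:
    """Permutation-averaged empirical FDR over a scan's real p-values.

    eFDR(p_i) = (average number of null p <= p_i across permutations)
                / (number of real p <= p_i), capped at 1, evaluated at the
    observed real p-values.
    """

    def __init__(self, p_real, p_null_per_perm) -> None:
        if len(p_null_per_perm) < 1:
            raise ValueError("at least one permutation required")
        self.p_real = np.sort(np.asarray(p_real, dtype=float))
        self.n_perm = len(p_null_per_perm)
        self._null_sorted = np.sort(np.concatenate([np.asarray(x, float) for x in p_null_per_perm]))

    def __call__(self, p_i: float) -> float:
        n_real = np.searchsorted(self.p_real, p_i, side="right")
        if n_real == 0:
            raise ValueError(f"no real p-value <= {p_i}; eFDR undefined there")
        avg_null = np.searchsorted(self._null_sorted, p_i, side="right") / self.n_perm
        return float(min(1.0, avg_null / n_real))

    def threshold(self, alpha: float = 0.05) -> float:
        """Largest real p with eFDR < alpha (0 if none passes)."""
        passing = [p for p in self.p_real if self(p) < alpha]
        return float(max(passing)) if passing else 0.0


def empirical_fdr(p_real, p_null_per_perm) -> EmpiricalFDR:
    """Build the empirical-FDR function from real and per-permutation null p."""
    return EmpiricalFDR(p_real, p_null_per_perm)


def significance_threshold(
    p_bh_alpha: float, p_emp_alpha: float, alpha: float = 0.05, n_permutations: int = 0
) -> ThresholdSpec:
    """Stricter-of-two rule: final threshold is min(BH, empirical)."""
    if p_bh_alpha < 0 or p_emp_alpha < 0:
        raise ValueError("thresholds must be nonnegative")
    return ThresholdSpec(
        p_bh=float(p_bh_alpha),
        p_emp=float(p_emp_alpha),
        alpha=alpha,
        n_permutations=n_permutations,
    )


# ---------------------------------------------------------------------------
# Scans
# ---------------------------------------------------------------------------


def _expr_aligned(g: GenotypeMatrix, e: ExpressionMatrix) -> np.ndarray:
    if e.samples != list(g.samples):
        raise ValueError("genotypes and expression must share sample order")
    return e.values.to_numpy(dtype=float)


def _results_frame(snv_ids, feature_ids, beta, se, t, p) -> pd.DataFrame:
    res = pd.DataFrame(
        {
            "snv_id": snv_ids,
            "feature_id": feature_ids,
            "beta": beta,
            "se": se,
            "t_stat": t,
            "p": p,
        }
    )
    res["fdr_bh"] = bh_fdr(res["p"].to_numpy()) if len(res) else []
    return res


def cis_pair_roster(
    g: GenotypeMatrix, genes: list[GeneModel], window_bp: int = 1_000_000
) -> pd.DataFrame:
    """SNV-gene pairs with SNV within ``window_bp`` of the gene's nearest boundary."""
    rows = []
    snv_chrom = g.variants["chrom"].to_numpy()
    snv_pos = g.variants["pos"].to_numpy()
    snv_id = g.variants["id"].to_numpy()
    for gene in genes:
        on_chrom = np.flatnonzero(snv_chrom == gene.chrom)
        pos = snv_pos[on_chrom]
        dist = np.where(
            pos < gene.start, gene.start - pos, np.where(pos > gene.end, pos - gene.end, 0)
        )
        for j in on_chrom[dist <= window_bp]:
            rows.append((snv_id[j], gene.gene_id))
    return pd.DataFrame(rows, columns=["snv_id", "feature_id"])


def cis_scan(
    g: GenotypeMatrix,
    e: ExpressionMatrix,
    genes: list[GeneModel],
    window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Test each SNV against expressed genes within ``window_bp``.

    BH FDR is computed jointly over all cis tests. Genes absent from the
    expression matrix are skipped.
    """
    expr = _expr_aligned(g, e)
    feature_index = {f: i for i, f in enumerate(e.values.index)}
    roster = cis_pair_roster(g, [gn for gn in genes if gn.gene_id in feature_index], window_bp)
    if roster.empty:
        warnings.warn("no cis SNV-gene pairs within the window", stacklevel=2)
        return _results_frame([], [], [], [], [], [])
    snv_idx = np.array([g.variant_index(s) for s in roster["snv_id"]])
    feat_idx = np.array([feature_index[f] for f in roster["feature_id"]])
    beta, se, t, p = _pairwise_pairs_stats(g.dosage, expr, snv_idx, feat_idx)
    return _results_frame(
        roster["snv_id"].to_numpy(), roster["feature_id"].to_numpy(), beta, se, t, p
    )


def _pairwise_pairs_stats(dosage, expr, snv_idx, feat_idx):
    """Per-pair OLS stats for explicit (SNV index, feature index) pairs."""
    n = dosage.shape[0]
    df = n - 2
    d = dosage[:, snv_idx].astype(float)
    y = expr[feat_idx, :].T
    dc = d - d.mean(axis=0)
    yc = y - y.mean(axis=0)
    sxx = (dc * dc).sum(axis=0)
    syy = (yc * yc).sum(axis=0)
    sxy = (dc * yc).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        r2 = np.clip((sxy * sxy) / (sxx * syy), 0.0, 1.0)
        se = np.sqrt(syy * (1.0 - r2) / (df * sxx))
        t = np.where(se > 0, beta / se, np.sign(beta) * np.inf)
        p = np.clip(2.0 * stats.t.sf(np.abs(t), df), _TINY_P, 1.0)
    constant = syy == 0
    beta = np.where(constant, 0.0, beta)
    t = np.where(constant, 0.0, t)
    p = np.where(constant, 1.0, p)
    return beta, se, t, p


def trans_scan(g: GenotypeMatrix, e: ExpressionMatrix) -> pd.DataFrame:
    """Test every SNV against every (TE subfamily) expression feature."""
    expr = _expr_aligned(g, e)
    beta, se, t, p = _scan_stats(g.dosage.astype(float), expr)
    m, k = beta.shape
    snv_ids = np.repeat(g.variants["id"].to_numpy(), k)
    feat_ids = np.tile(np.asarray(e.values.index), m)
    return _results_frame(snv_ids, feat_ids, beta.ravel(), se.ravel(), t.ravel(), p.ravel())


def permutation_null_pvalues(
    g: GenotypeMatrix, e: ExpressionMatrix, n_permutations: int, seed: int
) -> list[np.ndarray]:
    """Null p-value sets from scans of sample-scrambled expression.

    One shared sample permutation per round is applied to the whole
    expression matrix (preserving feature-feature correlation), and the full
    trans scan is repeated. Seeded and reproducible.
    """
    rng = np.random.default_rng(seed)
    expr = _expr_aligned(g, e)
    dosage = g.dosage.astype(float)
    nulls = []
    for _ in range(n_permutations):
        perm = rng.permutation(expr.shape[1])
        _, _, _, p = _scan_stats(dosage, expr[:, perm])
        nulls.append(p.ravel())
    return nulls


def trans_scan_with_empirical_fdr(
    g: GenotypeMatrix,
    e: ExpressionMatrix,
    n_permutations: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, ThresholdSpec, EmpiricalFDR]:
    """Trans scan plus both significance thresholds.

    Returns the result table (with ``fdr_emp`` evaluated at each real p),
    the stricter-of-two ThresholdSpec, and the EmpiricalFDR object.
    """
    res = trans_scan(g, e)
    nulls = permutation_null_pvalues(g, e, n_permutations, seed)
    efdr = empirical_fdr(res["p"].to_numpy(), nulls)
    res["fdr_emp"] = [efdr(p) for p in res["p"]]
    spec = significance_threshold(
        bh_threshold(res["p"].to_numpy(), alpha),
        efdr.threshold(alpha),
        alpha=alpha,
        n_permutations=n_permutations,
    )
    return res, spec, efdr


def targeted_scan(
    pairs: list[tuple[str, str]], g: GenotypeMatrix, e: ExpressionMatrix
) -> pd.DataFrame:
    """Marginal regressions for named (snv, feature) pairs only.

    BH FDR is adjusted over the targeted set alone — the replication-cohort
    design where only previously significant pairs are retested.
    """
    expr = _expr_aligned(g, e)
    if not pairs:
        return _results_frame([], [], [], [], [], [])
    feature_index = {f: i for i, f in enumerate(e.values.index)}
    snv_idx, feat_idx = [], []
    for snv, feat in pairs:
        if feat not in feature_index:
            raise KeyError(f"unknown feature {feat!r}")
        snv_idx.append(g.variant_index(snv))  # raises KeyError naming the SNV
        feat_idx.append(feature_index[feat])
    beta, se, t, p = _pairwise_pairs_stats(
        g.dosage, expr, np.array(snv_idx), np.array(feat_idx)
    )
    return _results_frame(
        [s for s, _ in pairs], [f for _, f in pairs], beta, se, t, p
    )
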