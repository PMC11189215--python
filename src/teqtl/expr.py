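"""Expression preparation: filtering, transformation, residualization, INT.

Count matrices hold genes, TE subfamilies (or loci), and the viral
expression feature as rows, samples as columns. Preparation moves an
ExpressionMatrix through the forward-only states

    raw counts -> transformed -> residualized -> inverse_normal

matching the usual eQTL recipe: drop lowly expressed features, apply a
variance-stabilizing transform (here log2 of median-of-ratios-normalized
counts + 1), regress out known covariates, then map each feature's values
onto exact normal scores so the association scan sees Gaussian phenotypes.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

logger = logging.getLogger(__name__)

FEATURE_KINDS = ("gene", "te_subfamily", "te_locus", "viral")

STATE_ORDER = {"transformed": 0, "residualized": 1, "inverse_normal": 2}


@dataclass
class CountMatrix:
    """Nonnegative integer counts, features x samples.

    ``kinds`` labels each feature as gene / te_subfamily / te_locus / viral.
    ``library_size`` is the per-sample column total at load time and is kept
    fixed through feature filtering so CPM thresholds refer to the original
    sequencing depth.
    """

    counts: pd.DataFrame  # features x samples
    kinds: pd.Series  # feature -> kind
    library_size: pd.Series = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        self.kinds = self.kinds.reindex(self.counts.index)
        unknown = set(self.kinds.dropna()) - set(FEATURE_KINDS)
        if unknown:
            raise ValueError(f"unknown feature kinds: {sorted(unknown)}")
        if self.library_size is None:
            self.library_size = self.counts.sum(axis=0)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    def subset_features(self, features) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts.loc[features],
            kinds=self.kinds.loc[features],
            library_size=self.library_size,
        )

    def of_kind(self, kind: str) -> "CountMatrix":
        keep = self.kinds[self.kinds == kind].index
        return self.subset_features(keep)

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "kind", self.kinds)
        out.index.name = "feature"
        out.to_csv(path, sep="\t")


@dataclass
class ExpressionMatrix:
    """Real-valued expression, features x samples, with a pipeline state.

    State only moves forward (transformed -> residualized -> inverse_normal);
    ``provenance`` accumulates a record per processing step.
    """

    values: pd.DataFrame
    kinds: pd.Series
    state: str
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.state not in STATE_ORDER:
            raise ValueError(f"unknown state {self.state!r}")
        self.kinds = self.kinds.reindex(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def _advance(self, new_state: str, values: pd.DataFrame, record: dict) -> "ExpressionMatrix":
        if STATE_ORDER[new_state] < STATE_ORDER[self.state]:
            raise ValueError(f"cannot move state {self.state} -> {new_state}")
        return ExpressionMatrix(
            values=values,
            kinds=self.kinds,
            state=new_state,
            provenance=[*self.provenance, record],
        )

    def of_kind(self, kind: str) -> "ExpressionMatrix":
        keep = self.kinds[self.kinds == kind].index
        return ExpressionMatrix(
            values=self.values.loc[keep],
            kinds=self.kinds.loc[keep],
            state=self.state,
            provenance=list(self.provenance),
        )

    def to_tsv(self, path, provenance_path=None) -> None:
        out = self.values.copy()
        out.insert(0, "kind", self.kinds)
        out.index.name = "feature"
        out.to_csv(path, sep="\t")
        if provenance_path is not None:
            with open(provenance_path, "w") as fh:
                for record in self.provenance:
                    fh.write(json.dumps(record) + "\n")


def read_counts_tsv(path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    kinds = df.pop("kind")
    return CountMatrix(counts=df, kinds=kinds)


def read_covariates_tsv(path) -> pd.DataFrame:
    cov = pd.read_csv(path, sep="\t", index_col=0)
    if cov.isna().any().any():
        raise ValueError("covariate table contains missing values")
    return cov


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def cpm_for_reads(reads: float, library_sizes) -> float:
    """CPM corresponding to ``reads`` in the median-size library.

    Used to derive the low-expression CPM cutoff from a read-count rule
    (e.g. 10 reads in the median-length library).
    """
    return reads * 1e6 / float(np.median(np.asarray(library_sizes, dtype=float)))


def filter_low_expression(
    c: CountMatrix, cpm_min: float, min_fraction: float = 0.9
) -> CountMatrix:
    """Drop features not exceeding ``cpm_min`` CPM in enough samples.

    A feature survives iff count * 1e6 / library_size > cpm_min (strictly)
    in at least ceil(min_fraction * n_samples) samples.
    """
    if cpm_min < 0:
        raise ValueError("cpm_min must be nonnegative")
    if (c.library_size <= 0).any():
        raise ValueError("library sizes must be positive")
    required = math.ceil(min_fraction * len(c.samples))
    cpm = c.counts * 1e6 / c.library_size
    keep = (cpm > cpm_min).sum(axis=1) >= required
    return c.subset_features(c.counts.index[keep])


# ---------------------------------------------------------------------------
# Normalization and transformation
# ---------------------------------------------------------------------------


def size_factors_median_ratio(c: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Per sample, the factor is the median across all-positive features of
    count / geometric-mean(count across samples). Raises if no feature is
    positive in every sample.
    """
    counts = c.counts.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature has positive counts in all samples; "
            "add a pseudocount upstream or filter samples"
        )
    logc = np.log(counts[positive])
    log_geo = logc.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logc - log_geo, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=c.counts.columns, name="size_factor")


def vst_transform(c: CountMatrix) -> ExpressionMatrix:
    """Variance-stabilizing transform: log2(count / size_factor + 1)."""
    factors = size_factors_median_ratio(c)
    values = np.log2(c.counts / factors + 1.0)
    return ExpressionMatrix(
        values=values,
        kinds=c.kinds,
        state="transformed",
        provenance=[
            {
                "step": "vst",
                "transform": "log2(median_ratio_normalized + 1)",
                "n_features": len(c.features),
            }
        ],
    )


# ---------------------------------------------------------------------------
# Covariate residualization
# ---------------------------------------------------------------------------


def build_design(cov: pd.DataFrame) -> pd.DataFrame:
    """Expand a covariate table into a full-rank design with intercept.

    Categorical (object/category/bool) columns are one-hot encoded with the
    lexicographically first level dropped as reference; numeric columns pass
    through. Raises on rank deficiency, naming the collinear columns.
    """
    pieces = [pd.Series(1.0, index=cov.index, name="intercept")]
    for col in cov.columns:
        s = cov[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool:
            levels = sorted(s.astype(str).unique())
            for level in levels[1:]:
                pieces.append(
                    (s.astype(str) == level).astype(float).rename(f"{col}[{level}]")
                )
        else:
            pieces.append(s.astype(float))
    design = pd.concat(pieces, axis=1)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        kept = []
        for col in design.columns:
            trial = design[kept + [col]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(col)
            else:
                bad.append(col)
        raise ValueError(f"rank-deficient covariate design; collinear: {bad}")
    return design


def residualize_covariates(
    e: ExpressionMatrix, cov: pd.DataFrame
) -> ExpressionMatrix:
    """Regress covariates out of each feature, keeping the feature mean.

    Fits per-feature least squares on the one-hot-expanded design (with
    intercept) and returns residual + feature mean, so downstream transforms
    see covariate-free but location-preserved values.
    """
    if e.state != "transformed":
        raise ValueError("residualization expects a transformed matrix")
    if list(cov.index) != e.samples:
        cov = cov.loc[e.samples]
    design = build_design(cov).to_numpy()
    y = e.values.to_numpy().T  # samples x features
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    values = pd.DataFrame(
        (resid + y.mean(axis=0)).T, index=e.values.index, columns=e.values.columns
    )
    return e._advance(
        "residualized",
        values,
        {"step": "residualize", "covariates": list(cov.columns)},
    )


# ---------------------------------------------------------------------------
# Inverse normal transform
# ---------------------------------------------------------------------------

BLOM_OFFSET = 3.0 / 8.0


def inverse_normal_transform(
    e: ExpressionMatrix, allow_transformed: bool = False
) -> ExpressionMatrix:
    """Rank-based inverse normal transform with the Blom offset.

    Per feature, value_i = Phi^-1((rank_i - 3/8) / (n + 1/4)); ties share
    their average rank. After this step every feature row is a permutation
    of the same fixed normal scores (exactly, absent ties).
    """
    if e.state == "transformed" and not allow_transformed:
        raise ValueError(
            "INT expects residualized input; pass allow_transformed=True to override"
        )
    if e.state == "inverse_normal":
        raise ValueError("matrix is already inverse-normal")
    x = e.values.to_numpy()
    n = x.shape[1]
    out = np.empty_like(x, dtype=float)
    for i in range(x.shape[0]):
        row = x[i]
        if np.ptp(row) == 0:
            raise ValueError(
                f"cannot rank constant row {e.values.index[i]!r}"
            )
        ranks = rankdata(row, method="average")
        out[i] = norm.ppf((ranks - BLOM_OFFSET) / (n - 2 * BLOM_OFFSET + 1))
    values = pd.DataFrame(out, index=e.values.index, columns=e.values.columns)
    return e._advance(
        "inverse_normal", values, {"step": "int", "offset": "blom_3_8"}
    )


# ---------------------------------------------------------------------------
# Hidden factors (PCA stand-in for hidden-confounder estimation)
# ---------------------------------------------------------------------------


def estimate_hidden_factors(e: ExpressionMatrix, k: int) -> pd.DataFrame:
    """Top-k principal components of the feature-standardized residuals.

    A light stand-in for dedicated hidden-factor models: each feature row is
    standardized, then sample-space PCs capture remaining global structure
    and can be fed back in as extra numeric covariates. ``k = 0`` returns an
    empty table.
    """
    if e.state != "residualized":
        raise ValueError("hidden factors are estimated on residualized data")
    cols = [f"HF{i + 1}" for i in range(k)]
    if k == 0:
        return pd.DataFrame(index=pd.Index(e.samples, name="sample"), columns=cols)
    x = e.values.to_numpy().astype(float)
    sd = x.std(axis=1)
    x = x[sd > 0]
    x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(x.T, full_matrices=False)  # samples x features
    if k > min(x.T.shape):
        raise ValueError("k exceeds matrix rank bound")
    scores = u[:, :k] * s[:k]
    for j in range(k):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            scores[:, j] *= -1
    return pd.DataFrame(scores, index=pd.Index(e.samples, name="sample"), columns=cols)
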