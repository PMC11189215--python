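"""Trait-category enrichment of hit SNV sets against random combinations.

Given a prepared SNV -> trait-category mapping (e.g. disease categories
from a GWAS portal), the observed hit set's per-category mapping counts
are compared with those of many random equal-size SNV sets drawn from the
scan universe. Per category, the random counts define an empirical
cumulative distribution; the enrichment p is the literal 1 - ecdf(observed
count), the enrichment score ES is observed / median(random counts), and a
category is significantly enriched when ES > 1 and BH FDR < 0.05. A
conservative add-one permutation p is reported alongside because the
literal formula can return exactly 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc import bh_fdr

logger = logging.getLogger(__name__)


@dataclass
class TraitMap:
    """SNV -> set-of-categories mapping over a defined SNV universe."""

    mapping: dict  # snv_id -> set of category labels
    universe: set  # all scannable SNV ids

    def __post_init__(self) -> None:
        outside = set(self.mapping) - self.universe
        if outside:
            raise ValueError(f"mapped SNVs outside universe: {sorted(outside)[:5]}")

    @property
    def categories(self) -> list[str]:
        return sorted({c for cats in self.mapping.values() for c in cats})

    @classmethod
    def read_tsv(cls, path, universe=None) -> "TraitMap":
        """Long-format TSV with columns snv_id, category."""
        df = pd.read_csv(path, sep="\t")
        mapping: dict[str, set] = {}
        for snv, cat in df[["snv_id", "category"]].itertuples(index=False):
            mapping.setdefault(str(snv), set()).add(str(cat))
        if universe is None:
            universe = set(mapping)
        return cls(mapping=mapping, universe=set(universe))

    def write_tsv(self, path) -> None:
        rows = [
            (snv, cat)
            for snv in sorted(self.mapping)
            for cat in sorted(self.mapping[snv])
        ]
        pd.DataFrame(rows, columns=["snv_id", "category"]).to_csv(
            path, sep="\t", index=False
        )


def count_category_mappings(snvs, tm: TraitMap) -> dict:
    """Number of query SNVs mapping to each category.

    An SNV carrying several categories counts once in each. Querying an SNV
    outside the universe is an error.
    """
    snvs = set(snvs)
    outside = snvs - tm.universe
    if outside:
        raise KeyError(f"SNVs outside the trait-map universe: {sorted(outside)[:5]}")
    counts = dict.fromkeys(tm.categories, 0)
    for snv in snvs:
        for cat in tm.mapping.get(snv, ()):
            counts[cat] += 1
    return counts


def category_enrichment(
    observed, tm: TraitMap, n_combos: int = 500, seed: int = 0
) -> pd.DataFrame:
    """Category-level enrichment of an observed SNV set vs random sets.

    Draws ``n_combos`` random SNV sets of the observed size (without
    replacement within each set, from the full universe), builds per-
    category ecdfs of random mapping counts, and reports per category:
    observed count, median random count, ES = observed/median,
    p_ecdf = 1 - ecdf(observed), a conservative add-one permutation p,
    BH fdr (on the literal p), and the ES > 1 & fdr < 0.05 significance
    flag. Seeded and reproducible.
    """
    observed = set(observed)
    if n_combos < 10:
        raise ValueError("n_combos must be >= 10")
    if len(observed) > len(tm.universe):
        raise ValueError("observed set larger than universe")
    rng = np.random.default_rng(seed)
    obs_counts = count_category_mappings(observed, tm)
    categories = tm.categories
    universe = sorted(tm.universe)
    rand = np.zeros((n_combos, len(categories)), dtype=int)
    for b in range(n_combos):
        draw = rng.choice(universe, size=len(observed), replace=False)
        counts = count_category_mappings(draw, tm)
        rand[b] = [counts[c] for c in categories]

    rows = []
    for j, cat in enumerate(categories):
        obs = obs_counts[cat]
        rc = rand[:, j]
        median_rand = float(np.median(rc))
        es = obs / median_rand if median_rand > 0 else np.inf
        p_ecdf = 1.0 - (rc <= obs).mean()  # literal 1 - ecdf(observed)
        p_cons = (1 + int((rc >= obs).sum())) / (n_combos + 1)
        rows.append((cat, obs, median_rand, es, p_ecdf, p_cons))
    out = pd.DataFrame(
        rows,
        columns=[
            "category", "observed", "median_random", "es", "p_ecdf", "p_conservative",
        ],
    )
    out["es_undefined"] = ~np.isfinite(out["es"])
    out.attrs["random_counts"] = rand
    out.attrs["categories"] = categories
    # BH needs p in (0,1]; the literal formula can hit 0 — floor for the
    # adjustment only, the reported p_ecdf stays literal
    p_for_fdr = np.clip(out["p_ecdf"].to_numpy(), np.finfo(float).tiny, 1.0)
    out["fdr"] = bh_fdr(p_for_fdr)
    out["significant"] = (out["es"] > 1) & (out["fdr"] < 0.05)
    return out
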