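"""Hypergeometric pathway enrichment of co-expression modules.

Each module is tested against every pathway with the upper-tail
hypergeometric test over the analysis universe (all genes that survived
preprocessing).  P-values are Benjamini-Hochberg adjusted within each
module's family of tested pathways, and significance is carried forward as
the enrichment score -log2(adjusted p).  Pathways with no overlap in a
module get a missing score: the classifier later treats those as missing
features rather than zeros.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .containers import GeneSetCollection
from .coexpress import ModulePartition

SCORE_FLOOR = 1e-300


def hypergeom_enrich(
    module_genes: set[str] | pd.Index,
    genesets: GeneSetCollection,
    universe: set[str] | pd.Index,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of one module against all sets.

    With universe size N, pathway size K (after intersection with the
    universe), module size n and overlap k, the p-value is P(X >= k).
    Returns one row per pathway with overlap counts, p, BH-adjusted p, and
    the -log2 score (missing where the overlap is zero).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    module = set(module_genes)
    if not module <= universe:
        extra = sorted(module - universe)
        raise ValueError(f"module genes outside the universe: {extra[:5]}")
    N, n = len(universe), len(module)
    rows = []
    for name, genes in genesets.sets.items():
        in_universe = genes & universe
        K = len(in_universe)
        k = len(in_universe & module)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {
                "pathway": name,
                "overlap_count": k,
                "module_size": n,
                "pathway_size_in_universe": K,
                "universe_size": N,
                "p_value": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows).set_index("pathway")
    table["p_adjusted"] = bh_adjust(table["p_value"].to_numpy())
    table["score"] = score_transform(table["p_adjusted"])
    table.loc[table["overlap_count"] == 0, "score"] = np.nan
    return table


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def score_transform(p_adjusted: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Enrichment score -log2(adjusted p), floored at 1e-300; missing stays missing."""
    arr = np.asarray(p_adjusted, float)
    with np.errstate(divide="ignore"):
        out = -np.log2(np.maximum(arr, SCORE_FLOOR))
    out = np.where(np.isnan(arr), np.nan, out)
    if isinstance(p_adjusted, pd.Series):
        return pd.Series(out, index=p_adjusted.index, name="score")
    return out


def enrich_modules(
    partition: ModulePartition,
    genesets: GeneSetCollection,
    universe: set[str] | pd.Index,
) -> dict[int, pd.DataFrame]:
    """Run per-module enrichment for every assigned module (module 0 skipped)."""
    return {
        m: hypergeom_enrich(set(partition.members(m)), genesets, universe)
        for m in partition.module_ids
    }


def heatmap_matrix(
    tables: dict[int, pd.DataFrame],
    significance_cutoff: float = 0.01,
) -> pd.DataFrame:
    """Module x pathway score matrix for pathways significant somewhere.

    A pathway is retained if its BH-adjusted p-value is <= the cutoff in at
    least one module; the matrix holds the -log2 scores (NaN where a module
    had no overlap).  This is the numeric backing of the enrichment heatmap.
    """
    if not tables:
        warnings.warn("no enrichment tables; empty heatmap", stacklevel=2)
        return pd.DataFrame()
    modules = sorted(tables)
    pathways = tables[modules[0]].index
    padj = pd.DataFrame({m: tables[m]["p_adjusted"] for m in modules}).T
    scores = pd.DataFrame({m: tables[m]["score"] for m in modules}).T
    keep = padj.columns[(padj <= significance_cutoff).any(axis=0)]
    if len(keep) == 0:
        warnings.warn("no pathway significant at the cutoff", stacklevel=2)
    out = scores.loc[:, keep]
    out.index.name = "module"
    return out
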