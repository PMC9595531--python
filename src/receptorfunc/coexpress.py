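"""Signed weighted co-expression network construction and module detection.

The network is built from biweight midcorrelations, soft-thresholded with a
signed adjacency a_ij = (0.5 * (1 + cor_ij))^beta, converted to topological
overlap, and clustered with average-linkage hierarchical clustering.  Modules
are summarized by eigengenes (first principal components) and gene-to-module
memberships (kME), and modules with highly correlated eigengenes are merged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import ExpressionMatrix

BIWEIGHT_TUNING_CONSTANT = 9.0


# ---------------------------------------------------------------------------
# correlation


def bicor(expr: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    """Biweight midcorrelation between all gene pairs (genes are rows).

    Values near the per-gene median receive Tukey biweight weights
    w = (1 - u^2)^2 with u = (x - med) / (9 * MAD), zero outside |u| < 1,
    which down-weights outlying samples.  Genes whose MAD is zero fall back
    to Pearson for every pair they participate in; constant genes get
    correlation 0 (with a warning) and a unit diagonal.
    """
    vals = expr.values if isinstance(expr, ExpressionMatrix) else expr
    X = vals.to_numpy(float)
    n_genes, n_samples = X.shape
    if n_samples < 4:
        raise ValueError("biweight midcorrelation requires at least 4 samples")
    if np.isnan(X).any():
        raise ValueError("missing values in expression matrix")

    med = np.median(X, axis=1, keepdims=True)
    mad = np.median(np.abs(X - med), axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0)
    constant = sd == 0
    fallback = (mad[:, 0] == 0) & ~constant

    with np.errstate(divide="ignore", invalid="ignore"):
        u = (X - med) / (BIWEIGHT_TUNING_CONSTANT * mad)
    u = np.nan_to_num(u, nan=np.inf)
    w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    xt = (X - med) * w
    norm = np.sqrt((xt**2).sum(axis=1, keepdims=True))
    norm[norm == 0] = 1.0
    B = xt / norm

    # Pearson-normalized rows for the MAD-0 fallback
    Xc = X - X.mean(axis=1, keepdims=True)
    pnorm = np.sqrt((Xc**2).sum(axis=1, keepdims=True))
    pnorm[pnorm == 0] = 1.0
    P = Xc / pnorm

    C = B @ B.T
    if fallback.any():
        rows = np.flatnonzero(fallback)
        C[rows, :] = P[rows] @ P.T
        C[:, rows] = C[rows, :].T
    if constant.any():
        warnings.warn("constant gene(s); correlations set to 0", stacklevel=2)
        rows = np.flatnonzero(constant)
        C[rows, :] = 0.0
        C[:, rows] = 0.0
    np.fill_diagonal(C, 1.0)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    return pd.DataFrame(C, index=vals.index, columns=vals.index)


# ---------------------------------------------------------------------------
# soft thresholding


def signed_adjacency(cor: pd.DataFrame, beta: float) -> pd.DataFrame:
    """Signed soft-threshold adjacency a_ij = (0.5 * (1 + cor_ij))^beta.

    Perfect positive correlation maps to 1, perfect negative to 0, so
    negatively correlated genes end up in distinct modules.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    return (0.5 * (1.0 + cor)) ** beta


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed R^2 and slope of the log-log degree-distribution fit.

    Connectivities are binned into ``n_bins`` equal-width bins; log10 of the
    per-bin frequency is regressed on log10 of the per-bin mean connectivity.
    The returned R^2 is signed by the negated slope, so a decreasing
    (scale-free-like) distribution scores positively.
    """
    k = np.asarray(connectivity, float)
    if np.allclose(k, k[0]):
        raise ValueError("degenerate connectivity: all values equal")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    dk, freq = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        dk.append(k[mask].mean())
        freq.append(mask.mean())
    dk = np.log10(np.maximum(np.asarray(dk), 1e-12))
    freq = np.log10(np.asarray(freq))
    if len(dk) < 3:
        return 0.0, 0.0
    slope, intercept = np.polyfit(dk, freq, 1)
    fitted = slope * dk + intercept
    ss_res = ((freq - fitted) ** 2).sum()
    ss_tot = ((freq - freq.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(-np.sign(slope) * r2), float(slope)


def pick_power(
    cor: pd.DataFrame,
    candidate_powers: list[int] | None = None,
    target_r2: float = 0.8,
    fallback: int = 14,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft-threshold power by the scale-free topology criterion.

    Returns the smallest candidate whose signed scale-free fit R^2 reaches
    ``target_r2``; if none does, returns ``fallback`` (default 14).  The full
    diagnostic table (power, signed R^2, slope, mean/max connectivity) is
    returned alongside.
    """
    if candidate_powers is None:
        candidate_powers = list(range(1, 21))
    if not candidate_powers:
        raise ValueError("candidate_powers must be non-empty")
    rows = []
    for beta in candidate_powers:
        adj = signed_adjacency(cor, beta).to_numpy()
        k = adj.sum(axis=1) - np.diag(adj)
        sr2, slope = scale_free_fit(k)
        rows.append(
            {"power": beta, "signed_r2": sr2, "slope": slope,
             "mean_connectivity": float(k.mean()), "max_connectivity": float(k.max())}
        )
    table = pd.DataFrame(rows)
    if len(candidate_powers) == 1:
        return int(candidate_powers[0]), table
    reaching = table.loc[table["signed_r2"] >= target_r2, "power"]
    if len(reaching):
        return int(reaching.iloc[0]), table
    return int(fallback), table


# ---------------------------------------------------------------------------
# topological overlap


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap TOM_ij comparing the network neighborhoods of i, j.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), where the
    sum runs over u distinct from i and j and k_i excludes the self-edge.
    The diagonal is 1; the dissimilarity used for clustering is 1 - TOM.
    """
    A = adj.to_numpy(float)
    diag = np.diag(A).copy()
    k = A.sum(axis=1) - diag
    L = A @ A
    # remove the u = i and u = j terms from the shared-neighbor sum
    numer = L - diag[:, None] * A - A * diag[None, :] + A
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = numer / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


# ---------------------------------------------------------------------------
# module detection


@dataclass
class ModulePartition:
    """Gene -> module assignment.  Module 0 collects unassigned genes."""

    labels: pd.Series  # gene -> module id (0 = unassigned)
    linkage: np.ndarray | None = None
    cut_height: float | None = None

    @property
    def module_ids(self) -> list[int]:
        return sorted(int(m) for m in self.labels.unique() if m != 0)

    @property
    def sizes(self) -> pd.Series:
        return self.labels[self.labels != 0].value_counts().sort_index()

    def members(self, module: int) -> pd.Index:
        return self.labels.index[self.labels == module]


def _relabel_by_size(raw: pd.Series) -> pd.Series:
    """Relabel modules 1..M by decreasing size; ties by first gene id."""
    out = pd.Series(0, index=raw.index, dtype=int, name="module")
    clusters = []
    for lbl in raw.unique():
        if lbl == 0:
            continue
        members = raw.index[raw == lbl]
        clusters.append((-len(members), min(members), lbl))
    for new_id, (_, _, lbl) in enumerate(sorted(clusters), start=1):
        out[raw == lbl] = new_id
    return out


def detect_modules(
    diss_tom: pd.DataFrame,
    min_module_size: int = 30,
    cut_method: str = "gap",
    cut_height_quantile: float = 0.99,
    gap_search_quantile: float = 0.25,
) -> ModulePartition:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    The default ``cut_method="gap"`` places the cut in the middle of the
    largest gap between consecutive sorted merge heights (searched above the
    ``gap_search_quantile`` of heights), a deterministic stand-in for
    dynamic tree cutting that adapts to where tight branches end and loose
    attachments begin.  ``cut_method="quantile"`` cuts at the
    ``cut_height_quantile`` quantile of merge heights instead.  Clusters
    smaller than ``min_module_size`` are assigned module 0 and the rest are
    relabeled 1..M by decreasing size.
    """
    D = diss_tom.to_numpy(float).copy()
    np.fill_diagonal(D, 0.0)
    condensed = squareform((D + D.T) / 2.0, checks=False)
    Z = linkage(condensed, method="average")
    heights = Z[:, 2]
    if cut_method == "gap":
        h = np.sort(heights)
        upper = h[h >= np.quantile(h, gap_search_quantile)]
        if len(upper) < 2:
            cut = float(h[-1])
        else:
            gaps = np.diff(upper)
            i = int(np.argmax(gaps))
            cut = float((upper[i] + upper[i + 1]) / 2.0)
    elif cut_method == "quantile":
        cut = float(np.quantile(heights, cut_height_quantile))
    else:
        raise ValueError(f"unknown cut_method {cut_method!r}")
    raw = fcluster(Z, t=cut, criterion="distance")
    raw = pd.Series(raw, index=diss_tom.index, name="module")
    sizes = raw.value_counts()
    small = sizes.index[sizes < min_module_size]
    raw[raw.isin(small)] = 0
    labels = _relabel_by_size(raw)
    if (labels == 0).all():
        warnings.warn("no module reached the minimum size; empty partition", stacklevel=2)
    return ModulePartition(labels=labels, linkage=Z, cut_height=cut)


# ---------------------------------------------------------------------------
# eigengenes and membership


@dataclass
class EigengeneMatrix:
    """Module x sample eigengene profiles (unit norm, kME-oriented)."""

    values: pd.DataFrame  # modules x samples
    explained_variance: pd.Series = field(default_factory=pd.Series)


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def compute_eigengenes(
    expr: ExpressionMatrix | pd.DataFrame, partition: ModulePartition
) -> EigengeneMatrix:
    """First principal component of each module's standardized submatrix.

    The eigengene is the first right singular vector over samples, scaled to
    unit norm and sign-oriented so that the mean correlation of the module's
    member genes with it is nonnegative.
    """
    vals = expr.values if isinstance(expr, ExpressionMatrix) else expr
    profiles, evs = {}, {}
    for m in partition.module_ids:
        members = partition.members(m)
        X = _standardize_rows(vals.loc[members].to_numpy(float))
        if X.shape[0] == 1:
            warnings.warn(f"module {m} has a single gene", stacklevel=2)
            v = X[0] / np.linalg.norm(X[0])
            evs[m] = 1.0
        else:
            _, s, vt = np.linalg.svd(X, full_matrices=False)
            v = vt[0]
            evs[m] = float(s[0] ** 2 / (s**2).sum())
        member_cor = _standardize_rows(vals.loc[members].to_numpy(float)) @ v
        if member_cor.mean() < 0:
            v = -v
        profiles[m] = v
    eig = pd.DataFrame(profiles, index=vals.columns).T
    eig.index.name = "module"
    return EigengeneMatrix(values=eig, explained_variance=pd.Series(evs, name="explained_variance"))


def compute_kme(
    expr: ExpressionMatrix | pd.DataFrame, eig: EigengeneMatrix
) -> pd.DataFrame:
    """Correlation of every gene with every module eigengene (gene x module).

    Cross-module entries are kept: they feed the classifier's
    receptor-to-module correlation block.  Zero-variance genes get a zero row.
    """
    vals = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if not vals.columns.equals(eig.values.columns):
        raise ValueError("expression and eigengene sample sets differ")
    X = vals.to_numpy(float)
    sd = X.std(axis=1, ddof=0)
    Zg = _standardize_rows(X)
    Ze = _standardize_rows(eig.values.to_numpy(float))
    n = X.shape[1]
    kme = (Zg @ Ze.T) / n
    if (sd == 0).any():
        warnings.warn("zero-variance gene(s); kME set to 0", stacklevel=2)
        kme[sd == 0, :] = 0.0
    return pd.DataFrame(
        np.clip(kme, -1.0, 1.0), index=vals.index, columns=eig.values.index
    )


def clean_membership(
    expr: ExpressionMatrix | pd.DataFrame,
    partition: ModulePartition,
    min_kme: float = 0.3,
    min_module_size: int = 30,
) -> ModulePartition:
    """Demote weakly connected members to module 0 by own-module kME.

    Genes whose correlation with their own module's eigengene falls below
    ``min_kme`` (conventional minimum module membership 0.3) are reassigned
    to the unassigned module; modules dropping below ``min_module_size``
    afterwards are dissolved.  Labels are re-ranked by size.
    """
    if not partition.module_ids:
        return partition
    eig = compute_eigengenes(expr, partition)
    kme = compute_kme(expr, eig)
    labels = partition.labels.copy()
    for gene, m in partition.labels.items():
        if m != 0 and kme.loc[gene, m] < min_kme:
            labels[gene] = 0
    sizes = labels[labels != 0].value_counts()
    labels[labels.isin(sizes.index[sizes < min_module_size])] = 0
    return ModulePartition(
        labels=_relabel_by_size(labels),
        linkage=partition.linkage,
        cut_height=partition.cut_height,
    )


# ---------------------------------------------------------------------------
# module merging


def merge_modules(
    partition: ModulePartition,
    eig: EigengeneMatrix,
    expr: ExpressionMatrix | pd.DataFrame,
    merge_height: float = 0.25,
    max_iterations: int = 20,
) -> tuple[ModulePartition, EigengeneMatrix]:
    """Merge modules whose eigengenes are closer than ``merge_height``.

    Merge height 0.25 corresponds to an eigengene correlation of 0.75.
    Modules are clustered (average linkage) on 1 - cor(eigengenes); groups
    merging below the height are unioned, eigengenes recomputed, and the
    process repeats until no eigengene pair is closer than the threshold.
    """
    vals = expr.values if isinstance(expr, ExpressionMatrix) else expr
    labels = partition.labels.copy()
    current = eig
    for _ in range(max_iterations):
        ids = sorted(int(m) for m in labels.unique() if m != 0)
        if len(ids) <= 1:
            break
        E = current.values.loc[ids].to_numpy(float)
        C = np.corrcoef(E)
        D = 1.0 - C
        np.fill_diagonal(D, 0.0)
        if (D[np.triu_indices_from(D, k=1)] >= merge_height).all():
            break
        Z = linkage(squareform(np.clip(D, 0, None), checks=False), method="average")
        groups = fcluster(Z, t=merge_height, criterion="distance")
        mapping = {m: g for m, g in zip(ids, groups)}
        merged = labels.map(lambda m: 0 if m == 0 else mapping[m])
        labels = _relabel_by_size(pd.Series(merged, index=labels.index, name="module"))
        part = ModulePartition(labels=labels, linkage=partition.linkage,
                               cut_height=partition.cut_height)
        current = compute_eigengenes(vals, part)
    out = ModulePartition(labels=labels, linkage=partition.linkage,
                          cut_height=partition.cut_height)
    return out, compute_eigengenes(vals, out)
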