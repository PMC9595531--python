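"""Expression preprocessing: filtering, normalization, outlier screening, and
confounder residualization.

Pipeline order (enforced by the stage tag on :class:`ExpressionMatrix`):
death-circumstance sample filter -> TPM gene filter -> log2 transform ->
quantile normalization -> isolation-forest outlier removal -> per-gene OLS
residualization on the known confounders.  The residuals are the input to
co-expression module detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import IsolationForest

from .containers import ExpressionMatrix, validate_metadata

DEFAULT_CONFOUNDERS = ("batch", "sex", "age_bracket", "ischemic_time", "hardy_code")

#: Confounders encoded as one-hot (drop-first); the rest enter numerically.
_CATEGORICAL = ("batch", "sex", "hardy_code")


@dataclass
class ConfounderModel:
    """Per-gene OLS coefficients over a shared confounder design matrix."""

    design: pd.DataFrame  # samples x design columns (incl. intercept)
    coefficients: pd.DataFrame  # genes x design columns


def filter_samples_by_death(
    expr: ExpressionMatrix,
    meta: pd.DataFrame,
    excluded_codes: set[int] = frozenset({4}),
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Drop samples whose death-circumstance (Hardy) code is excluded.

    Code 4 (slow death after a long illness) is excluded by default so the
    cohort reflects reasonably healthy donors at time of death.
    """
    validate_metadata(meta)
    missing = expr.sample_ids.difference(meta.index)
    if len(missing):
        raise KeyError(f"samples missing from metadata: {missing.tolist()[:5]}")
    meta = meta.loc[expr.sample_ids]
    keep = ~meta["hardy_code"].isin(excluded_codes)
    if not keep.any():
        raise ValueError("no samples remain after death-circumstance filtering")
    kept_ids = meta.index[keep]
    return expr.with_values(expr.values.loc[:, kept_ids]), meta.loc[kept_ids]


def filter_genes(
    expr: ExpressionMatrix,
    min_tpm: float = 0.1,
    min_fraction: float = 0.8,
) -> ExpressionMatrix:
    """Keep genes with >= ``min_tpm`` TPM in >= ``min_fraction`` of samples.

    Genes with any missing value or zero variance are dropped as well.
    Both thresholds are inclusive ("at least").
    """
    expr.require_stage("tpm")
    vals = expr.values
    complete = vals.notna().all(axis=1)
    frac = (vals >= min_tpm).sum(axis=1) / vals.shape[1]
    variance = vals.var(axis=1, ddof=0)
    keep = complete & (frac >= min_fraction) & (variance > 0)
    return expr.with_values(vals.loc[keep])


def log2_transform(expr: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Elementwise ``log2(x + pseudocount)`` on TPM values."""
    expr.require_stage("tpm")
    vals = expr.values
    if (vals.to_numpy() < 0).any():
        raise ValueError("negative TPM values")
    shifted = vals + pseudocount
    if (shifted.to_numpy() <= 0).any():
        raise ValueError("log2 of a non-positive value; increase the pseudocount")
    return expr.with_values(np.log2(shifted), stage="log2")


def quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the mean empirical distribution.

    The reference distribution is the across-sample mean of within-sample
    sorted values; tied values within a sample receive the mean of the
    reference values at their tied ranks.
    """
    expr.require_stage("log2", "tpm")
    vals = expr.values
    if vals.isna().any().any():
        raise ValueError("missing values; quantile normalization requires complete data")
    arr = vals.to_numpy(float)
    order = np.sort(arr, axis=0)
    reference = order.mean(axis=1)

    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        ranks = np.argsort(np.argsort(col, kind="stable"), kind="stable")
        assigned = reference[ranks]
        # average the reference over tied ranks
        s = pd.Series(assigned)
        out[:, j] = s.groupby(col, sort=False).transform("mean").to_numpy()
    return expr.with_values(
        pd.DataFrame(out, index=vals.index, columns=vals.columns), stage="qnorm"
    )


def remove_outlier_samples(
    expr: ExpressionMatrix,
    contamination: float = 0.05,
    seed: int = 0,
    n_components: int = 30,
) -> tuple[ExpressionMatrix, pd.Index]:
    """Remove anomalous samples with an isolation forest.

    Samples are projected onto their top principal components (the tree
    ensemble then isolates anomalous points in that reduced space) and the
    ``contamination`` fraction with the most anomalous scores is removed.
    """
    if expr.n_samples < 10:
        raise ValueError("outlier screening requires at least 10 samples")
    if contamination >= 0.5:
        raise ValueError("contamination must be < 0.5")
    if contamination <= 0:
        return expr, pd.Index([], name="sample")
    X = expr.values.to_numpy(float).T  # samples x genes
    k = min(n_components, X.shape[0] - 1, X.shape[1])
    Xr = PCA(n_components=k, random_state=seed).fit_transform(X)
    forest = IsolationForest(contamination=contamination, random_state=seed)
    flags = forest.fit_predict(Xr)
    removed = expr.sample_ids[flags == -1]
    kept = expr.sample_ids[flags == 1]
    return expr.with_values(expr.values.loc[:, kept]), removed


def build_design(meta: pd.DataFrame, confounders: list[str]) -> pd.DataFrame:
    """Shared OLS design: intercept + one-hot (drop-first) categoricals +
    numeric covariates, in a deterministic column order."""
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(meta))}
    for name in confounders:
        if name not in meta.columns:
            raise KeyError(f"confounder {name!r} not present in metadata")
        col = meta[name]
        if name in _CATEGORICAL:
            levels = sorted(pd.unique(col).tolist())
            for level in levels[1:]:  # drop-first
                cols[f"{name}[{level}]"] = (col == level).to_numpy(float)
        else:
            cols[name] = col.to_numpy(float)
    design = pd.DataFrame(cols, index=meta.index)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # name the columns involved in the collinearity via QR
        _, r = np.linalg.qr(design.to_numpy())
        bad = design.columns[np.abs(np.diag(r)) < 1e-10].tolist()
        raise ValueError(f"rank-deficient confounder design; collinear columns: {bad}")
    return design


def residualize(
    expr: ExpressionMatrix,
    meta: pd.DataFrame,
    confounders: list[str] = list(DEFAULT_CONFOUNDERS),
) -> tuple[ExpressionMatrix, ConfounderModel]:
    """Per-gene OLS of expression on the confounder design; keep residuals.

    Every gene is regressed on the same design matrix (with intercept); the
    residual matrix Residual_ij = Exp_ij - fitted_ij replaces the expression
    values for all downstream network analysis.
    """
    meta = meta.loc[expr.sample_ids]
    design = build_design(meta, list(confounders))
    X = design.to_numpy(float)
    Y = expr.values.to_numpy(float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = (Y - X @ beta).T
    model = ConfounderModel(
        design=design,
        coefficients=pd.DataFrame(
            beta.T, index=expr.gene_ids, columns=design.columns
        ),
    )
    out = expr.with_values(
        pd.DataFrame(resid, index=expr.gene_ids, columns=expr.sample_ids),
        stage="residual",
    )
    return out, model


def preprocess_pipeline(
    expr: ExpressionMatrix,
    meta: pd.DataFrame,
    excluded_codes: set[int] = frozenset({4}),
    min_tpm: float = 0.1,
    min_fraction: float = 0.8,
    pseudocount: float = 1.0,
    contamination: float = 0.05,
    confounders: list[str] = list(DEFAULT_CONFOUNDERS),
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.Index, ConfounderModel]:
    """Run the full preprocessing chain in the canonical order.

    Returns the residual matrix, the aligned metadata, the removed-sample
    index, and the fitted confounder model.
    """
    expr, meta = filter_samples_by_death(expr, meta, excluded_codes)
    expr = filter_genes(expr, min_tpm=min_tpm, min_fraction=min_fraction)
    expr = log2_transform(expr, pseudocount=pseudocount)
    expr = quantile_normalize(expr)
    expr, removed = remove_outlier_samples(expr, contamination=contamination, seed=seed)
    meta = meta.loc[expr.sample_ids]
    resid, model = residualize(expr, meta, confounders)
    return resid, meta, removed, model
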