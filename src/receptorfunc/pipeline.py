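"""End-to-end pipeline driver: preprocessing through prediction.

A single global seed fans out to per-stage seeds by stable hashing, so any
stage can be re-run individually and reproduce its part of a full run.  The
driver writes every stage artifact as TSV/JSON and a manifest with parameter
values, stage seeds, key counts, and a checksum of every artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as _classify
from . import coexpress as _coexpress
from . import enrich as _enrich
from . import explain as _explain
from . import features as _features
from . import io as _io
from . import preprocess as _preprocess
from . import pu as _pu
from .containers import ExpressionMatrix, GeneSetCollection


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed (< 2^31)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """All stage parameters, with the published defaults.

    Paths are optional: the in-memory entry point
    :func:`run_tissue` takes objects directly.
    """

    # inputs
    expression_path: str | None = None
    metadata_path: str | None = None
    genesets_path: str | None = None
    receptors_path: str | None = None
    metabolic_path: str | None = None
    inflammatory_path: str | None = None
    exclusion_path: str | None = None
    output_dir: str = "results"
    # preprocessing
    excluded_death_codes: tuple[int, ...] = (4,)
    min_tpm: float = 0.1
    min_fraction: float = 0.8
    pseudocount: float = 1.0
    contamination: float = 0.05
    confounders: tuple[str, ...] = _preprocess.DEFAULT_CONFOUNDERS
    # network
    power: int | str = "auto"  # "auto" or a fixed integer (e.g. 14)
    target_r2: float = 0.8
    fallback_power: int = 14
    min_module_size: int = 30
    cut_method: str = "gap"
    cut_height_quantile: float = 0.99
    min_kme: float = 0.3
    merge_height: float = 0.25
    # enrichment
    significance_cutoff: float = 0.01
    # labeling
    pu_iterations: int = 100
    pu_k: int = 50
    pu_feature_space: str = "expression"  # or "receptor-features"
    # classification
    n_folds: int = 10
    models: tuple[str, ...] = ("gbt", "linear-svm", "knn")
    grid: str = "quick"  # "quick" or "full"
    # prediction
    cutoff: float = 0.85
    switch_diff: float = 0.85
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class TissueResult:
    """All in-memory artifacts of one tissue run."""

    residuals: ExpressionMatrix
    metadata: pd.DataFrame
    removed_samples: pd.Index
    power: int
    power_table: pd.DataFrame
    partition: _coexpress.ModulePartition
    eigengenes: _coexpress.EigengeneMatrix
    kme: pd.DataFrame
    enrichment: dict[int, pd.DataFrame]
    heatmap: pd.DataFrame
    features: pd.DataFrame
    drop_report: pd.DataFrame
    oob_scores: pd.DataFrame
    labels: pd.DataFrame
    cv_results: dict[str, _classify.CVResult]
    best_family: str
    final_model: _classify.FittedModel
    train_probabilities: pd.DataFrame
    attribution: _explain.AttributionTable | None
    predictions: pd.DataFrame
    counts: dict = field(default_factory=dict)


def run_tissue(
    expr: ExpressionMatrix,
    meta: pd.DataFrame,
    genesets: GeneSetCollection,
    catalog: pd.Index,
    metabolic: list[str],
    inflammatory: list[str],
    exclusion: list[str],
    config: PipelineConfig | None = None,
) -> TissueResult:
    """Run preprocessing -> network -> enrichment -> features -> labeling ->
    classification -> explanation -> prediction for one tissue."""
    cfg = config or PipelineConfig()

    # --- preprocessing
    resid, meta2, removed, _model = _preprocess.preprocess_pipeline(
        expr,
        meta,
        excluded_codes=set(cfg.excluded_death_codes),
        min_tpm=cfg.min_tpm,
        min_fraction=cfg.min_fraction,
        pseudocount=cfg.pseudocount,
        contamination=cfg.contamination,
        confounders=list(cfg.confounders),
        seed=stage_seed(cfg.seed, "outliers"),
    )

    # --- network and modules
    cor = _coexpress.bicor(resid)
    if cfg.power == "auto":
        power, power_table = _coexpress.pick_power(
            cor, target_r2=cfg.target_r2, fallback=cfg.fallback_power
        )
    else:
        power = int(cfg.power)
        power_table = pd.DataFrame({"power": [power]})
    adj = _coexpress.signed_adjacency(cor, power)
    tom = _coexpress.tom_similarity(adj)
    partition = _coexpress.detect_modules(
        1.0 - tom,
        min_module_size=cfg.min_module_size,
        cut_method=cfg.cut_method,
        cut_height_quantile=cfg.cut_height_quantile,
    )
    partition = _coexpress.clean_membership(
        resid, partition, min_kme=cfg.min_kme, min_module_size=cfg.min_module_size
    )
    eig = _coexpress.compute_eigengenes(resid, partition)
    partition, eig = _coexpress.merge_modules(
        partition, eig, resid, merge_height=cfg.merge_height
    )
    kme = _coexpress.compute_kme(resid, eig)

    # --- enrichment
    universe = set(resid.gene_ids)
    enrichment = _enrich.enrich_modules(partition, genesets.restrict(universe), universe)
    heatmap = _enrich.heatmap_matrix(enrichment, cfg.significance_cutoff)

    # --- features
    eig_cor = _features.eigengene_correlation_matrix(eig)
    feats, drop_report = _features.build_feature_matrix(
        catalog, partition, enrichment, eig_cor, kme
    )

    # --- labeling (PU for the "other" class)
    met_set, inf_set = _pu.assemble_positive_lists(
        metabolic, inflammatory, exclusion, pd.Index(feats.index)
    )
    if cfg.pu_feature_space == "expression":
        pu_space = resid.values.loc[resid.gene_ids.intersection(feats.index)]
    elif cfg.pu_feature_space == "receptor-features":
        pu_space = feats
    else:
        raise ValueError(f"unknown pu_feature_space {cfg.pu_feature_space!r}")
    other_set, oob_scores = _pu.derive_other_class(
        pu_space, met_set, inf_set,
        T=cfg.pu_iterations, K=cfg.pu_k, seed=stage_seed(cfg.seed, "pu"),
    )
    labels = _pu.assemble_labels(met_set, inf_set, other_set, pd.Index(feats.index))
    labeled = labels.loc[labels["label"] != "unlabeled", "label"]

    # --- classification
    grids = _classify.QUICK_GRIDS if cfg.grid == "quick" else _classify.DEFAULT_GRIDS
    folds = _classify.stratified_folds(labeled.loc[feats.index.intersection(labeled.index)],
                                       n_folds=cfg.n_folds)
    cv_results = {}
    for family in cfg.models:
        spec = _classify.ClassifierSpec(
            family=family, grid=grids[family], seed=stage_seed(cfg.seed, f"cv-{family}")
        )
        cv_results[family] = _classify.train_eval(feats, labeled, spec, folds=folds)
    best_family = max(
        cv_results,
        key=lambda f: (cv_results[f].fold_metrics["accuracy"].mean(), f == "gbt", f),
    )
    best = cv_results[best_family]
    final_spec = _classify.ClassifierSpec(
        family=best_family, grid=grids[best_family],
        seed=stage_seed(cfg.seed, f"final-{best_family}"),
    )
    final_model, train_probs = _classify.fit_final(
        feats, labeled, final_spec, best.best_params
    )

    # --- explanation (always on the tree model: the exact Shapley method
    # requires accessible tree structure)
    attribution = None
    if "gbt" in cv_results:
        if best_family == "gbt":
            tree_model = final_model
        else:
            tree_spec = _classify.ClassifierSpec(
                family="gbt", grid=grids["gbt"],
                seed=stage_seed(cfg.seed, "final-gbt"),
            )
            tree_model, _ = _classify.fit_final(
                feats, labeled, tree_spec, cv_results["gbt"].best_params
            )
        labeled_feats = feats.loc[labeled.index.intersection(feats.index)]
        attribution = _explain.shap_attribution(tree_model, labeled_feats)

    # --- prediction of unlabeled receptors
    unlabeled = feats.index.difference(labeled.index)
    predictions = _explain.predict_unlabeled(
        final_model, feats.loc[unlabeled], cutoff=cfg.cutoff
    )

    counts = {
        "n_samples_input": expr.n_samples,
        "n_genes_input": expr.n_genes,
        "n_samples_kept": resid.n_samples,
        "n_genes_kept": resid.n_genes,
        "n_outliers_removed": len(removed),
        "power": power,
        "n_modules": len(partition.module_ids),
        "n_receptors_in_modules": len(feats),
        "n_labeled": int(len(labeled)),
        "label_counts": labeled.value_counts().to_dict(),
        "best_family": best_family,
        "cv_accuracy": {f: float(r.fold_metrics["accuracy"].mean()) for f, r in cv_results.items()},
        "n_unlabeled_predicted": int(len(predictions)),
        "n_pass_cutoff": int(predictions["passes_cutoff"].sum()),
    }
    return TissueResult(
        residuals=resid, metadata=meta2, removed_samples=removed,
        power=power, power_table=power_table, partition=partition,
        eigengenes=eig, kme=kme, enrichment=enrichment, heatmap=heatmap,
        features=feats, drop_report=drop_report, oob_scores=oob_scores,
        labels=labels, cv_results=cv_results, best_family=best_family,
        final_model=final_model, train_probabilities=train_probs,
        attribution=attribution, predictions=predictions, counts=counts,
    )


# ---------------------------------------------------------------------------
# artifact writing and manifest


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_tissue_artifacts(result: TissueResult, outdir: str | Path, tag: str = "") -> dict[str, str]:
    """Write every stage artifact as TSV/JSON; returns path -> checksum."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prefix = f"{tag}_" if tag else ""

    def _p(name: str) -> Path:
        return outdir / f"{prefix}{name}"

    _io.write_table(result.residuals.values, _p("residuals.tsv"))
    _io.write_table(
        pd.DataFrame({"sample": result.removed_samples}), _p("removed_samples.tsv"), index=False
    )
    _io.write_table(result.power_table, _p("power_diagnostics.tsv"), index=False)
    _io.write_table(result.partition.labels.to_frame(), _p("module_assignment.tsv"))
    _io.write_table(result.eigengenes.values, _p("eigengenes.tsv"))
    _io.write_table(result.kme, _p("kme.tsv"))
    long = pd.concat(
        [t.assign(module=m) for m, t in result.enrichment.items()]
    ).reset_index().set_index(["module", "pathway"])
    _io.write_table(long, _p("enrichment.tsv"))
    _io.write_table(result.heatmap, _p("enrichment_heatmap.tsv"))
    _io.write_table(result.features, _p("features.tsv"))
    _p("features.schema.json").write_text(
        json.dumps(_features.feature_schema(result.features), indent=2)
    )
    _io.write_table(result.drop_report, _p("dropped_receptors.tsv"))
    _io.write_table(result.oob_scores, _p("pu_oob_scores.tsv"))
    _io.write_table(result.labels, _p("labels.tsv"))
    metrics_rows = []
    for family, cv in result.cv_results.items():
        row = {"family": family, **{f"mean_{k}": v for k, v in cv.mean_metrics.items()},
               **{f"sd_{k}": v for k, v in cv.std_metrics.items()}}
        metrics_rows.append(row)
    _io.write_table(pd.DataFrame(metrics_rows).set_index("family"), _p("cv_metrics.tsv"))
    best = result.cv_results[result.best_family]
    _io.write_table(best.misclassification_report(), _p("misclassified.tsv"))
    _io.write_table(best.oof_predictions, _p("oof_predictions.tsv"))
    if result.attribution is not None:
        _io.write_table(result.attribution.global_importance(), _p("shap_importance.tsv"))
        _io.write_table(result.attribution.top_features(n=10), _p("shap_top10.tsv"))
    _io.write_table(result.predictions, _p("predictions.tsv"))

    checksums = {}
    for path in sorted(outdir.glob(f"{prefix}*")):
        if path.is_file():
            checksums[path.name] = _checksum(path)
    return checksums


def run_pipeline(config: PipelineConfig) -> dict:
    """File-based entry point: read inputs, run one tissue, write artifacts
    and a manifest.  Returns the manifest dictionary."""
    for name in ("expression_path", "metadata_path", "genesets_path",
                 "receptors_path", "metabolic_path", "inflammatory_path"):
        if getattr(config, name) is None:
            raise ValueError(f"pipeline config missing {name}")
    expr = _io.read_expression(config.expression_path)
    meta = _io.read_metadata(config.metadata_path)
    genesets = _io.read_gmt(config.genesets_path)
    catalog = pd.Index(_pu.read_gene_list(config.receptors_path), name="receptor")
    metabolic = _pu.read_gene_list(config.metabolic_path)
    inflammatory = _pu.read_gene_list(config.inflammatory_path)
    exclusion = (
        _pu.read_gene_list(config.exclusion_path) if config.exclusion_path else []
    )
    result = run_tissue(expr, meta, genesets, catalog, metabolic, inflammatory,
                        exclusion, config)
    outdir = Path(config.output_dir)
    checksums = write_tissue_artifacts(result, outdir)
    manifest = {
        "parameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "stage_seeds": {
            s: stage_seed(config.seed, s)
            for s in ("outliers", "pu", "cv-gbt", "cv-linear-svm", "cv-knn")
        },
        "counts": result.counts,
        "artifacts": checksums,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
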