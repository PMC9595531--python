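"""receptorfunc: tissue-specific receptor function classification from bulk
expression data.

The pipeline detects signed weighted co-expression modules, annotates them
with hypergeometric pathway enrichment, builds per-receptor feature vectors
from the enrichment scores and eigengene correlations, derives the "other"
class by positive-unlabeled SVM bagging, trains multi-class classifiers
under stratified cross-validation, explains the tree model with exact
Shapley attributions, and predicts unlabeled receptors at a probability
cutoff — optionally comparing predictions between two tissues.
"""

from .containers import CLASS_ORDER, ExpressionMatrix, GeneSetCollection
from .coexpress import (
    EigengeneMatrix,
    ModulePartition,
    bicor,
    compute_eigengenes,
    compute_kme,
    detect_modules,
    merge_modules,
    pick_power,
    signed_adjacency,
    tom_similarity,
)
from .classify import (
    ClassifierSpec,
    CVResult,
    FittedModel,
    compute_metrics,
    fit_final,
    stratified_folds,
    train_eval,
)
from .enrich import bh_adjust, enrich_modules, heatmap_matrix, hypergeom_enrich, score_transform
from .explain import (
    AttributionTable,
    cross_tissue_compare,
    predict_unlabeled,
    shap_attribution,
)
from .features import build_feature_matrix, eigengene_correlation_matrix
from .pipeline import PipelineConfig, TissueResult, run_pipeline, run_tissue, stage_seed
from .preprocess import (
    filter_genes,
    filter_samples_by_death,
    log2_transform,
    preprocess_pipeline,
    quantile_normalize,
    remove_outlier_samples,
    residualize,
)
from .pu import (
    assemble_labels,
    assemble_positive_lists,
    derive_other_class,
    pu_bagging,
    select_other,
)
from .synthetic import GroundTruth, SyntheticConfig, generate_dataset, separable_pu_problem

__version__ = "0.1.0"

__all__ = [name for name in dir() if not name.startswith("_")]
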