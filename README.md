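# receptorfunc

Classifying the tissue-specific functions of receptor genes — "metabolic",
"inflammatory", or "other" — from bulk gene-expression data.

Receptors relay signals from circulating ligands (hormones, cytokines) into
cells, and the same receptor can serve different roles in different tissues.
`receptorfunc` infers those roles from co-expression: receptors embedded in
gene modules enriched for metabolic pathways tend to carry metabolic
functions, and likewise for immune signaling. The package is aimed at
computational biologists who have a genes × samples TPM matrix, per-sample
covariates, a pathway collection (GMT), and curated positive lists of
metabolic and inflammatory receptors — and who want per-receptor class
probabilities plus the pathway features that drive them.

## The method

1. **Preprocessing.** Samples with death-circumstance (Hardy) code 4 are
   removed; genes are kept when TPM ≥ 0.1 in ≥ 80 % of samples; values are
   log2(TPM+1) transformed and quantile normalized; anomalous samples are
   removed with an isolation forest; each gene is residualized by OLS on the
   known confounders (batch, sex, age bracket, ischemic time, Hardy code):
   `Residual_ij = Exp_ij − Σ_n Coef_in · Confounder_nj`.
2. **Co-expression network.** Biweight midcorrelation between all genes,
   signed soft-threshold adjacency `a_ij = (0.5 · (1 + cor_ij))^β` (β chosen
   by the scale-free-topology criterion, falling back to 14), topological
   overlap (TOM), average-linkage clustering of 1 − TOM, static tree cut,
   kME membership cleanup, and merging of modules whose eigengenes
   (first principal components) correlate above 0.75.
3. **Pathway enrichment.** Per module, an upper-tail hypergeometric test for
   every gene set over the expressed-gene universe, Benjamini–Hochberg
   adjustment, and the enrichment score −log2(adjusted p). Pathways with no
   overlap carry *missing* scores.
4. **Feature space.** A receptor inherits its module's pathway-score vector,
   the module's eigengene correlations with every module, and its own kME
   to every eigengene.
5. **Labels.** Metabolic and inflammatory positives come from curated lists;
   the "other" class is inferred by positive-unlabeled bagging: linear SVMs
   trained repeatedly on positives vs. bootstrap draws of unlabeled
   receptors, out-of-bag decision values averaged, and the 50 lowest-scoring
   receptors retained.
6. **Classification.** XGBoost (native missing-value routing), linear SVM,
   and k-NN under non-shuffled stratified 10-fold cross-validation with a
   hyperparameter grid; metrics (accuracy, precision, recall, F1) follow
   one-vs-rest confusion counts, averaged over classes.
7. **Explanation and prediction.** Exact float64 tree-Shapley attributions
   for the boosted model (local accuracy holds to machine precision);
   unlabeled receptors classified with a strict probability cutoff of 0.85;
   predictions from two tissues compared for consistent or switching
   functions.

No external data are required: `receptorfunc.synthetic` generates TPM panels
with planted modules, confounders, outlier samples, pathway gene sets, and
receptor classes, so the entire pipeline is testable offline.

## Worked example

```python
import warnings; warnings.simplefilter("ignore")
from receptorfunc import SyntheticConfig, generate_dataset, run_tissue, PipelineConfig

cfg = SyntheticConfig(seed=7)          # 8 modules x 200 genes, 200 samples
expr, meta, genesets, catalog, labels, truth = generate_dataset(cfg)
metabolic = labels.index[labels["label"] == "metabolic"].tolist()
inflammatory = labels.index[labels["label"] == "inflammatory"].tolist()

result = run_tissue(expr, meta, genesets, catalog, metabolic, inflammatory, [],
                    PipelineConfig(seed=11))

c = result.counts
print(f"genes kept          : {c['n_genes_kept']} / {c['n_genes_input']}")
print(f"samples kept        : {c['n_samples_kept']} / {c['n_samples_input']}")
print(f"modules detected    : {c['n_modules']} (soft power {c['power']})")
print(f"label counts        : {c['label_counts']}")
print(f"CV mean accuracy    : " + ", ".join(f"{k}={v:.3f}" for k, v in c['cv_accuracy'].items()))
print(f"top metabolic SHAP  : {result.attribution.top_features('metabolic', n=1).index[0]}")
preds = result.predictions
print(f"unlabeled predicted : {len(preds)}, passing 0.85 cutoff: {int(preds['passes_cutoff'].sum())}")
```

Output:

```
genes kept          : 4000 / 4100
samples kept        : 167 / 200
modules detected    : 8 (soft power 14)
label counts        : {'metabolic': 50, 'inflammatory': 50, 'other': 50}
CV mean accuracy    : gbt=0.964, linear-svm=0.964, knn=0.960
top metabolic SHAP  : pw:PW01_Metabolism
unlabeled predicted : 150, passing 0.85 cutoff: 143
```

Reading this: the 100 low-expression decoy genes were filtered out; Hardy-4
donors and isolation-forest outliers reduced 200 samples to 167. All eight
planted modules were recovered, the PU step assembled a balanced 50/50/50
training set, all three classifiers exceed 0.95 mean cross-validated
accuracy, the single most important feature for calling a receptor
"metabolic" is a pathway planted into the metabolic modules, and 143 of the
150 held-out receptors are classified above the 0.85 probability cutoff.

## Command line

Every stage is exposed as a subcommand over TSV/GCT/GMT artifacts:

```sh
receptorfunc simulate --out data/ --seed 7
receptorfunc run-all --expr data/expression.tsv --meta data/metadata.tsv \
    --gmt data/pathways.gmt --receptors data/receptors.txt \
    --metabolic data/metabolic_positives.txt \
    --inflammatory data/inflammatory_positives.txt \
    --out results/ --seed 11
```

`run-all` writes every intermediate table (residuals, module assignment,
eigengenes, kME, enrichment, features, PU scores, labels, CV metrics,
misclassification report, Shapley importances, predictions) plus a
`manifest.json` with parameters, stage seeds, and artifact checksums. Stage
commands (`preprocess`, `modules`, `enrich`, `features`, `label`, `train`,
`explain`, `predict`, `compare`) run any part in isolation.

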