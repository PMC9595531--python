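"""Synthetic bulk-expression data with planted co-expression structure.

The generator emulates the statistical shape of a bulk RNA-seq tissue panel
(TPM units, hundreds of samples, known confounders) together with the ground
truth the downstream stages are supposed to recover:

* correlated gene modules built from latent per-module sample factors, so the
  module eigengene (first principal component) has a well-defined target;
* receptor genes planted inside class-specific modules ("metabolic",
  "inflammatory", "other");
* pathway gene sets concentrated in the modules of their class, with a single
  "home" module holding the plurality of each pathway's genes;
* linear confounder effects (batch, sex, age bracket, ischemic time, death
  circumstance) and globally shifted outlier samples;
* low-expression decoy genes that the TPM filter should remove.

Everything is drawn from one seeded generator, so identical configs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CLASS_ORDER, ExpressionMatrix, GeneSetCollection


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of the planted-structure generator.

    Defaults give 8 modules of 200 genes over 200 samples at within-module
    correlation 0.6, 40 pathways, and 100 planted receptors per class of
    which half are held out unlabeled.
    """

    n_samples: int = 200
    n_modules: int = 8
    genes_per_module: int = 200
    n_background_genes: int = 2400
    within_module_cor: float = 0.6
    n_pathways: int = 40
    pathway_module_affinity: float = 0.8
    n_receptors_per_class: int = 100
    confounder_effect_size: float = 0.15
    outlier_fraction: float = 0.05
    seed: int = 0
    # secondary knobs
    unlabeled_fraction: float = 0.5
    pathway_size: int = 40
    n_low_expression_genes: int = 100
    class_factor_cor: float = 0.3

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_modules", "genes_per_module", "n_pathways",
                     "n_receptors_per_class", "pathway_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.within_module_cor < 1.0:
            raise ValueError("within_module_cor must be in (0, 1)")
        if not 0.0 <= self.outlier_fraction < 0.5:
            raise ValueError("outlier_fraction must be in [0, 0.5)")
        if not 0.0 <= self.unlabeled_fraction < 1.0:
            raise ValueError("unlabeled_fraction must be in [0, 1)")
        if not 0.0 < self.pathway_module_affinity <= 1.0:
            raise ValueError("pathway_module_affinity must be in (0, 1]")


@dataclass
class GroundTruth:
    """Planted truth for a generated dataset.

    ``gene_module`` maps every gene to its planted module id (0 = background),
    ``module_factors`` holds the latent per-module sample profiles, and the
    receptor/pathway tables record planted classes and home modules.
    """

    gene_module: pd.Series
    module_factors: pd.DataFrame  # modules x samples
    receptor_class: pd.Series  # receptor gene -> class
    labeled_receptors: pd.Index
    unlabeled_receptors: pd.Index
    pathway_module: pd.Series  # pathway -> home module id
    pathway_class: pd.Series  # pathway -> class
    module_class: pd.Series  # module id -> class
    outlier_samples: pd.Index
    low_expression_genes: pd.Index = field(default_factory=lambda: pd.Index([]))


def _module_classes(n_modules: int) -> pd.Series:
    """Split module ids 1..M into three near-equal class groups."""
    ids = np.arange(1, n_modules + 1)
    groups = np.array_split(ids, min(3, n_modules))
    labels = {}
    for cls, grp in zip(CLASS_ORDER, groups):
        for m in grp:
            labels[int(m)] = cls
    # fewer than 3 modules: reuse the last class for the leftover labels
    for m in ids:
        labels.setdefault(int(m), CLASS_ORDER[-1])
    return pd.Series(labels, name="class")


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, GeneSetCollection, pd.Index, pd.DataFrame, GroundTruth]:
    """Generate one synthetic tissue dataset.

    Returns
    -------
    expr
        TPM-scale :class:`ExpressionMatrix` (nonnegative, finite).
    meta
        Per-sample metadata (batch, ischemic_time, sex, age_bracket, hardy_code).
    genesets
        Pathway collection with class category labels.
    catalog
        Receptor catalog (index of receptor gene ids).
    labels
        DataFrame (receptor, label, provenance) holding the given-positive
        metabolic/inflammatory lists; all other receptors are "unlabeled".
    truth
        :class:`GroundTruth` with every planted assignment.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    n_module_genes = cfg.n_modules * cfg.genes_per_module
    n_genes = n_module_genes + cfg.n_background_genes
    class_of_module = _module_classes(cfg.n_modules)

    # receptors live inside modules of their class; check capacity first
    genes_per_class = {
        cls: cfg.genes_per_module * int((class_of_module == cls).sum())
        for cls in CLASS_ORDER
    }
    for cls in CLASS_ORDER:
        if cfg.n_receptors_per_class > genes_per_class[cls]:
            raise ValueError(
                f"config asks for {cfg.n_receptors_per_class} {cls} receptors but the "
                f"{cls} modules only contain {genes_per_class[cls]} genes"
            )
    if cfg.pathway_size > n_genes:
        raise ValueError(
            f"pathway_size {cfg.pathway_size} exceeds the {n_genes} available genes"
        )

    width = len(str(n_genes + cfg.n_low_expression_genes))
    gene_ids = pd.Index(
        [f"G{i:0{width}d}" for i in range(1, n_genes + 1)], name="gene"
    )
    sample_ids = pd.Index(
        [f"S{j:04d}" for j in range(1, cfg.n_samples + 1)], name="sample"
    )

    gene_module = np.zeros(n_genes, dtype=int)
    for m in range(cfg.n_modules):
        gene_module[m * cfg.genes_per_module:(m + 1) * cfg.genes_per_module] = m + 1

    # per-sample metadata (drawn first: the confounder variance share enters
    # the signal/noise budget below)
    meta = pd.DataFrame(
        {
            "batch": rng.choice(["B1", "B2", "B3"], size=cfg.n_samples),
            "ischemic_time": rng.uniform(60.0, 1200.0, size=cfg.n_samples).round(1),
            "sex": rng.choice(["F", "M"], size=cfg.n_samples),
            "age_bracket": rng.choice([20, 30, 40, 50, 60, 70], size=cfg.n_samples),
            "hardy_code": rng.choice(
                [0, 1, 2, 3, 4], size=cfg.n_samples, p=[0.2, 0.2, 0.25, 0.2, 0.15]
            ),
        },
        index=sample_ids,
    )
    design_cols = []
    for level in ("B1", "B2", "B3"):
        design_cols.append((meta["batch"] == level).to_numpy(float))
    design_cols.append((meta["sex"] == "M").to_numpy(float))
    for code in range(5):
        design_cols.append((meta["hardy_code"] == code).to_numpy(float))
    age = meta["age_bracket"].to_numpy(float)
    design_cols.append((age - age.mean()) / age.std())
    isch = meta["ischemic_time"].to_numpy(float)
    design_cols.append((isch - isch.mean()) / isch.std())
    Z = np.column_stack(design_cols)
    Z = Z - Z.mean(axis=0)  # centered so effects do not move the global mean
    # expected per-gene variance added by the confounder effects
    conf_var = cfg.confounder_effect_size**2 * Z.var(axis=0, ddof=0).sum()

    # latent factors (standardized over samples so the planted correlation is
    # calibrated, not just its expectation) and log-scale signal:
    # x_i = w e_m + s eps with w^2/(w^2 + s^2 + conf_var) = within_module_cor
    factors = rng.standard_normal((cfg.n_modules, cfg.n_samples))
    # immunometabolic coupling: metabolic and inflammatory module factors share
    # a common component (their modules co-activate, as in adipose tissue),
    # while "other" modules stay independent of both
    if cfg.class_factor_cor > 0:
        shared = rng.standard_normal(cfg.n_samples)
        c = cfg.class_factor_cor
        for m in range(1, cfg.n_modules + 1):
            if class_of_module[m] in ("metabolic", "inflammatory"):
                factors[m - 1] = np.sqrt(c) * shared + np.sqrt(1 - c) * factors[m - 1]
    factors = (factors - factors.mean(axis=1, keepdims=True)) / factors.std(
        axis=1, keepdims=True
    )
    rho = cfg.within_module_cor
    w2 = rho * (1.0 + conf_var)
    s2 = (1.0 - rho) - rho * conf_var
    if s2 <= 0:
        raise ValueError(
            "confounder_effect_size too large for the requested within_module_cor"
        )
    signal = np.sqrt(s2) * rng.standard_normal((n_genes, cfg.n_samples))
    for m in range(1, cfg.n_modules + 1):
        rows = gene_module == m
        signal[rows] += np.sqrt(w2) * factors[m - 1]
    # background genes keep unit total variance
    signal[gene_module == 0] *= 1.0 / np.sqrt(s2)

    base_mean = rng.uniform(2.0, 6.0, size=n_genes)
    log2_expr = base_mean[:, None] + signal

    # linear confounder effects on the log2 scale
    if cfg.confounder_effect_size > 0:
        coef = rng.normal(0.0, cfg.confounder_effect_size, size=(n_genes, Z.shape[1]))
        log2_expr = log2_expr + coef @ Z.T

    # planted outlier samples: a global shift, drawn among samples that will
    # survive the death-circumstance filter
    n_outliers = int(round(cfg.outlier_fraction * cfg.n_samples))
    eligible = np.flatnonzero(meta["hardy_code"].to_numpy() != 4)
    outlier_pos = (
        rng.choice(eligible, size=n_outliers, replace=False)
        if n_outliers > 0
        else np.array([], dtype=int)
    )
    # sample-wide upward shift with per-gene, per-sample susceptibility:
    # still a global shift, but rank-perturbing so it survives quantile
    # normalization, and sample-specific so each outlier is individually
    # separable
    if n_outliers:
        susceptibility = rng.uniform(0.25, 1.75, size=(n_genes, n_outliers))
        log2_expr[:, outlier_pos] += 4.0 * susceptibility

    tpm = np.exp2(log2_expr)

    # low-expression decoys for the 0.1-TPM/80% filter
    if cfg.n_low_expression_genes > 0:
        decoy_ids = pd.Index(
            [f"LOW{i:0{width}d}" for i in range(1, cfg.n_low_expression_genes + 1)],
            name="gene",
        )
        decoy = np.exp2(
            np.log2(0.03) + 0.5 * rng.standard_normal((cfg.n_low_expression_genes, cfg.n_samples))
        )
        tpm = np.vstack([tpm, decoy])
        all_gene_ids = gene_ids.append(decoy_ids)
        gene_module = np.concatenate([gene_module, np.zeros(cfg.n_low_expression_genes, int)])
    else:
        decoy_ids = pd.Index([], name="gene")
        all_gene_ids = gene_ids

    expr = ExpressionMatrix(
        values=pd.DataFrame(tpm, index=all_gene_ids, columns=sample_ids),
        stage="tpm",
    )

    # receptors: planted inside modules of their class, spread round-robin
    receptor_rows: list[tuple[str, str]] = []
    for cls in CLASS_ORDER:
        class_modules = class_of_module.index[class_of_module == cls].to_numpy()
        pool = np.flatnonzero(np.isin(gene_module[:n_genes], class_modules))
        chosen = rng.choice(pool, size=cfg.n_receptors_per_class, replace=False)
        for idx in chosen:
            receptor_rows.append((gene_ids[idx], cls))
    receptor_class = pd.Series(
        {gene: cls for gene, cls in receptor_rows}, name="class"
    ).sort_index()
    catalog = pd.Index(receptor_class.index, name="receptor")

    # hold out a fraction of each class as unlabeled
    labeled, unlabeled = [], []
    for cls in CLASS_ORDER:
        members = receptor_class.index[receptor_class == cls].to_numpy()
        n_unlab = int(round(cfg.unlabeled_fraction * len(members)))
        unlab = rng.choice(members, size=n_unlab, replace=False)
        unlab_set = set(unlab)
        unlabeled.extend(sorted(unlab_set))
        labeled.extend(g for g in members if g not in unlab_set)
    labeled_idx = pd.Index(sorted(labeled), name="receptor")
    unlabeled_idx = pd.Index(sorted(unlabeled), name="receptor")

    label_rows = []
    for gene in catalog:
        if gene in set(labeled_idx) and receptor_class[gene] in ("metabolic", "inflammatory"):
            label_rows.append((gene, receptor_class[gene], "given-positive"))
        else:
            label_rows.append((gene, "unlabeled", "held-out" if gene in set(unlabeled_idx) else "unlisted"))
    labels = pd.DataFrame(label_rows, columns=["receptor", "label", "provenance"]).set_index("receptor")

    # pathways: home module round-robin; the affinity share of genes comes from
    # the home class's modules with the plurality in the home module itself
    pw_width = len(str(cfg.n_pathways))
    sets: dict[str, frozenset[str]] = {}
    categories: dict[str, str] = {}
    pathway_module: dict[str, int] = {}
    pathway_cls: dict[str, str] = {}
    category_name = {"metabolic": "Metabolism", "inflammatory": "Immune", "other": "Other"}
    for p in range(cfg.n_pathways):
        home = (p % cfg.n_modules) + 1
        cls = class_of_module[home]
        name = f"PW{p + 1:0{pw_width}d}_{category_name[cls]}"
        n_in_class = int(round(cfg.pathway_module_affinity * cfg.pathway_size))
        n_home = max(1, int(round(0.6 * n_in_class)))
        other_class_modules = [
            m for m in class_of_module.index[class_of_module == cls] if m != home
        ]
        n_spread = n_in_class - n_home if other_class_modules else 0
        n_home = n_in_class - n_spread

        home_pool = np.flatnonzero(gene_module[:n_genes] == home)
        members = list(rng.choice(home_pool, size=min(n_home, len(home_pool)), replace=False))
        if n_spread:
            spread_pool = np.flatnonzero(
                np.isin(gene_module[:n_genes], other_class_modules)
            )
            members += list(rng.choice(spread_pool, size=n_spread, replace=False))
        n_rest = cfg.pathway_size - len(members)
        rest_pool = np.setdiff1d(np.arange(n_genes), np.array(members, dtype=int))
        members += list(rng.choice(rest_pool, size=n_rest, replace=False))
        sets[name] = frozenset(gene_ids[i] for i in members)
        categories[name] = category_name[cls]
        pathway_module[name] = home
        pathway_cls[name] = cls

    genesets = GeneSetCollection(sets=sets, categories=categories)

    truth = GroundTruth(
        gene_module=pd.Series(gene_module, index=all_gene_ids, name="module"),
        module_factors=pd.DataFrame(
            factors,
            index=pd.Index(range(1, cfg.n_modules + 1), name="module"),
            columns=sample_ids,
        ),
        receptor_class=receptor_class,
        labeled_receptors=labeled_idx,
        unlabeled_receptors=unlabeled_idx,
        pathway_module=pd.Series(pathway_module, name="module"),
        pathway_class=pd.Series(pathway_cls, name="class"),
        module_class=class_of_module,
        outlier_samples=sample_ids[np.sort(outlier_pos)],
        low_expression_genes=decoy_ids,
    )
    return expr, meta, genesets, catalog, labels, truth


def write_dataset(
    outdir,
    expr: ExpressionMatrix,
    meta: pd.DataFrame,
    genesets: GeneSetCollection,
    catalog: pd.Index,
    labels: pd.DataFrame,
    truth: GroundTruth,
) -> dict[str, str]:
    """Write a generated dataset to disk (TSV/GCT/GMT/JSON); returns paths."""
    import json
    from pathlib import Path

    from . import io as _io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression_tsv": outdir / "expression.tsv",
        "expression_gct": outdir / "expression.gct",
        "metadata": outdir / "metadata.tsv",
        "genesets": outdir / "pathways.gmt",
        "receptors": outdir / "receptors.txt",
        "metabolic": outdir / "metabolic_positives.txt",
        "inflammatory": outdir / "inflammatory_positives.txt",
        "exclusion": outdir / "exclusion.txt",
        "truth": outdir / "ground_truth.json",
        "factors": outdir / "module_factors.tsv",
    }
    _io.write_expression_tsv(expr, paths["expression_tsv"])
    _io.write_gct(expr, paths["expression_gct"])
    _io.write_table(meta, paths["metadata"])
    _io.write_gmt(genesets, paths["genesets"])
    _io.write_gene_list(catalog, paths["receptors"])
    _io.write_gene_list(
        labels.index[labels["label"] == "metabolic"], paths["metabolic"]
    )
    _io.write_gene_list(
        labels.index[labels["label"] == "inflammatory"], paths["inflammatory"]
    )
    _io.write_gene_list([], paths["exclusion"])
    _io.write_table(truth.module_factors, paths["factors"])
    truth_json = {
        "gene_module": {g: int(m) for g, m in truth.gene_module.items()},
        "receptor_class": truth.receptor_class.to_dict(),
        "labeled_receptors": truth.labeled_receptors.tolist(),
        "unlabeled_receptors": truth.unlabeled_receptors.tolist(),
        "pathway_module": {p: int(m) for p, m in truth.pathway_module.items()},
        "pathway_class": truth.pathway_class.to_dict(),
        "module_class": {int(m): c for m, c in truth.module_class.items()},
        "outlier_samples": truth.outlier_samples.tolist(),
        "low_expression_genes": truth.low_expression_genes.tolist(),
    }
    paths["truth"].write_text(json.dumps(truth_json, indent=2, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}


def separable_pu_problem(
    n_positive: int = 30,
    n_unlabeled: int = 200,
    n_negative: int = 50,
    n_features: int = 5,
    separation: float = 6.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Index, pd.Index, pd.Index]:
    """A planted positive-unlabeled problem in feature space.

    ``n_unlabeled`` points contain ``n_negative`` well-separated planted
    negatives (mean shifted by ``separation`` along every coordinate); the
    remaining unlabeled points are drawn from the positive distribution.
    Returns (features, positives, unlabeled, planted_negatives).
    """
    if n_negative > n_unlabeled:
        raise ValueError("n_negative cannot exceed n_unlabeled")
    rng = np.random.default_rng(seed)
    n_pos_like = n_unlabeled - n_negative
    X_pos = rng.standard_normal((n_positive, n_features))
    X_unl_pos = rng.standard_normal((n_pos_like, n_features))
    X_neg = rng.standard_normal((n_negative, n_features)) - separation / np.sqrt(n_features)
    pos_ids = pd.Index([f"P{i:03d}" for i in range(n_positive)])
    unl_ids = pd.Index(
        [f"U{i:03d}" for i in range(n_pos_like)] + [f"N{i:03d}" for i in range(n_negative)]
    )
    X = pd.DataFrame(
        np.vstack([X_pos, X_unl_pos, X_neg]),
        index=pos_ids.append(unl_ids),
        columns=[f"f{j:02d}" for j in range(n_features)],
    )
    neg_ids = pd.Index([f"N{i:03d}" for i in range(n_negative)])
    return X, pos_ids, unl_ids, neg_ids
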