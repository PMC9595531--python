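"""Positive-unlabeled bagging and three-class label assembly.

The "other" receptor class (neither metabolic nor inflammatory) has no
curated list, so it is inferred semi-supervised: linear SVMs are repeatedly
trained on the metabolic positives against a bootstrap draw of unlabeled
receptors treated as provisional negatives, out-of-bag unlabeled receptors
are scored with the signed decision value, and the receptors with the lowest
mean out-of-bag score (least positive-like) become the "other" group.
Known inflammatory receptors are excluded from the unlabeled pool first.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .containers import CLASS_ORDER


def read_gene_list(path: str | Path) -> list[str]:
    """One gene per line; blank lines and '#' comments ignored."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return genes


def assemble_positive_lists(
    metabolic: list[str],
    inflammatory: list[str],
    exclusion: list[str],
    catalog: pd.Index,
) -> tuple[set[str], set[str]]:
    """Build the two positive sets from the curated lists.

    Metabolic labels take precedence: a gene on both lists stays metabolic.
    The exclusion list removes inflammatory receptors tied to
    metabolic/growth-regulation processes (it stands in for an
    ontology-derived filter).  Both sets are intersected with the catalog.
    """
    cat = set(catalog)
    met = set(metabolic) & cat
    inf = (set(inflammatory) & cat) - met - set(exclusion)
    overlap = met & inf
    if overlap:
        raise ValueError(f"positive sets overlap after subtraction: {sorted(overlap)}")
    return met, inf


def pu_bagging(
    features: pd.DataFrame,
    positives: set[str],
    unlabeled: set[str],
    T: int = 100,
    seed: int = 0,
    C: float = 1.0,
) -> pd.DataFrame:
    """Bagged PU scoring of unlabeled receptors with linear SVMs.

    Each of the ``T`` iterations draws |positives| unlabeled receptors with
    replacement as provisional negatives, fits a linear SVM (positives = +1)
    on standardized, zero-imputed features, and records the signed decision
    value of every out-of-bag unlabeled receptor.  Lower mean scores mean
    less positive-like.  Returns a table with ``oob_score``,
    ``n_oob_evaluations`` and a ``scored`` flag.
    """
    pos = sorted(positives)
    unl = sorted(unlabeled)
    if len(pos) < 5:
        raise ValueError("need at least 5 positives for PU bagging")
    if set(pos) & set(unl):
        raise ValueError("positives and unlabeled sets must be disjoint")
    rng = np.random.default_rng(seed)

    X_pos = features.loc[pos].fillna(0.0).to_numpy(float)
    X_unl = features.loc[unl].fillna(0.0).to_numpy(float)
    n_unl = len(unl)

    score_sum = np.zeros(n_unl)
    n_oob = np.zeros(n_unl, dtype=int)
    y = np.concatenate([np.ones(len(pos)), -np.ones(len(pos))])
    for _ in range(T):
        draw = rng.integers(0, n_unl, size=len(pos))
        oob = np.setdiff1d(np.arange(n_unl), draw)
        X_train = np.vstack([X_pos, X_unl[draw]])
        mu = X_train.mean(axis=0)
        sd = X_train.std(axis=0)
        sd[sd == 0] = 1.0
        clf = SVC(kernel="linear", C=C)
        clf.fit((X_train - mu) / sd, y)
        score_sum[oob] += clf.decision_function((X_unl[oob] - mu) / sd)
        n_oob[oob] += 1

    never = n_oob == 0
    if never.any():
        warnings.warn(
            f"{never.sum()} receptor(s) never out-of-bag after {T} iterations",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        mean_score = np.where(never, np.nan, score_sum / np.maximum(n_oob, 1))
    table = pd.DataFrame(
        {"oob_score": mean_score, "n_oob_evaluations": n_oob, "scored": ~never},
        index=pd.Index(unl, name="receptor"),
    )
    table.attrs["iterations"] = T
    return table


def select_other(scores: pd.DataFrame, K: int = 50) -> set[str]:
    """The K scored receptors with the lowest mean out-of-bag score.

    K defaults to 50 to keep the three training classes balanced.  Ties are
    broken lexicographically on receptor id.
    """
    scored = scores.loc[scores["scored"]]
    if K <= 0:
        return set()
    if len(scored) < K:
        warnings.warn(
            f"only {len(scored)} scored receptors (< K={K}); returning all",
            stacklevel=2,
        )
        return set(scored.index)
    ordered = scored.reset_index().sort_values(["oob_score", "receptor"], kind="stable")
    return set(ordered["receptor"].iloc[:K])


def assemble_labels(
    metabolic: set[str],
    inflammatory: set[str],
    other: set[str],
    catalog: pd.Index,
    provenance: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Combine the three class sets into a per-receptor label table.

    Catalog receptors outside all three sets are labeled "unlabeled".
    """
    sets = {"metabolic": metabolic, "inflammatory": inflammatory, "other": other}
    for a in CLASS_ORDER:
        for b in CLASS_ORDER:
            if a < b and sets[a] & sets[b]:
                raise ValueError(f"label sets {a!r} and {b!r} overlap")
    if not other:
        warnings.warn("empty 'other' set; emitting a two-class label set", stacklevel=2)
    rows = []
    for receptor in catalog:
        label = "unlabeled"
        for cls in CLASS_ORDER:
            if receptor in sets[cls]:
                label = cls
                break
        prov = (provenance or {}).get(
            receptor,
            {"metabolic": "given-positive", "inflammatory": "given-positive",
             "other": "pu-selected"}.get(label, "unlabeled"),
        )
        rows.append((receptor, label, prov))
    table = pd.DataFrame(rows, columns=["receptor", "label", "provenance"]).set_index("receptor")
    return table


def derive_other_class(
    features: pd.DataFrame,
    metabolic: set[str],
    inflammatory: set[str],
    T: int = 100,
    K: int = 50,
    seed: int = 0,
) -> tuple[set[str], pd.DataFrame]:
    """Full PU step: score the unlabeled pool and pick the "other" group.

    The unlabeled pool is every receptor with features that is neither a
    metabolic positive nor a known inflammatory receptor.
    """
    pool = set(features.index) - set(metabolic) - set(inflammatory)
    positives = set(metabolic) & set(features.index)
    scores = pu_bagging(features, positives, pool, T=T, seed=seed)
    return select_other(scores, K=K), scores
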