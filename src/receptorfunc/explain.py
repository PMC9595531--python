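"""Shapley-value feature attribution, thresholded prediction, and
cross-tissue comparison.

Attribution for the gradient-boosted model uses the exact path-dependent
tree-Shapley algorithm (feature contributions computed from tree covers,
no sampling) executed in float64 over the booster's dumped trees, so the
additivity identity ``base value + sum of attributions = class margin``
holds to numerical precision.  A seeded permutation-sampling estimator is
available for non-tree models and is flagged approximate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .classify import FittedModel
from .containers import CLASS_ORDER

# ---------------------------------------------------------------------------
# tree extraction


@dataclass
class _Tree:
    left: np.ndarray
    right: np.ndarray
    default: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    value: np.ndarray
    cover: np.ndarray


def _parse_tree(node_json: dict, feature_index: dict[str, int]) -> _Tree:
    nodes = []
    stack = [node_json]
    max_id = 0
    while stack:
        node = stack.pop()
        nodes.append(node)
        max_id = max(max_id, node["nodeid"])
        stack.extend(node.get("children", []))
    n = max_id + 1
    left = np.full(n, -1, np.int64)
    right = np.full(n, -1, np.int64)
    default = np.full(n, -1, np.int64)
    feature = np.zeros(n, np.int64)
    threshold = np.zeros(n, np.float64)
    value = np.zeros(n, np.float64)
    cover = np.zeros(n, np.float64)
    for node in nodes:
        i = node["nodeid"]
        cover[i] = node["cover"]
        if "leaf" in node:
            value[i] = node["leaf"]
        else:
            left[i] = node["yes"]
            right[i] = node["no"]
            default[i] = node["missing"]
            feature[i] = feature_index[node["split"]]
            threshold[i] = node["split_condition"]
    return _Tree(left, right, default, feature, threshold, value, cover)


def _extract_trees(model: FittedModel) -> tuple[list[list[_Tree]], float]:
    """Per-class tree lists and the learner base score."""
    if model.family != "gbt":
        raise TypeError(
            "exact tree-Shapley attribution requires the tree-ensemble model; "
            "use permutation_attribution for other families (approximate)"
        )
    booster = model.estimator.get_booster()
    names = booster.feature_names or [f"f{i}" for i in range(len(model.columns))]
    feature_index = {name: i for i, name in enumerate(names)}
    dumps = booster.get_dump(dump_format="json", with_stats=True)
    n_classes = len(CLASS_ORDER)
    per_class: list[list[_Tree]] = [[] for _ in range(n_classes)]
    for t, dump in enumerate(dumps):
        per_class[t % n_classes].append(_parse_tree(json.loads(dump), feature_index))
    cfg = json.loads(booster.save_config())
    base_score = float(cfg["learner"]["learner_model_param"]["base_score"])
    return per_class, base_score


# ---------------------------------------------------------------------------
# exact tree-Shapley (path-dependent, float64)


@njit(cache=False)
def _extend(fidx, fzero, fone, pweight, unique_depth, zero_fraction, one_fraction, feature_index):
    fidx[unique_depth] = feature_index
    fzero[unique_depth] = zero_fraction
    fone[unique_depth] = one_fraction
    pweight[unique_depth] = 1.0 if unique_depth == 0 else 0.0
    for i in range(unique_depth - 1, -1, -1):
        pweight[i + 1] += one_fraction * pweight[i] * (i + 1.0) / (unique_depth + 1.0)
        pweight[i] = zero_fraction * pweight[i] * (unique_depth - i) / (unique_depth + 1.0)


@njit(cache=False)
def _unwind(fidx, fzero, fone, pweight, unique_depth, path_index):
    one_fraction = fone[path_index]
    zero_fraction = fzero[path_index]
    next_one_portion = pweight[unique_depth]
    for i in range(unique_depth - 1, -1, -1):
        if one_fraction != 0.0:
            tmp = pweight[i]
            pweight[i] = next_one_portion * (unique_depth + 1.0) / ((i + 1.0) * one_fraction)
            next_one_portion = tmp - pweight[i] * zero_fraction * (unique_depth - i) / (unique_depth + 1.0)
        else:
            pweight[i] = pweight[i] * (unique_depth + 1.0) / (zero_fraction * (unique_depth - i))
    for i in range(path_index, unique_depth):
        fidx[i] = fidx[i + 1]
        fzero[i] = fzero[i + 1]
        fone[i] = fone[i + 1]


@njit(cache=False)
def _unwound_sum(fzero, fone, pweight, unique_depth, path_index):
    one_fraction = fone[path_index]
    zero_fraction = fzero[path_index]
    next_one_portion = pweight[unique_depth]
    total = 0.0
    if one_fraction != 0.0:
        for i in range(unique_depth - 1, -1, -1):
            tmp = next_one_portion / ((i + 1.0) * one_fraction)
            total += tmp
            next_one_portion = pweight[i] - tmp * zero_fraction * (unique_depth - i)
    else:
        for i in range(unique_depth - 1, -1, -1):
            total += pweight[i] / (zero_fraction * (unique_depth - i))
    return total * (unique_depth + 1.0)


@njit(cache=False)
def _recurse(left, right, default, feature, threshold, value, cover, x, phi,
             node, unique_depth, pfidx, pfzero, pfone, ppweight,
             parent_zero_fraction, parent_one_fraction, parent_feature_index):
    fidx = np.empty(unique_depth + 2, np.int64)
    fzero = np.empty(unique_depth + 2, np.float64)
    fone = np.empty(unique_depth + 2, np.float64)
    pweight = np.empty(unique_depth + 2, np.float64)
    for i in range(unique_depth):
        fidx[i] = pfidx[i]
        fzero[i] = pfzero[i]
        fone[i] = pfone[i]
        pweight[i] = ppweight[i]
    _extend(fidx, fzero, fone, pweight, unique_depth,
            parent_zero_fraction, parent_one_fraction, parent_feature_index)

    if left[node] < 0:  # leaf
        leaf_value = value[node]
        for i in range(1, unique_depth + 1):
            w = _unwound_sum(fzero, fone, pweight, unique_depth, i)
            phi[fidx[i]] += w * (fone[i] - fzero[i]) * leaf_value
        return

    split_index = feature[node]
    xval = x[split_index]
    if np.isnan(xval):
        hot = default[node]
    elif xval < threshold[node]:
        hot = left[node]
    else:
        hot = right[node]
    cold = right[node] if hot == left[node] else left[node]
    w = cover[node]
    hot_zero_fraction = cover[hot] / w
    cold_zero_fraction = cover[cold] / w
    incoming_zero = 1.0
    incoming_one = 1.0

    path_index = 0
    found = False
    for i in range(unique_depth + 1):
        if fidx[i] == split_index:
            path_index = i
            found = True
            break
    depth = unique_depth
    if found:
        incoming_zero = fzero[path_index]
        incoming_one = fone[path_index]
        _unwind(fidx, fzero, fone, pweight, depth, path_index)
        depth -= 1

    _recurse(left, right, default, feature, threshold, value, cover, x, phi,
             hot, depth + 1, fidx, fzero, fone, pweight,
             hot_zero_fraction * incoming_zero, incoming_one, split_index)
    _recurse(left, right, default, feature, threshold, value, cover, x, phi,
             cold, depth + 1, fidx, fzero, fone, pweight,
             cold_zero_fraction * incoming_zero, 0.0, split_index)


@njit(cache=False)
def _tree_shap(left, right, default, feature, threshold, value, cover, x, phi):
    dummy_i = np.empty(1, np.int64)
    dummy_f = np.empty(1, np.float64)
    _recurse(left, right, default, feature, threshold, value, cover, x, phi,
             0, 0, dummy_i, dummy_f, dummy_f, dummy_f, 1.0, 1.0, -1)


@njit(cache=False)
def _tree_leaf_value(left, right, default, feature, threshold, value, x):
    j = 0
    while left[j] >= 0:
        f = feature[j]
        if np.isnan(x[f]):
            j = default[j]
        elif x[f] < threshold[j]:
            j = left[j]
        else:
            j = right[j]
    return value[j]


def _tree_expected_value(tree: _Tree) -> float:
    leaves = tree.left < 0
    return float((tree.value[leaves] * tree.cover[leaves]).sum() / tree.cover[0])


# ---------------------------------------------------------------------------
# attribution table


@dataclass
class AttributionTable:
    """Receptor x class x feature Shapley attributions for the tree model.

    ``values[r, c, f]`` is the contribution of feature f to the class-c
    margin of receptor r; ``base_values[c] + values[r, c, :].sum()`` equals
    the class-c margin (local accuracy).
    """

    values: np.ndarray  # (n_receptors, n_classes, n_features)
    base_values: np.ndarray  # (n_classes,)
    margins: np.ndarray  # (n_receptors, n_classes), float64 tree traversal
    receptors: pd.Index
    feature_names: list[str]
    feature_values: pd.DataFrame

    def local_accuracy_error(self) -> float:
        """Max |base + sum(attributions) - margin| over receptors and classes."""
        total = self.base_values[None, :] + self.values.sum(axis=2)
        return float(np.abs(total - self.margins).max())

    def global_importance(self) -> pd.DataFrame:
        """Mean |attribution| per feature: one column per class plus the
        across-class average (the bar-ranking quantity)."""
        mean_abs = np.abs(self.values).mean(axis=0)  # classes x features
        table = pd.DataFrame(
            mean_abs.T, index=self.feature_names,
            columns=[f"mean_abs_shap_{c}" for c in CLASS_ORDER],
        )
        table["mean_abs_shap_overall"] = mean_abs.mean(axis=0)
        table.index.name = "feature"
        return table.sort_values("mean_abs_shap_overall", ascending=False)

    def top_features(self, class_name: str | None = None, n: int = 10) -> pd.DataFrame:
        """Top-n features by mean |attribution| for one class (or overall)."""
        imp = self.global_importance()
        col = (
            "mean_abs_shap_overall"
            if class_name is None
            else f"mean_abs_shap_{class_name}"
        )
        return imp.sort_values(col, ascending=False).head(n)[[col]]

    def signed_summary(self, class_name: str) -> pd.DataFrame:
        """Long-format (receptor, feature, feature value, attribution) pairs
        for direction plots of one class."""
        c = CLASS_ORDER.index(class_name)
        rows = []
        for ri, receptor in enumerate(self.receptors):
            for fi, feat in enumerate(self.feature_names):
                rows.append(
                    (receptor, feat, self.feature_values.iloc[ri, fi], self.values[ri, c, fi])
                )
        return pd.DataFrame(rows, columns=["receptor", "feature", "value", "attribution"])

    def to_long_frame(self) -> pd.DataFrame:
        frames = []
        for c, cls in enumerate(CLASS_ORDER):
            df = pd.DataFrame(self.values[:, c, :], index=self.receptors,
                              columns=self.feature_names)
            long = df.stack().rename("attribution").reset_index()
            long.columns = ["receptor", "feature", "attribution"]
            long.insert(1, "class", cls)
            frames.append(long)
        return pd.concat(frames, ignore_index=True)


def shap_attribution(model: FittedModel, features: pd.DataFrame) -> AttributionTable:
    """Exact per-class tree-Shapley attributions for every receptor.

    Raises ``TypeError`` for non-tree model families; those require the
    approximate :func:`permutation_attribution`.
    """
    model.check_schema(features)
    per_class, base_score = _extract_trees(model)
    X = features.to_numpy(float)
    n, p = X.shape
    k = len(CLASS_ORDER)
    values = np.zeros((n, k, p))
    margins = np.full((n, k), base_score)
    base = np.full(k, base_score)
    for c in range(k):
        for tree in per_class[c]:
            base[c] += _tree_expected_value(tree)
            for r in range(n):
                _tree_shap(tree.left, tree.right, tree.default, tree.feature,
                           tree.threshold, tree.value, tree.cover, X[r], values[r, c])
                margins[r, c] += _tree_leaf_value(
                    tree.left, tree.right, tree.default, tree.feature,
                    tree.threshold, tree.value, X[r]
                )
    return AttributionTable(
        values=values,
        base_values=base,
        margins=margins,
        receptors=features.index,
        feature_names=features.columns.tolist(),
        feature_values=features,
    )


def permutation_attribution(
    predict_proba, X: pd.DataFrame, class_index: int,
    n_permutations: int = 100, seed: int = 0,
) -> pd.DataFrame:
    """Approximate Shapley attributions by permutation sampling.

    Features "absent" from a coalition are replaced by their column mean;
    marginal contributions are averaged over seeded random feature orders.
    Use for non-tree models only; the tree model has an exact method.
    """
    rng = np.random.default_rng(seed)
    arr = np.nan_to_num(X.to_numpy(float), nan=0.0)
    background = arr.mean(axis=0)
    n, p = arr.shape
    phi = np.zeros((n, p))
    for _ in range(n_permutations):
        order = rng.permutation(p)
        current = np.tile(background, (n, 1))
        prev = predict_proba(current)[:, class_index]
        for f in order:
            current[:, f] = arr[:, f]
            new = predict_proba(current)[:, class_index]
            phi[:, f] += new - prev
            prev = new
    phi /= n_permutations
    return pd.DataFrame(phi, index=X.index, columns=X.columns)


# ---------------------------------------------------------------------------
# prediction at the probability cutoff


def predict_unlabeled(
    model: FittedModel, features: pd.DataFrame, cutoff: float = 0.85
) -> pd.DataFrame:
    """Class probabilities for unlabeled receptors with a strict cutoff flag.

    ``passes_cutoff`` is True only when the maximum class probability is
    strictly greater than ``cutoff`` (default 0.85).
    """
    table = model.predict_proba_table(features)
    table["passes_cutoff"] = table["max_probability"] > cutoff
    return table


def cross_tissue_compare(
    preds_a: pd.DataFrame,
    preds_b: pd.DataFrame,
    cutoff: float = 0.85,
    switch_diff: float = 0.85,
) -> tuple[pd.DataFrame, pd.Index]:
    """Compare per-receptor predictions between two tissues.

    ``consistent``: same predicted class in both tissues with both maximum
    probabilities strictly above ``cutoff``.  ``switch``: some class whose
    probability differs between the tissues by strictly more than
    ``switch_diff`` (a strong predicted change of function).  Receptors
    present in only one tissue are returned separately.
    """
    shared = preds_a.index.intersection(preds_b.index)
    only_one = preds_a.index.symmetric_difference(preds_b.index)
    if len(shared) == 0:
        import warnings

        warnings.warn("no shared receptors between tissues", stacklevel=2)
        return pd.DataFrame(), only_one
    a = preds_a.loc[shared]
    b = preds_b.loc[shared]
    prob_cols = ["p_metabolic", "p_inflammatory", "p_other"]
    diff = (a[prob_cols] - b[prob_cols]).abs()
    table = pd.DataFrame(index=shared)
    for col in prob_cols:
        table[f"{col}_a"] = a[col]
        table[f"{col}_b"] = b[col]
    table["predicted_a"] = a["predicted"]
    table["predicted_b"] = b["predicted"]
    table["consistent"] = (
        (a["predicted"] == b["predicted"])
        & (a["max_probability"] > cutoff)
        & (b["max_probability"] > cutoff)
    )
    table["switch"] = (diff > switch_diff).any(axis=1)
    return table, only_one
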