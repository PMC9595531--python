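"""Per-receptor feature assembly.

A receptor inherits its module's pathway-enrichment score vector, the row of
the module-eigengene correlation matrix belonging to its module, and its own
kME correlations to every module eigengene.  Receptors that fall in the
unassigned module (or are absent from the expression data) are excluded and
reported, mirroring the retain-only-receptors-in-modules rule.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .coexpress import EigengeneMatrix, ModulePartition

PATHWAY_PREFIX = "pw:"
EIGCOR_PREFIX = "eigcor:M"
KME_PREFIX = "kme:M"


def eigengene_correlation_matrix(eig: EigengeneMatrix) -> pd.DataFrame:
    """Pairwise Pearson correlations of module eigengene profiles."""
    E = eig.values.to_numpy(float)
    if E.shape[0] < 2:
        warnings.warn("fewer than 2 modules; trivial eigengene correlation matrix",
                      stacklevel=2)
        C = np.ones((E.shape[0], E.shape[0]))
    else:
        C = np.corrcoef(E)
    return pd.DataFrame(C, index=eig.values.index, columns=eig.values.index)


def build_feature_matrix(
    catalog: pd.Index,
    partition: ModulePartition,
    enrichment: dict[int, pd.DataFrame],
    eig_cor: pd.DataFrame,
    kme: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the receptor x feature matrix.

    Feature blocks, in fixed column order:

    * ``pw:<pathway>`` — the enrichment scores of the receptor's module
      (NaN where the module had no overlap with the pathway);
    * ``eigcor:M<m>`` — the correlation of the receptor's module eigengene
      with every module eigengene;
    * ``kme:M<m>`` — the receptor's own correlation with every eigengene.

    Returns (features, drop_report); dropped receptors are those missing
    from the partition or assigned to module 0.
    """
    modules = sorted(enrichment)
    if not modules:
        raise ValueError("no module enrichment tables")
    pathways = enrichment[modules[0]].index
    columns = (
        [f"{PATHWAY_PREFIX}{p}" for p in pathways]
        + [f"{EIGCOR_PREFIX}{m}" for m in modules]
        + [f"{KME_PREFIX}{m}" for m in modules]
    )

    rows, dropped = {}, []
    for receptor in catalog:
        if receptor not in partition.labels.index:
            dropped.append((receptor, "absent from expression data"))
            continue
        m = int(partition.labels[receptor])
        if m == 0:
            dropped.append((receptor, "unassigned (module 0)"))
            continue
        scores = enrichment[m]["score"].reindex(pathways).to_numpy()
        ecor = eig_cor.loc[m, modules].to_numpy(float)
        krow = kme.loc[receptor, modules].to_numpy(float)
        rows[receptor] = np.concatenate([scores, ecor, krow])

    features = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    features.index.name = "receptor"
    drop_report = pd.DataFrame(dropped, columns=["receptor", "reason"]).set_index("receptor")
    return features, drop_report


def feature_schema(features: pd.DataFrame) -> dict:
    """Serializable schema descriptor used to guard train/predict alignment."""
    return {"columns": features.columns.tolist()}
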