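"""Core in-memory containers shared across the pipeline.

The pipeline passes a genes x samples expression matrix through a fixed
sequence of preprocessing stages.  ``ExpressionMatrix`` carries a stage tag so
that each operation can assert it receives data in the units it expects
(raw TPM, log2-TPM, quantile-normalized log2, or confounder residuals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Allowed stage tags, in pipeline order.
STAGES = ("tpm", "log2", "qnorm", "residual")

#: Metadata columns required by the confounder model.
METADATA_COLUMNS = ("batch", "ischemic_time", "sex", "age_bracket", "hardy_code")

HARDY_CODES = frozenset({0, 1, 2, 3, 4})


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with a processing-stage tag.

    Parameters
    ----------
    values
        DataFrame with gene identifiers as the index and sample identifiers
        as columns.
    stage
        One of :data:`STAGES`.
    """

    values: pd.DataFrame
    stage: str = "tpm"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups[:5]}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def require_stage(self, *stages: str) -> None:
        if self.stage not in stages:
            raise ValueError(
                f"operation requires stage in {stages}, got {self.stage!r}"
            )

    def with_values(self, values: pd.DataFrame, stage: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, stage=stage or self.stage)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Check a per-sample metadata table for the required confounder columns."""
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    bad = set(meta["hardy_code"].unique()) - HARDY_CODES
    if bad:
        raise ValueError(f"hardy_code outside 0-4: {sorted(bad)}")
    if meta.index.has_duplicates:
        raise ValueError("duplicate sample identifiers in metadata")
    return meta


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics) with optional per-set category labels.

    ``categories`` is a stand-in for a pathway-hierarchy class annotation
    (e.g. metabolism vs immune); it rides in the GMT description field.
    """

    sets: dict[str, frozenset[str]]
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {name: frozenset(genes) for name, genes in self.sets.items()}
        empty = [name for name, genes in self.sets.items() if not genes]
        if empty:
            raise ValueError(f"empty gene sets: {empty[:5]}")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def restrict(self, universe: set[str]) -> "GeneSetCollection":
        """Intersect every set with ``universe``, dropping sets left empty."""
        kept = {
            name: genes & frozenset(universe)
            for name, genes in self.sets.items()
        }
        kept = {name: genes for name, genes in kept.items() if genes}
        cats = {name: self.categories[name] for name in kept if name in self.categories}
        return GeneSetCollection(sets=kept, categories=cats)


CLASS_ORDER = ("metabolic", "inflammatory", "other")
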