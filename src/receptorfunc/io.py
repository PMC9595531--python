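"""Readers and writers for the interchange formats.

Expression travels as plain TSV (genes in rows, sample-ID header) or GCT 1.2;
gene sets as GMT; metadata, labels and all result tables as TSV.  Floats are
serialized at 15 significant digits so that write -> read round-trips are
lossless at the precision the pipeline cares about.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSetCollection

FLOAT_FORMAT = "%.15g"


# ---------------------------------------------------------------------------
# expression matrices


def read_expression(path: str | Path, format: str | None = None, stage: str = "tpm") -> ExpressionMatrix:
    """Read a genes x samples matrix from TSV or GCT 1.2.

    ``format`` is inferred from the suffix when omitted.
    """
    path = Path(path)
    fmt = format or ("gct" if path.suffix.lower() == ".gct" else "tsv")
    if fmt == "gct":
        return _read_gct(path, stage)
    if fmt == "tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        _check_numeric(frame, path)
        return ExpressionMatrix(values=frame, stage=stage)
    raise ValueError(f"unknown expression format {fmt!r}")


def _check_numeric(frame: pd.DataFrame, path: Path) -> None:
    non_numeric = [c for c in frame.columns if not np.issubdtype(frame[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"{path}: non-numeric expression column(s): {non_numeric[:5]}")


def _read_gct(path: Path, stage: str) -> ExpressionMatrix:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValueError(f"{path}:1: expected GCT version line '#1.2', got {version!r}")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise ValueError(f"{path}:2: malformed GCT dimension line")
        n_genes, n_samples = int(dims[0]), int(dims[1])
        frame = pd.read_csv(fh, sep="\t", index_col=0)
    if "Description" in frame.columns:
        frame = frame.drop(columns="Description")
    if frame.shape != (n_genes, n_samples):
        raise ValueError(
            f"{path}: header declares {n_genes} x {n_samples} "
            f"but the body is {frame.shape[0]} x {frame.shape[1]}"
        )
    _check_numeric(frame, path)
    frame.index.name = "gene"
    return ExpressionMatrix(values=frame, stage=stage)


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def write_gct(expr: ExpressionMatrix, path: str | Path) -> None:
    vals = expr.values
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{vals.shape[0]}\t{vals.shape[1]}\n")
        out = vals.copy()
        out.insert(0, "Description", "na")
        out.index.name = "Name"
        out.to_csv(fh, sep="\t", float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file; the description field carries the category label.

    Empty sets are dropped with a warning; duplicate names are an error.
    """
    sets: dict[str, frozenset[str]] = {}
    categories: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: GMT line needs name and description")
        name, description, *genes = parts
        genes = [g for g in genes if g]
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
        if not genes:
            warnings.warn(f"{path}:{lineno}: empty gene set {name!r} dropped", stacklevel=2)
            continue
        sets[name] = frozenset(genes)
        if description and description != "na":
            categories[name] = description
    return GeneSetCollection(sets=sets, categories=categories)


def write_gmt(genesets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(genesets.sets):
            description = genesets.categories.get(name, "na")
            genes = "\t".join(sorted(genesets.sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


# ---------------------------------------------------------------------------
# tables and lists


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(frame: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_gene_list(genes, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("".join(f"{g}\n" for g in genes))
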