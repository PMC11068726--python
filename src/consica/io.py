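"""Readers and writers for the plain-text interchange formats.

Expression matrices travel as TSV (genes in rows, header row of sample ids),
survival tables as CSV, gene sets as GMT, spatial profiles as MatrixMarket
plus a spot-coordinate CSV, and TCSets as TSV with a JSON sidecar carrying
credibility indices and provenance parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import (
    ExpressionMatrix,
    GeneSetCollection,
    MixingMatrix,
    SpatialProfile,
    SurvivalTable,
    TCSet,
)

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_survival_csv",
    "write_survival_csv",
    "read_gmt",
    "write_gmt",
    "read_tcset",
    "write_tcset",
    "read_mixing_tsv",
    "write_mixing_tsv",
    "read_spatial",
    "write_spatial",
]


def read_expression_tsv(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix.from_frame(df)


def write_expression_tsv(X: ExpressionMatrix, path) -> None:
    X.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_survival_csv(path) -> SurvivalTable:
    df = pd.read_csv(path)
    return SurvivalTable(df)


def write_survival_csv(table: SurvivalTable, path) -> None:
    table.data.to_csv(path, index=False)


def read_gmt(path, name: str | None = None) -> GeneSetCollection:
    sets = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return GeneSetCollection(name or Path(path).stem, sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for set_name, genes in collection:
            fh.write("\t".join([set_name, collection.name, *genes]) + "\n")


def write_tcset(tcs: TCSet, path, sidecar: dict | None = None) -> None:
    """TSV (rows = components, columns = genes) + `<path>.json` sidecar."""
    path = Path(path)
    pd.DataFrame(tcs.weights, index=tcs.component_ids, columns=tcs.gene_ids).to_csv(
        path, sep="\t", index_label="component_id"
    )
    meta = {
        "credibility": {c: float(v) for c, v in zip(tcs.component_ids, tcs.credibility)},
    }
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=2, sort_keys=True)
    )


def read_tcset(path) -> TCSet:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    cred = np.array([meta["credibility"][str(c)] for c in df.index])
    return TCSet(list(df.index), list(df.columns), df.to_numpy(dtype=float), cred)


def write_mixing_tsv(mixing: MixingMatrix, path) -> None:
    mixing.to_frame().to_csv(path, sep="\t", index_label="component_id")


def read_mixing_tsv(path) -> MixingMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return MixingMatrix(list(df.index), list(df.columns), df.to_numpy(dtype=float))


def write_spatial(profile: SpatialProfile, prefix) -> None:
    """MTX (genes x spots) + `<prefix>_genes.tsv`, `<prefix>_coords.csv`."""
    prefix = Path(prefix)
    scipy.io.mmwrite(
        str(prefix) + ".mtx", scipy.sparse.csr_matrix(profile.expression.values)
    )
    pd.Series(profile.expression.gene_ids).to_csv(
        str(prefix) + "_genes.tsv", sep="\t", index=False, header=["gene_id"]
    )
    profile.coords.to_csv(str(prefix) + "_coords.csv", index=False)


def read_spatial(prefix) -> SpatialProfile:
    prefix = Path(prefix)
    values = np.asarray(scipy.io.mmread(str(prefix) + ".mtx").todense(), dtype=float)
    genes = list(pd.read_csv(str(prefix) + "_genes.tsv", sep="\t")["gene_id"])
    coords = pd.read_csv(str(prefix) + "_coords.csv")
    X = ExpressionMatrix(genes, list(coords["spot_id"]), values)
    return SpatialProfile(X, coords)
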