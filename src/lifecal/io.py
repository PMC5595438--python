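"""Readers/writers for the external formats and the duplicate-probe rule.

Formats are deliberately plain text: TSV expression matrix + TSV sample
metadata, GMT gene sets, TSV gene x cell-type matrices, whitespace-
delimited MAGMA ``.genes.out`` association tables and TSV feature
annotation.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    ExpressionDataset,
    FeatureAnnotation,
    GeneAssociationTable,
    GeneSetCollection,
    SpecificityMatrix,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# expression matrix + metadata
# ---------------------------------------------------------------------------

def read_expression_dataset(matrix_path, meta_path, species: str = "human",
                            age_unit: str | None = None) -> ExpressionDataset:
    """Load a TSV expression matrix and its per-sample metadata.

    The matrix has a header row of sample identifiers and one feature
    per line; the metadata has a ``sample_id`` column (or first column)
    plus ``age``, ``sex`` and optional covariates.  Samples are ordered
    as in the metadata.  Features containing any missing value are
    dropped (with a logged count).
    """
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0,
                         float_precision="round_trip")
    meta = pd.read_csv(meta_path, sep="\t", float_precision="round_trip")
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    else:
        meta = meta.set_index(meta.columns[0])
    meta.index = meta.index.astype(str)
    matrix.columns = matrix.columns.astype(str)

    missing_in_meta = [s for s in matrix.columns if s not in meta.index]
    missing_in_matrix = [s for s in meta.index if s not in matrix.columns]
    if missing_in_meta or missing_in_matrix:
        raise ValueError(
            "sample identifiers differ between matrix and metadata; "
            f"in matrix only: {missing_in_meta[:10]}; in metadata only: {missing_in_matrix[:10]}")

    if "age" not in meta.columns:
        raise ValueError("metadata needs an 'age' column")
    age = pd.to_numeric(meta["age"], errors="coerce")
    if age.isna().any():
        bad = meta.index[age.isna()]
        raise ValueError(f"non-numeric age for samples: {list(bad)[:10]}")
    meta["age"] = age.astype(float)

    matrix = matrix[meta.index]
    n_before = matrix.shape[0]
    matrix = matrix.dropna(axis=0, how="any").astype(float)
    dropped = n_before - matrix.shape[0]
    if dropped:
        logger.info("dropped %d features with missing values", dropped)

    if age_unit is None:
        age_unit = {"human": "year", "mouse": "day"}[species]
    return ExpressionDataset(matrix, meta, species=species, age_unit=age_unit)


def write_expression_dataset(ds: ExpressionDataset, matrix_path, meta_path) -> None:
    """Write matrix and metadata TSVs; full float precision so a
    write/read round-trip is bit-exact."""
    ds.values.to_csv(matrix_path, sep="\t", float_format="%.17g",
                     index_label="feature_id")
    meta = ds.samples.copy()
    meta.to_csv(meta_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gene_sets(path) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> member...  Duplicate
    members within a set are removed; duplicate set names are an error."""
    sets: dict[str, list[str]] = {}
    provenance: dict[str, str] = {}
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: GMT line needs name and description")
        name, desc, *members = parts
        if name in sets:
            raise ValueError(f"duplicate gene-set name {name!r} in {path}")
        sets[name] = [m for m in members if m]
        provenance[name] = desc
    if not sets:
        logger.warning("no gene sets found in %s", path)
    return GeneSetCollection(sets, provenance)


def write_gene_sets(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in coll.sets.items():
            desc = coll.provenance.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# specificity / annotation / associations
# ---------------------------------------------------------------------------

def read_specificity_matrix(path, kind: str = "specificity") -> SpecificityMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    return SpecificityMatrix(values, kind=kind)


def write_specificity_matrix(spec: SpecificityMatrix, path) -> None:
    spec.values.to_csv(path, sep="\t", float_format="%.17g", index_label="gene")


def read_feature_annotation(path) -> FeatureAnnotation:
    table = pd.read_csv(path, sep="\t", index_col=0)
    return FeatureAnnotation(table)


def read_gene_associations(path) -> GeneAssociationTable:
    """Read a MAGMA ``.genes.out``-dialect table: whitespace-delimited
    with a header containing GENE and ZSTAT columns (CHR/START/STOP kept
    when present for region exclusion)."""
    raw = pd.read_csv(path, sep=r"\s+")
    cols = {c.upper(): c for c in raw.columns}
    if "GENE" not in cols or "ZSTAT" not in cols:
        raise ValueError("association table needs GENE and ZSTAT columns")
    table = pd.DataFrame({"zscore": raw[cols["ZSTAT"]].astype(float).to_numpy()},
                         index=raw[cols["GENE"]].astype(str))
    table.index.name = "gene_id"
    for up, name in (("CHR", "chrom"), ("START", "start"), ("STOP", "stop")):
        if up in cols:
            table[name] = raw[cols[up]].to_numpy()
    return GeneAssociationTable(table)


# ---------------------------------------------------------------------------
# duplicate probes
# ---------------------------------------------------------------------------

def collapse_duplicate_features(ds: ExpressionDataset, ann: FeatureAnnotation,
                                peget: pd.Series) -> ExpressionDataset:
    """Keep one probe per gene symbol: the one with the largest peak
    turning (PeGeT) score; deterministic ties break to the
    lexicographically smallest feature id.  Probes without annotation
    are retained under their own id (logged)."""
    symbols = []
    unannotated = 0
    for fid in ds.feature_ids:
        sym = ann.symbol_of(fid)
        if sym is None or (isinstance(sym, float) and np.isnan(sym)):
            symbols.append(fid)  # self-keyed: never collides with another gene
            unannotated += 1
        else:
            symbols.append(sym)
    if unannotated:
        logger.info("%d features without annotation retained under their own id",
                    unannotated)

    missing = [fid for fid, sym in zip(ds.feature_ids, symbols)
               if sym != fid and fid not in peget.index]
    if missing:
        raise ValueError(f"PeGeT score missing for annotated features: {missing[:10]}")

    frame = pd.DataFrame({
        "feature_id": ds.feature_ids,
        "symbol": symbols,
        "score": [float(peget.get(fid, 0.0)) for fid in ds.feature_ids],
    })
    # largest score first, ties by lexicographically smallest feature_id
    frame = frame.sort_values(["score", "feature_id"],
                              ascending=[False, True], kind="mergesort")
    keep = frame.drop_duplicates("symbol", keep="first")["feature_id"]
    keep = [fid for fid in ds.feature_ids if fid in set(keep)]  # original order
    return ds.select_features(keep)
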