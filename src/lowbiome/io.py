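"""Readers and writers for the plain-text formats the pipeline touches.

Everything is delimited text (QIIME-era conventions): TSV OTU tables with
taxa as rows, TSV sample metadata, newick trees, and square TSV distance
matrices.  Readers reject malformed input rather than coercing it.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    CtRecord,
    DistanceMatrix,
    OtuTable,
    PhyloTree,
    SampleRecord,
    Taxonomy,
    ValidationError,
)


class ParseError(ValueError):
    pass


@dataclass(frozen=True)
class TableDialect:
    delimiter: str = "\t"
    taxa_as_rows: bool = True
    id_column: str = "taxon_id"
    missing_token: str = ""

    def __post_init__(self):
        if len(self.delimiter) != 1:
            raise ValidationError("delimiter must be a single character")


DEFAULT_DIALECT = TableDialect()


def _as_stream(source):
    if isinstance(source, str):
        return _io.StringIO(source)
    return source


def read_otu_table(source, dialect: TableDialect = DEFAULT_DIALECT) -> OtuTable:
    """Parse a delimited count table into taxa x samples orientation."""
    try:
        frame = pd.read_csv(_as_stream(source), sep=dialect.delimiter, index_col=0)
    except Exception as exc:
        raise ParseError(f"cannot parse table: {exc}") from exc
    if not dialect.taxa_as_rows:
        frame = frame.T
    if frame.index.has_duplicates or frame.columns.has_duplicates:
        raise ParseError("duplicate row or column identifiers")
    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() | ~np.isfinite(converted.to_numpy(dtype=float))
        if bad.any():
            row = frame.index[int(np.argmax(bad.to_numpy()))]
            raise ParseError(f"non-numeric entry at row {row!r}, column {col!r}")
        values[:, j] = converted.to_numpy(dtype=float)
    neg = np.argwhere(values < 0)
    if neg.size:
        i, j = neg[0]
        raise ParseError(
            f"negative entry at row {frame.index[i]!r}, column {frame.columns[j]!r}"
        )
    return OtuTable(list(frame.index.astype(str)), list(frame.columns.astype(str)), values)


def write_otu_table(table: OtuTable, dialect: TableDialect = DEFAULT_DIALECT) -> str:
    frame = table.to_frame()
    if not dialect.taxa_as_rows:
        frame = frame.T
    frame.index.name = dialect.id_column
    # repr-format floats so real-valued (post-averaging) entries round-trip
    return frame.to_csv(sep=dialect.delimiter, float_format="%.17g")


_META_COLUMNS = ("sample_id", "sample_class", "organ", "fetus_id", "ega_weeks", "facility")


def read_metadata(source) -> list:
    frame = pd.read_csv(_as_stream(source), sep="\t", dtype=str)
    for col in ("sample_id", "sample_class"):
        if col not in frame.columns:
            raise ParseError(f"metadata missing required column {col!r}")
    records = []
    for _, row in frame.iterrows():
        def get(col, default=None):
            v = row.get(col)
            if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
                return default
            return v

        ega = get("ega_weeks")
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                sample_class=str(row["sample_class"]),
                organ=get("organ", "none"),
                fetus_id=get("fetus_id"),
                ega_weeks=float(ega) if ega is not None else None,
                facility=get("facility"),
            )
        )
    return records


def write_metadata(records) -> str:
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "sample_class": r.sample_class,
                "organ": r.organ,
                "fetus_id": r.fetus_id if r.fetus_id is not None else "",
                "ega_weeks": r.ega_weeks if r.ega_weeks is not None else "",
                "facility": r.facility if r.facility is not None else "",
            }
        )
    return pd.DataFrame(rows, columns=list(_META_COLUMNS)).to_csv(sep="\t", index=False)


def read_newick(source) -> PhyloTree:
    text = source if isinstance(source, str) else source.read()
    if text.count("(") != text.count(")"):
        raise ParseError("unbalanced parentheses in newick")
    try:
        return PhyloTree.from_newick(text)
    except ValidationError as exc:
        raise ParseError(str(exc)) from exc


def write_newick(tree: PhyloTree) -> str:
    return tree.to_newick()


def read_distance_matrix(source) -> DistanceMatrix:
    frame = pd.read_csv(_as_stream(source), sep="\t", index_col=0)
    if list(frame.index.astype(str)) != list(frame.columns.astype(str)):
        raise ParseError("distance matrix rows and columns disagree")
    try:
        return DistanceMatrix(list(frame.index.astype(str)), frame.to_numpy(dtype=float))
    except ValidationError as exc:
        raise ParseError(str(exc)) from exc


def write_distance_matrix(dm: DistanceMatrix) -> str:
    frame = pd.DataFrame(dm.values, index=dm.sample_ids, columns=dm.sample_ids)
    frame.index.name = "sample_id"
    return frame.to_csv(sep="\t", float_format="%.17g")


def read_taxonomy(source) -> Taxonomy:
    """Two-column TSV: taxon_id <tab> lineage string."""
    frame = pd.read_csv(_as_stream(source), sep="\t", dtype=str)
    if "taxon_id" not in frame.columns or "lineage" not in frame.columns:
        raise ParseError("taxonomy needs columns taxon_id, lineage")
    return Taxonomy(dict(zip(frame["taxon_id"], frame["lineage"])))


def write_taxonomy(taxonomy: Taxonomy) -> str:
    frame = pd.DataFrame(
        {"taxon_id": list(taxonomy.lineages), "lineage": list(taxonomy.lineages.values())}
    )
    return frame.to_csv(sep="\t", index=False)


def read_ct_records(source) -> list:
    """TSV with sample_id and one or more replicate columns (ct1, ct2, ...)."""
    frame = pd.read_csv(_as_stream(source), sep="\t")
    if "sample_id" not in frame.columns:
        raise ParseError("ct table needs a sample_id column")
    rep_cols = [c for c in frame.columns if c != "sample_id"]
    records = []
    for _, row in frame.iterrows():
        reps = [float(row[c]) for c in rep_cols if pd.notna(row[c])]
        records.append(CtRecord(sample_id=str(row["sample_id"]), replicate_cts=tuple(reps)))
    return records


def write_ct_records(records) -> str:
    max_reps = max(len(r.replicate_cts) for r in records)
    cols = [f"ct{i + 1}" for i in range(max_reps)]
    rows = []
    for r in records:
        row = {"sample_id": r.sample_id}
        for i, c in enumerate(cols):
            row[c] = r.replicate_cts[i] if i < len(r.replicate_cts) else ""
        rows.append(row)
    return pd.DataFrame(rows, columns=["sample_id"] + cols).to_csv(sep="\t", index=False)
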