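"""Readers and writers for the plain-text tables the pipeline exchanges.

All tables are tab-separated with a header row.  Expression matrices are
genes x samples with gene identifiers in the first column; sample-group
maps are two columns (sample_id, condition); presence-flag matrices mirror
the expression layout with Affymetrix-style P/M/A calls or 1/0 values.

Expression data live in a :class:`pandas.DataFrame` (index = gene ids,
columns = sample ids, float values); sample groups in a
:class:`pandas.Series` mapping sample id to condition label.  The readers
validate the invariants every downstream stage relies on: unique
identifiers, rectangular data, numeric values.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionParseError",
    "read_expression_table",
    "write_expression_table",
    "read_groups_table",
    "write_groups_table",
    "read_flags_table",
    "validate_expression",
    "validate_groups",
    "write_matrix",
]


class ExpressionParseError(ValueError):
    """Raised when an input table violates the format contract."""


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_expression_table(path) -> pd.DataFrame:
    """Read a genes x samples expression TSV.

    The first row holds sample identifiers, the first column gene
    identifiers.  Duplicate identifiers, ragged rows and non-numeric
    values are rejected with an error naming the offending line.
    """
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if not lines:
        raise ExpressionParseError(f"{path}: no data rows (file is empty)")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    if len(sample_ids) == 0:
        raise ExpressionParseError(f"{path}: header has no sample columns")
    if len(set(sample_ids)) != len(sample_ids):
        dup = next(s for s in sample_ids if sample_ids.count(s) > 1)
        raise ExpressionParseError(f"{path}: duplicate sample id {dup!r} in header")
    if len(lines) == 1:
        raise ExpressionParseError(f"{path}: no data rows")

    gene_ids: list[str] = []
    seen: set[str] = set()
    rows = np.empty((len(lines) - 1, len(sample_ids)), dtype=float)
    for k, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(sample_ids) + 1:
            raise ExpressionParseError(
                f"{path}: line {k}: expected {len(sample_ids) + 1} fields, got {len(fields)}"
            )
        gid = fields[0]
        if gid in seen:
            raise ExpressionParseError(f"{path}: line {k}: duplicate gene id {gid!r}")
        seen.add(gid)
        gene_ids.append(gid)
        try:
            rows[k - 2] = [float(x) if x not in ("", "NA", "nan") else np.nan for x in fields[1:]]
        except ValueError as exc:
            raise ExpressionParseError(f"{path}: line {k}: non-numeric value ({exc})") from None
    return pd.DataFrame(rows, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)


def write_expression_table(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


def read_groups_table(path) -> pd.Series:
    """Read a two-column sample_id<TAB>condition map (header optional)."""
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if not lines:
        raise ExpressionParseError(f"{path}: no data rows")
    pairs = []
    for k, line in enumerate(lines, start=1):
        fields = line.split("\t")
        if len(fields) != 2:
            raise ExpressionParseError(f"{path}: line {k}: expected 2 fields, got {len(fields)}")
        pairs.append(fields)
    # tolerate a header row such as "sample_id\tcondition"
    if pairs and pairs[0][0].lower() in ("sample", "sample_id", "id"):
        pairs = pairs[1:]
    ids = [p[0] for p in pairs]
    if len(set(ids)) != len(ids):
        dup = next(s for s in ids if ids.count(s) > 1)
        raise ExpressionParseError(f"{path}: duplicate sample id {dup!r}")
    return pd.Series({s: c for s, c in pairs}, name="condition")


def write_groups_table(groups: pd.Series, path) -> None:
    groups.rename_axis("sample_id").to_frame().to_csv(path, sep="\t")


_PRESENT = {"P", "p", "1", "TRUE", "True", "true"}
_ABSENT = {"A", "a", "M", "m", "0", "FALSE", "False", "false"}


def read_flags_table(path) -> pd.DataFrame:
    """Read a detection-call matrix aligned to an expression table.

    Accepts Affymetrix P/M/A calls (P = present, M/A = not present) or
    boolean/0-1 values; returns a boolean DataFrame.
    """
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if len(lines) < 2:
        raise ExpressionParseError(f"{path}: no data rows")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    gene_ids = []
    values = np.empty((len(lines) - 1, len(sample_ids)), dtype=bool)
    for k, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(sample_ids) + 1:
            raise ExpressionParseError(
                f"{path}: line {k}: expected {len(sample_ids) + 1} fields, got {len(fields)}"
            )
        gene_ids.append(fields[0])
        for j, tok in enumerate(fields[1:]):
            if tok in _PRESENT:
                values[k - 2, j] = True
            elif tok in _ABSENT:
                values[k - 2, j] = False
            else:
                raise ExpressionParseError(f"{path}: line {k}: unrecognized call {tok!r}")
    return pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Assert the ExpressionMatrix invariants on an in-memory frame."""
    if expr.index.has_duplicates:
        dup = expr.index[expr.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r}")
    if expr.columns.has_duplicates:
        dup = expr.columns[expr.columns.duplicated()][0]
        raise ValueError(f"duplicate sample id {dup!r}")
    if expr.shape[0] == 0 or expr.shape[1] == 0:
        raise ValueError("empty expression matrix")
    return expr


def validate_groups(expr: pd.DataFrame, groups: pd.Series, min_per_group: int = 1) -> pd.Series:
    """Check every sample has a condition and conditions are adequately populated."""
    missing = [s for s in expr.columns if s not in groups.index]
    if missing:
        raise ValueError(f"samples without a condition label: {missing[:5]}")
    groups = groups.loc[expr.columns]
    counts = groups.value_counts()
    small = counts[counts < min_per_group]
    if len(small):
        raise ValueError(
            f"condition(s) with fewer than {min_per_group} samples: {dict(small)}"
        )
    return groups


def write_matrix(matrix: np.ndarray, ids, path) -> None:
    """Write a square gene x gene matrix (adjacency/TOM) as TSV, gzipped if the path ends .gz."""
    df = pd.DataFrame(matrix, index=ids, columns=ids)
    df.to_csv(path, sep="\t", index_label="gene_id")
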