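"""Readers and writers for the tabular formats the pipeline touches.

Expression matrices (TSV or GCT v1.2), sample annotations, probe-to-gene
maps, cell-type aggregation maps, signature matrices and fraction tables
are all plain delimited text.  In memory an expression matrix is a pandas
``DataFrame`` with feature IDs on the index and sample IDs on the columns;
values are normalized expression intensities (typically log2 scale from
upstream RMA-style preprocessing).

All readers skip ``#``-prefixed provenance comment lines, enforce the
structural invariants (unique IDs, finite values) and raise
:class:`ExpressionIOError` with an explicit message rather than silently
dropping or coercing rows.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Replicate count below which a cell type is flagged as thinly sampled.
#: The reference compendium this tool is modeled on recruited at least
#: nine replicate arrays per immune cell type.
MIN_REPLICATES_WARN = 9


class ExpressionIOError(ValueError):
    """Malformed input file (duplicates, non-numeric cells, empty matrix...)."""


def _find_duplicates(values) -> list:
    seen: set = set()
    dups: list = []
    for v in values:
        if v in seen and v not in dups:
            dups.append(v)
        seen.add(v)
    return dups


def validate_expression_matrix(df: pd.DataFrame, *, what: str = "expression matrix") -> pd.DataFrame:
    """Enforce the expression-matrix invariants on ``df`` and return it.

    Checks: non-empty, unique feature and sample IDs, all-finite numeric
    values.  Raises :class:`ExpressionIOError` naming the offender.
    """
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ExpressionIOError(f"empty {what}: shape {df.shape}")
    dup_rows = _find_duplicates(df.index)
    if dup_rows:
        raise ExpressionIOError(f"duplicate feature IDs in {what}: {dup_rows[:5]}")
    dup_cols = _find_duplicates(df.columns)
    if dup_cols:
        raise ExpressionIOError(f"duplicate sample IDs in {what}: {dup_cols[:5]}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ExpressionIOError(f"non-numeric value in {what}: {exc}") from exc
    if not np.isfinite(values).all():
        bad = np.argwhere(~np.isfinite(values))[0]
        raise ExpressionIOError(
            f"non-finite value in {what} at feature "
            f"{df.index[bad[0]]!r}, sample {df.columns[bad[1]]!r}"
        )
    out = pd.DataFrame(values, index=df.index.astype(str), columns=df.columns.astype(str))
    out.index.name = df.index.name or "feature_id"
    return out


def read_expression_matrix(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Read an expression matrix from TSV or GCT v1.2.

    Parameters
    ----------
    path:
        File with a header row of sample IDs and feature IDs in the first
        column.  GCT files carry two extra header lines and a Description
        column, which is dropped.
    fmt:
        ``"tsv"`` or ``"gct"``; inferred from the suffix when ``None``.

    Returns
    -------
    DataFrame of shape (features, samples) with finite float values.
    """
    path = Path(path)
    if not path.exists():
        raise ExpressionIOError(f"no such file: {path}")
    if fmt is None:
        fmt = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if fmt == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if not version.startswith("#1."):
                raise ExpressionIOError(f"{path}: not a GCT v1.x file (first line {version!r})")
            dims = fh.readline().split()
            df = pd.read_csv(fh, sep="\t", index_col=0)
        if "Description" in df.columns:
            df = df.drop(columns=["Description"])
        elif df.columns.size and df.columns[0].lower() == "description":
            df = df.drop(columns=[df.columns[0]])
        if len(dims) >= 2 and int(dims[0]) != df.shape[0]:
            raise ExpressionIOError(
                f"{path}: GCT header declares {dims[0]} rows but {df.shape[0]} were read"
            )
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'tsv' or 'gct'")
    return validate_expression_matrix(df, what=str(path))


def write_expression_matrix(df: pd.DataFrame, path: str | Path, *, header_lines: list[str] | None = None) -> None:
    """Write an expression or signature matrix as TSV, with optional ``#`` provenance lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index_label=df.index.name or "feature_id")


def read_sample_annotation(path: str | Path) -> pd.DataFrame:
    """Read a sample annotation table (sample_id, cell_type[, subtype_or_treatment]).

    Returns a DataFrame indexed by sample_id with a ``cell_type`` column and
    an optional ``subtype_or_treatment`` column.  Warns when any cell type
    has fewer than :data:`MIN_REPLICATES_WARN` replicates.
    """
    path = Path(path)
    if not path.exists():
        raise ExpressionIOError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ExpressionIOError(f"{path}: need at least sample_id and cell_type columns")
    df = df.rename(
        columns={df.columns[0]: "sample_id", df.columns[1]: "cell_type"}
    )
    if df.shape[1] >= 3:
        df = df.rename(columns={df.columns[2]: "subtype_or_treatment"})
    dups = _find_duplicates(df["sample_id"])
    if dups:
        raise ExpressionIOError(f"{path}: sample(s) listed twice: {dups[:5]}")
    if df["cell_type"].isna().any() or (df["cell_type"].str.strip() == "").any():
        bad = df.loc[df["cell_type"].isna() | (df["cell_type"].str.strip() == ""), "sample_id"]
        raise ExpressionIOError(f"{path}: empty cell-type label for sample(s) {list(bad[:5])}")
    ann = df.set_index("sample_id")
    census = ann["cell_type"].value_counts()
    thin = census[census < MIN_REPLICATES_WARN]
    if len(thin):
        warnings.warn(
            "cell type(s) with fewer than "
            f"{MIN_REPLICATES_WARN} replicates: {dict(thin)}; "
            "medians and ANOVA will be less stable",
            stacklevel=2,
        )
    return ann


def cell_type_census(ann: pd.DataFrame) -> pd.Series:
    """Replicate count per cell type, sorted by label."""
    return ann["cell_type"].value_counts().sort_index()


def read_probe_gene_map(path: str | Path) -> pd.Series:
    """Read a two-column probe_id -> gene_symbol map.

    Many probes may map to one gene, but a probe mapped to two distinct
    genes is an error.  An empty file yields an empty map (downstream
    collapsing becomes the identity).
    """
    path = Path(path)
    if not path.exists():
        raise ExpressionIOError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#", header=None)
    except pd.errors.EmptyDataError:
        return pd.Series(dtype=str, name="gene_symbol")
    # Tolerate a header line naming the columns.
    if df.iloc[0, 0].lower() in {"probe_id", "probe", "probeset", "probe_set_id"}:
        df = df.iloc[1:]
    if df.shape[1] < 2:
        raise ExpressionIOError(f"{path}: need two columns (probe_id, gene_symbol)")
    df = df.iloc[:, :2]
    df.columns = ["probe_id", "gene_symbol"]
    conflicts = df.drop_duplicates().groupby("probe_id")["gene_symbol"].nunique()
    bad = conflicts[conflicts > 1]
    if len(bad):
        raise ExpressionIOError(f"{path}: probe(s) mapped to multiple genes: {list(bad.index[:5])}")
    out = df.drop_duplicates().set_index("probe_id")["gene_symbol"]
    return out


def read_cell_type_map(path: str | Path) -> dict[str, list[str]]:
    """Read a cell-type aggregation map.

    Each line: ``assay_cell_type<TAB>predicted_type[,predicted_type...]``.
    Every predicted (signature) cell type may appear in at most one group.
    """
    path = Path(path)
    if not path.exists():
        raise ExpressionIOError(f"no such file: {path}")
    groups: dict[str, list[str]] = {}
    seen: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ExpressionIOError(f"{path}:{lineno}: need assay type and member list")
            assay = parts[0].strip()
            members = [m.strip() for m in parts[1].split(",") if m.strip()]
            if assay in groups:
                raise ExpressionIOError(f"{path}:{lineno}: assay type {assay!r} listed twice")
            for m in members:
                if m in seen:
                    raise ExpressionIOError(
                        f"{path}:{lineno}: predicted type {m!r} already in group {seen[m]!r}"
                    )
                seen[m] = assay
            groups[assay] = members
    return groups


def write_fraction_table(fractions: pd.DataFrame, path: str | Path, *, header_lines: list[str] | None = None) -> None:
    """Write a samples x cell-types fraction table with a trailing row-sum column."""
    out = fractions.copy()
    out["row_sum"] = out.sum(axis=1)
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        out.to_csv(fh, sep="\t", index_label="sample_id")


def read_fraction_table(path: str | Path) -> pd.DataFrame:
    """Read a fraction table written by :func:`write_fraction_table`."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if "row_sum" in df.columns:
        df = df.drop(columns=["row_sum"])
    return df
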