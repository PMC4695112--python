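"""Expression matrices and sample metadata: I/O, normalisation, collapsing.

Expression values are strictly positive, linear-scale intensities (genes in
rows, samples in columns).  The sample table maps array samples to biological
cell lines and group labels (ESC, iPSC, FIB, EB, or any free label); every
line belongs to exactly one group.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleTable",
    "ExpressionValidationError",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_sample_table",
    "write_sample_table",
    "quantile_normalize",
    "average_replicates",
]


class ExpressionValidationError(ValueError):
    """Expression data or metadata violates a structural invariant."""


class ExpressionMatrix:
    """Genes × samples matrix of strictly positive, finite intensities."""

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise ExpressionValidationError(f"duplicate gene identifier(s): {dupes}")
        if data.columns.has_duplicates:
            dupes = data.columns[data.columns.duplicated()].unique().tolist()
            raise ExpressionValidationError(f"duplicate sample identifier(s): {dupes}")
        if data.empty:
            raise ExpressionValidationError("expression matrix is empty")
        values = data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = data.columns[
                ~data.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())
            ].tolist()
            raise ExpressionValidationError(
                f"non-numeric values in sample column(s): {bad}"
            )
        bad_mask = ~np.isfinite(values) | (values <= 0)
        if bad_mask.any():
            gi, si = np.argwhere(bad_mask)[0]
            raise ExpressionValidationError(
                f"non-positive or non-finite value {values[gi, si]!r} at "
                f"gene {data.index[gi]!r}, sample {data.columns[si]!r}"
            )
        self.data = data.astype(float)

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def equals(self, other: "ExpressionMatrix") -> bool:
        return self.data.equals(other.data)

    def __repr__(self) -> str:
        g, s = self.shape
        return f"ExpressionMatrix({g} genes × {s} samples)"


class SampleTable:
    """Per-sample metadata: sample_id → (line_id, group)."""

    COLUMNS = ("sample_id", "line_id", "group")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ExpressionValidationError(f"sample table lacks column(s): {missing}")
        frame = frame.loc[:, list(self.COLUMNS)].astype(str).reset_index(drop=True)
        if frame["sample_id"].duplicated().any():
            dupes = frame.loc[frame["sample_id"].duplicated(), "sample_id"].tolist()
            raise ExpressionValidationError(f"duplicate sample_id(s): {dupes}")
        groups_per_line = frame.groupby("line_id")["group"].nunique()
        conflicted = groups_per_line[groups_per_line > 1].index.tolist()
        if conflicted:
            raise ExpressionValidationError(
                f"line(s) mapped to more than one group: {conflicted}"
            )
        self.frame = frame

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.frame["sample_id"])

    def line_of(self, sample_id: str) -> str:
        row = self.frame.loc[self.frame["sample_id"] == sample_id, "line_id"]
        if row.empty:
            raise KeyError(sample_id)
        return row.iloc[0]

    def group_of_line(self, line_id: str) -> str:
        row = self.frame.loc[self.frame["line_id"] == line_id, "group"]
        if row.empty:
            raise KeyError(line_id)
        return row.iloc[0]

    def lines(self, group: str | None = None) -> list[str]:
        """Line ids, optionally restricted to one group, first-appearance order."""
        frame = self.frame if group is None else self.frame[self.frame["group"] == group]
        return list(dict.fromkeys(frame["line_id"]))

    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.frame["group"]))

    def samples_of_line(self, line_id: str) -> list[str]:
        return self.frame.loc[self.frame["line_id"] == line_id, "sample_id"].tolist()

    def collapse_to_lines(self) -> "SampleTable":
        """One row per line, with sample_id = line_id."""
        frame = (
            self.frame.drop_duplicates("line_id")
            .assign(sample_id=lambda f: f["line_id"])
            .reset_index(drop=True)
        )
        return SampleTable(frame)

    def __len__(self) -> int:
        return len(self.frame)

    def __repr__(self) -> str:
        counts = self.frame.drop_duplicates("line_id")["group"].value_counts()
        summary = ", ".join(f"{g}: {n}" for g, n in counts.items())
        return f"SampleTable({len(self)} samples; lines by group: {summary})"


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a genes × samples TSV (first column gene ids, header sample ids)."""
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        if coerced.isna().any():
            gene = frame.index[coerced.isna()][0]
            raise ExpressionValidationError(
                f"{path}: non-numeric value at gene {gene!r}, sample {col!r}"
            )
        frame[col] = coerced
    try:
        return ExpressionMatrix(frame)
    except ExpressionValidationError as exc:
        raise ExpressionValidationError(f"{path}: {exc}") from None


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV; values are written with full round-trip precision."""
    frame = matrix.data.copy()
    frame.index.name = "gene"
    frame.to_csv(path, sep="\t", lineterminator="\n")


def read_sample_table(path: str | Path) -> SampleTable:
    return SampleTable(pd.read_csv(path, sep="\t", dtype=str))


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample to the common (mean) quantile distribution.

    The reference distribution is the vector of row-wise means of the
    column-sorted matrix; each column's values are replaced by the reference
    value at their rank.  Ties within a column receive the mean of the
    reference values across the tied ranks, which keeps the result
    deterministic and rank-preserving.
    """
    if matrix.shape[1] < 2:
        raise ExpressionValidationError(
            "quantile normalisation needs at least 2 samples"
        )
    values = matrix.data.to_numpy()
    reference = np.sort(values, axis=0).mean(axis=1)
    # average ranks (1-based); half-integer ranks interpolate the reference
    ranks = matrix.data.rank(method="average").to_numpy()
    lo = np.floor(ranks).astype(int) - 1
    hi = np.ceil(ranks).astype(int) - 1
    normalized = (reference[lo] + reference[hi]) / 2.0
    out = pd.DataFrame(normalized, index=matrix.genes, columns=matrix.samples)
    return ExpressionMatrix(out)


def average_replicates(
    matrix: ExpressionMatrix, table: SampleTable
) -> tuple[ExpressionMatrix, SampleTable]:
    """Collapse replicate sample columns to one column per cell line.

    Averaging is the arithmetic mean on the linear intensity scale.  Returns
    the collapsed matrix (columns keyed by line_id, in the sample table's
    line order) and the matching per-line sample table.
    """
    known = set(table.sample_ids)
    missing = [s for s in matrix.samples if s not in known]
    if missing:
        raise ExpressionValidationError(
            f"sample(s) absent from the sample table: {missing}"
        )
    lines = [
        line
        for line in table.lines()
        if any(s in matrix.samples for s in table.samples_of_line(line))
    ]
    collapsed = pd.DataFrame(
        {
            line: matrix.data[
                [s for s in table.samples_of_line(line) if s in matrix.samples]
            ].mean(axis=1)
            for line in lines
        },
        index=matrix.genes,
    )
    line_table = SampleTable(
        table.frame[table.frame["line_id"].isin(lines)]
    ).collapse_to_lines()
    return ExpressionMatrix(collapsed), line_table
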