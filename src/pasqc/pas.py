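"""Pathway activation scoring against a control sample group.

For a case line and a pathway p, the pathway activation score is

    PAS_p = sum over member genes n of  ARR_np * BTIF_n * log10(CNR_n)

where CNR_n is the ratio of the case expression of gene n to the control
aggregate (the geometric mean across control lines), BTIF_n is a 0/1
"beyond tolerance interval" flag admitting only genes whose log-ratio exceeds
a tolerance band, and ARR_np is the gene's discrete activator/repressor role
weight in the pathway.  A positive PAS means net activation of the pathway in
the case line relative to the controls.

The tolerance band is variance-aware: gene n is flagged when

    |log10 CNR_n| > max(k * SD_n, floor)

with SD_n the standard deviation of log10 expression across the control
lines, k a band multiplier (default 2.0) and a fixed floor (default 0.1
log10 units, i.e. ~1.26-fold) guarding genes with near-zero control variance.

When a case line is itself a control (e.g. fibroblasts scored against the
fibroblast reference), the ``leave_one_out`` policy rebuilds the reference
without that line so no line is compared against itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .pathway_db import Pathway, PathwayDB

__all__ = [
    "BTIFParams",
    "ReferenceModel",
    "PASMatrix",
    "PASError",
    "build_reference",
    "compute_cnr",
    "compute_btif",
    "compute_pas",
    "compute_pas_matrix",
    "read_pas_tsv",
    "write_pas_tsv",
]

Policy = Literal["pooled", "leave_one_out"]


class PASError(ValueError):
    """Invalid input to the pathway scoring engine."""


@dataclass(frozen=True)
class BTIFParams:
    """Tolerance-band parameters for the beyond-tolerance-interval flag.

    k
        Multiplier on the per-gene control log10-SD (dimensionless, >= 0).
    floor
        Minimum absolute log10 fold-change required to flag a gene,
        regardless of control variance (log10 units, >= 0).
    """

    k: float = 2.0
    floor: float = 0.1

    def __post_init__(self) -> None:
        if self.k < 0 or self.floor < 0:
            raise PASError("BTIF parameters k and floor must be >= 0")


@dataclass(frozen=True)
class ReferenceModel:
    """Per-gene control aggregate: mean and SD of log10 expression."""

    log_mean: pd.Series
    log_sd: pd.Series
    control_line_ids: tuple[str, ...]
    policy: Policy = "pooled"

    def __post_init__(self) -> None:
        if (self.log_sd < 0).any():
            raise PASError("reference log-SD must be non-negative")
        if not self.log_mean.index.equals(self.log_sd.index):
            raise PASError("reference mean and SD must share one gene index")

    @property
    def genes(self) -> pd.Index:
        return self.log_mean.index

    def describe(self) -> str:
        return (
            f"{self.policy} reference over {len(self.control_line_ids)} "
            f"control line(s): {', '.join(self.control_line_ids)}"
        )


class PASMatrix:
    """Pathways × lines matrix of pathway activation scores."""

    def __init__(self, data: pd.DataFrame, reference: str = ""):
        values = data.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise PASError("PAS values must be finite")
        if data.index.has_duplicates or data.columns.has_duplicates:
            raise PASError("pathway and line identifiers must be unique")
        self.data = data.astype(float)
        self.reference = reference

    @property
    def pathways(self) -> pd.Index:
        return self.data.index

    @property
    def lines(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_lines(self, lines: Sequence[str]) -> "PASMatrix":
        missing = [l for l in lines if l not in self.data.columns]
        if missing:
            raise PASError(f"line(s) not in PAS matrix: {missing}")
        return PASMatrix(self.data[list(lines)], self.reference)

    def __repr__(self) -> str:
        p, l = self.shape
        ref = f", reference: {self.reference}" if self.reference else ""
        return f"PASMatrix({p} pathways × {l} lines{ref})"


def build_reference(
    matrix: ExpressionMatrix,
    control_line_ids: Iterable[str],
    policy: Policy = "pooled",
) -> ReferenceModel:
    """Aggregate control lines into a per-gene log10 mean and SD.

    The mean is the arithmetic mean of log10 expression across control lines
    (i.e. the log of the geometric mean); the SD uses the n-1 denominator and
    is 0 when only one control line is present.
    """
    controls = tuple(dict.fromkeys(control_line_ids))
    if not controls:
        raise PASError("control line set is empty")
    unknown = [c for c in controls if c not in matrix.samples]
    if unknown:
        raise PASError(f"unknown control line id(s): {unknown}")
    if policy == "leave_one_out" and len(controls) < 2:
        raise PASError("leave_one_out reference needs at least 2 control lines")
    if policy not in ("pooled", "leave_one_out"):
        raise PASError(f"unknown reference policy {policy!r}")
    logs = np.log10(matrix.data[list(controls)])
    log_mean = logs.mean(axis=1)
    if len(controls) == 1:
        log_sd = pd.Series(0.0, index=matrix.genes)
    else:
        log_sd = logs.std(axis=1, ddof=1)
    return ReferenceModel(log_mean, log_sd, controls, policy)


def _align_case(case: pd.Series, ref: ReferenceModel) -> pd.Series:
    missing = case.index.difference(ref.genes)
    if len(missing):
        raise PASError(
            f"gene(s) present in case but absent from reference: "
            f"{missing[:5].tolist()}"
        )
    if (case <= 0).any() or not np.isfinite(case).all():
        raise PASError("case expression values must be strictly positive and finite")
    return case


def compute_cnr(case: pd.Series, ref: ReferenceModel) -> pd.Series:
    """Case-to-normal ratio per gene: case / geometric mean of controls."""
    case = _align_case(case, ref)
    return case / np.power(10.0, ref.log_mean.loc[case.index])


def compute_btif(
    case: pd.Series, ref: ReferenceModel, params: BTIFParams = BTIFParams()
) -> pd.Series:
    """Beyond-tolerance-interval flag per gene (0 or 1)."""
    case = _align_case(case, ref)
    log_ratio = np.log10(case) - ref.log_mean.loc[case.index]
    band = np.maximum(params.k * ref.log_sd.loc[case.index], params.floor)
    return (log_ratio.abs() > band).astype(int)


def compute_pas(
    case: pd.Series,
    pathway: Pathway,
    ref: ReferenceModel,
    params: BTIFParams = BTIFParams(),
    missing_genes: Literal["warn", "strict", "ignore"] = "warn",
) -> float:
    """Pathway activation score of one case column for one pathway."""
    present = [m for m in pathway.members if m.gene in case.index]
    absent = [m.gene for m in pathway.members if m.gene not in case.index]
    if absent:
        if missing_genes == "strict":
            raise PASError(
                f"pathway {pathway.name!r}: gene(s) missing from matrix: {absent}"
            )
        if missing_genes == "warn":
            warnings.warn(
                f"pathway {pathway.name!r}: skipping {len(absent)} gene(s) "
                f"missing from the expression matrix",
                stacklevel=2,
            )
    if not present:
        return 0.0
    genes = [m.gene for m in present]
    arr = np.array([m.arr for m in present])
    sub = case.loc[genes]
    log_ratio = np.log10(compute_cnr(sub, ref)).to_numpy()
    btif = compute_btif(sub, ref, params).to_numpy()
    return float(np.sum(arr * btif * log_ratio))


def _membership_matrix(
    db: PathwayDB,
    genes: pd.Index,
    missing_genes: Literal["warn", "strict", "ignore"],
) -> pd.DataFrame:
    """Pathways × genes ARR weight matrix restricted to genes on the chip."""
    weights = pd.DataFrame(
        0.0, index=pd.Index(db.names, name="pathway"), columns=genes
    )
    for pathway in db:
        absent = [g for g in pathway.genes if g not in genes]
        if absent:
            if missing_genes == "strict":
                raise PASError(
                    f"pathway {pathway.name!r}: gene(s) missing from matrix: "
                    f"{absent[:5]}"
                )
            if missing_genes == "warn":
                warnings.warn(
                    f"pathway {pathway.name!r}: skipping {len(absent)} gene(s) "
                    f"missing from the expression matrix",
                    stacklevel=3,
                )
        for member in pathway.members:
            if member.gene in weights.columns:
                weights.at[pathway.name, member.gene] = member.arr
    return weights


def compute_pas_matrix(
    matrix: ExpressionMatrix,
    db: PathwayDB,
    control_line_ids: Iterable[str],
    params: BTIFParams = BTIFParams(),
    policy: Policy = "leave_one_out",
    missing_genes: Literal["warn", "strict", "ignore"] = "warn",
) -> PASMatrix:
    """Score every line of a replicate-collapsed matrix against the controls.

    Non-control lines are scored against the pooled control reference.
    Control lines are scored against a reference rebuilt with that line
    excluded when ``policy="leave_one_out"`` (the default), so no line is
    compared to a reference containing itself; with ``policy="pooled"`` they
    are scored against the full pooled reference.
    """
    controls = tuple(dict.fromkeys(control_line_ids))
    if not controls:
        raise PASError("control line set is empty")
    pooled = build_reference(matrix, controls, "pooled")
    weights = _membership_matrix(db, matrix.genes, missing_genes)
    logs = np.log10(matrix.data)

    columns: dict[str, np.ndarray] = {}
    for line in matrix.samples:
        if line in controls and policy == "leave_one_out":
            rest = [c for c in controls if c != line]
            if not rest:
                raise PASError(
                    "leave_one_out policy needs at least 2 control lines "
                    "to score a control line"
                )
            ref = build_reference(matrix, rest, "pooled")
        else:
            ref = pooled
        log_ratio = logs[line] - ref.log_mean
        band = np.maximum(params.k * ref.log_sd, params.floor)
        flagged = (log_ratio.abs() > band).to_numpy()
        contrib = log_ratio.to_numpy() * flagged
        columns[line] = weights.to_numpy() @ contrib

    data = pd.DataFrame(columns, index=weights.index)
    return PASMatrix(data, reference=pooled.describe() + f" [{policy}]")


def write_pas_tsv(pas: PASMatrix, path) -> None:
    frame = pas.data.copy()
    frame.index.name = "pathway"
    frame.to_csv(path, sep="\t", lineterminator="\n")


def read_pas_tsv(path) -> PASMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return PASMatrix(frame)
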