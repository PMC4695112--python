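"""Model/Results interface over the pathway-activation pipeline.

:class:`PathwayActivation` is the entry point: build it from an expression
matrix, a sample table and a pathway DB, call :meth:`~PathwayActivation.fit`
and work with the returned :class:`PathwayActivationResults` — group
significance tables, variability rankings, the deviation correlation, the
ESC quality corridor screen and the sparse iPSC-vs-fibroblast signature all
hang off the results object.

Example
-------
>>> from pasqc import simulate, models
>>> design = simulate.StudyDesign(seed=7)
>>> db = simulate.gen_pathway_db(design)
>>> expr, samples, truth = simulate.gen_study(db, design)
>>> res = models.PathwayActivation(expr, samples, db, reference_group="FIB").fit()
>>> screen = res.quality_screen(reference_group="ESC", case_group="iPSC")
>>> screen.flagged  # doctest: +SKIP
['iPSC02', 'iPSC03', 'iPSC01']
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import expression as eio
from . import pas as pas_mod
from . import qc as qc_mod
from . import signature as sig_mod
from . import stats as stats_mod
from .pas import BTIFParams, PASMatrix, Policy
from .pathway_db import PathwayDB

__all__ = [
    "PathwayActivation",
    "PathwayActivationResults",
    "QualityScreenResults",
    "SignatureResults",
]


class PathwayActivation:
    """Pathway activation scoring of cell lines against a reference group.

    Parameters
    ----------
    matrix
        Replicate-level (or already line-level) expression matrix, strictly
        positive linear intensities.
    samples
        Sample table mapping samples to line ids and group labels.
    db
        Pathway DB with ARR topology weights.
    reference_group
        Group label of the control lines (default ``"FIB"``).
    btif
        Tolerance-band parameters for the beyond-tolerance flag.
    policy
        ``"leave_one_out"`` (default) scores control lines against a
        reference excluding themselves; ``"pooled"`` does not.
    quantile_norm
        Quantile-normalise the matrix before replicate averaging.
    """

    def __init__(
        self,
        matrix: eio.ExpressionMatrix,
        samples: eio.SampleTable,
        db: PathwayDB,
        reference_group: str = "FIB",
        btif: BTIFParams = BTIFParams(),
        policy: Policy = "leave_one_out",
        quantile_norm: bool = False,
        missing_genes: str = "warn",
    ):
        self.matrix = matrix
        self.samples = samples
        self.db = db
        self.reference_group = reference_group
        self.btif = btif
        self.policy = policy
        self.quantile_norm = quantile_norm
        self.missing_genes = missing_genes

    @classmethod
    def from_files(
        cls,
        expression_path: str | Path,
        samples_path: str | Path,
        pathways_path: str | Path,
        **kwargs,
    ) -> "PathwayActivation":
        from .pathway_db import read_pathway_table

        return cls(
            eio.read_expression_tsv(expression_path),
            eio.read_sample_table(samples_path),
            read_pathway_table(pathways_path),
            **kwargs,
        )

    def fit(self) -> "PathwayActivationResults":
        """Collapse replicates, build the reference, and score every line."""
        matrix = self.matrix
        if self.quantile_norm:
            matrix = eio.quantile_normalize(matrix)
        line_matrix, line_table = eio.average_replicates(matrix, self.samples)
        controls = line_table.lines(self.reference_group)
        if not controls:
            raise pas_mod.PASError(
                f"no lines in reference group {self.reference_group!r}"
            )
        pas = pas_mod.compute_pas_matrix(
            line_matrix,
            self.db,
            controls,
            params=self.btif,
            policy=self.policy,
            missing_genes=self.missing_genes,  # type: ignore[arg-type]
        )
        return PathwayActivationResults(self, pas, line_table)


class PathwayActivationResults:
    """Fitted PAS matrix plus the downstream analyses."""

    def __init__(
        self,
        model: PathwayActivation,
        pas: PASMatrix,
        line_table: eio.SampleTable,
    ):
        self.model = model
        self.pas = pas
        self.line_table = line_table

    def lines(self, group: str | None = None) -> list[str]:
        return self.line_table.lines(group)

    def group_pas(self, group: str) -> PASMatrix:
        lines = self.lines(group)
        if not lines:
            raise stats_mod.StatsError(f"no lines in group {group!r}")
        return self.pas.subset_lines(lines)

    def group_test(self, group: str) -> pd.DataFrame:
        """Per-pathway one-sample t-test of the group's PAS against 0."""
        return stats_mod.pathway_group_test(self.pas, self.lines(group))

    def significant(
        self, group: str, q_max: float = 0.05, p_max: float | None = None
    ) -> list[str]:
        return stats_mod.significant_pathways(self.group_test(group), q_max, p_max)

    def variability(self, group: str) -> pd.DataFrame:
        """SD of PAS across the group's lines, ranked (1 = most variable)."""
        return stats_mod.variability_rank(self.pas, self.lines(group))

    def shared_variable(
        self, group_a: str, group_b: str, k: int = 20, end: str = "most"
    ) -> tuple[int, list[str]]:
        return stats_mod.shared_top(
            self.variability(group_a), self.variability(group_b), k, end  # type: ignore[arg-type]
        )

    def cluster(self, top_n: int = 50, groups: Sequence[str] | None = None):
        """Hierarchical clustering of the top-n most variable pathways."""
        lines = None
        if groups is not None:
            lines = [l for g in groups for l in self.lines(g)]
        return stats_mod.cluster_pas(self.pas, top_n=top_n, group_lines=lines)

    def quality_screen(
        self,
        reference_group: str = "ESC",
        case_group: str = "iPSC",
        pathway_subset: Sequence[str] | str = "significant",
        threshold: float = 0.5,
        q_max: float = 0.05,
        corridor_width: float = 1.0,
    ) -> "QualityScreenResults":
        """Score case lines against the reference group's PAS corridor.

        ``pathway_subset="significant"`` (default) restricts the corridor to
        pathways dysregulated in the reference group at q < ``q_max``;
        ``"all"`` keeps every pathway; an explicit list is used verbatim.
        """
        if isinstance(pathway_subset, str):
            if pathway_subset == "significant":
                subset = stats_mod.significant_pathways(
                    self.group_test(reference_group), q_max=q_max
                )
            elif pathway_subset == "all":
                subset = None
            else:
                raise qc_mod.QCError(
                    f"pathway_subset must be 'significant', 'all' or a list, "
                    f"got {pathway_subset!r}"
                )
        else:
            subset = list(pathway_subset)
        corridor = qc_mod.build_corridor(
            self.group_pas(reference_group), subset, width=corridor_width
        )
        report = qc_mod.quality_score(self.group_pas(case_group), corridor, threshold)
        return QualityScreenResults(corridor, report, threshold)

    def signature(
        self,
        positive_group: str = "FIB",
        negative_group: str = "iPSC",
        lambda_grid: Sequence[float] | None = None,
        seed: int = 42,
        loocv: bool = True,
    ) -> "SignatureResults":
        """Sparse classifier separating two groups on pathway PAS features.

        The positive class (label 1) defaults to fibroblasts so positive
        coefficients mark pathways with higher PAS in fibroblasts.
        """
        lines = self.lines(negative_group) + self.lines(positive_group)
        labels = pd.Series(
            {l: int(self.line_table.group_of_line(l) == positive_group) for l in lines}
        )
        sub = self.pas.subset_lines(lines)
        model = sig_mod.fit_signature(sub, labels, lambda_grid=lambda_grid, seed=seed)
        accuracy, predictions = (None, None)
        if loocv:
            accuracy, predictions = sig_mod.loocv_accuracy(
                sub, labels, lambda_grid=lambda_grid, seed=seed
            )
        return SignatureResults(
            model, labels, accuracy, predictions, positive_group, negative_group
        )

    def summary(self) -> str:
        lines = []
        lines.append("Pathway activation results")
        lines.append("=" * 26)
        lines.append(f"pathways: {len(self.pas.pathways)}")
        counts = {g: len(self.lines(g)) for g in self.line_table.groups()}
        lines.append(
            "lines:    " + ", ".join(f"{g}: {n}" for g, n in counts.items())
        )
        lines.append(f"reference: {self.pas.reference}")
        for group, n in counts.items():
            if n >= 3:
                sig = self.significant(group)
                lines.append(
                    f"{group}: {len(sig)} of {len(self.pas.pathways)} pathways "
                    f"dysregulated at q < 0.05"
                )
        return "\n".join(lines)

    def plot_heatmap(self, top_n: int = 50, path: str | Path | None = None):
        """Clustered PAS heat map of the top-n most variable pathways."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        result = self.cluster(top_n=top_n)
        frame = self.pas.data.loc[list(result.pathway_order), list(result.line_order)]
        fig, ax = plt.subplots(
            figsize=(max(6, 0.25 * len(frame.columns)), max(6, 0.14 * len(frame)))
        )
        vmax = abs(frame.to_numpy()).max() or 1.0
        mesh = ax.pcolormesh(frame.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        ax.set_xticks([i + 0.5 for i in range(len(frame.columns))])
        ax.set_xticklabels(frame.columns, rotation=90, fontsize=6)
        ax.set_yticks([i + 0.5 for i in range(len(frame))])
        ax.set_yticklabels(frame.index, fontsize=5)
        fig.colorbar(mesh, ax=ax, label="PAS")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


@dataclass
class QualityScreenResults:
    """Corridor, per-line quality report, and flagged outliers."""

    corridor: qc_mod.Corridor
    report: pd.DataFrame
    threshold: float

    @property
    def flagged(self) -> list[str]:
        return qc_mod.flag_outliers(self.report, self.threshold)

    def summary(self) -> str:
        lines = [
            "Quality screen",
            "=" * 14,
            f"corridor: {self.corridor.source}, {len(self.corridor)} pathways",
            f"threshold: {self.threshold:.0%} of {len(self.corridor)} "
            f"= {self.threshold * len(self.corridor):.0f} pathways in band",
        ]
        ordered = self.report.sort_values("fraction")
        for line_id, row in ordered.iterrows():
            mark = "FLAG" if row["fraction"] < self.threshold else "ok"
            lines.append(
                f"  {line_id}: {int(row['n_within'])}/{int(row['n_total'])} "
                f"({row['fraction']:.1%}) {mark}"
            )
        return "\n".join(lines)


@dataclass
class SignatureResults:
    """Fitted sparse signature with optional LOOCV assessment."""

    model: sig_mod.SignatureModel
    labels: pd.Series
    loocv_accuracy_: float | None
    loocv_predictions: pd.Series | None
    positive_group: str
    negative_group: str

    @property
    def selected(self) -> list[str]:
        return self.model.selected

    @property
    def coefficients(self) -> pd.Series:
        return self.model.coefficients[self.model.coefficients != 0.0]

    def summary(self) -> str:
        lines = [
            "Pathway signature "
            f"({self.positive_group} = 1 vs {self.negative_group} = 0)",
            "=" * 40,
            f"lambda: {self.model.lambda_:g}   "
            f"selected pathways: {len(self.selected)}",
        ]
        if self.loocv_accuracy_ is not None:
            lines.append(f"LOOCV accuracy: {self.loocv_accuracy_:.1%}")
        for name, coef in self.coefficients.sort_values().items():
            side = self.positive_group if coef > 0 else self.negative_group
            lines.append(f"  {name}: {coef:+.3f} (higher PAS in {side})")
        return "\n".join(lines)
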