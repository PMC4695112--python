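"""Synthetic expression studies with known ground truth.

Emulates the design of the reference compendium the pipeline targets: a
panel of ESC, iPSC, fibroblast and embryoid-body (EB) cell lines profiled
with replicates on a single array platform, scored against the fibroblast
group.  The generative model works on the log10 scale and is aligned with
the pathway topology weights so the expected PAS of every pathway is known
analytically:

* every gene has a baseline log10 intensity  b_g ~ Normal(loc, scale²);
* each pathway p carries a variability multiplier f_p ~ LogNormal(0, τ²)
  that scales the line-to-line noise of its member genes in the pluripotent
  groups — this is what makes some pathways reproducibly "most variable"
  and others quiet; fibroblast controls, a homogeneous somatic cell type,
  keep unscaled baseline noise;
* pluripotent lines (ESC and iPSC) shift every member gene of each
  stem-program pathway by δ·ARR, so those pathways' PAS is pushed positive
  by construction; EB lines receive the same shift attenuated by a factor;
  fibroblasts sit at baseline;
* planted "impaired" iPSC lines additionally shift a random subset of the
  stem-program pathways by a magnitude expressed in corridor half-widths
  (the SD of PAS across ESC lines), converted analytically to a per-gene
  log10 shift, with a random sign per pathway;
* each line carries a coherent pathway-activity effect per pathway,
  η_lp ~ Normal(0, (σ_act·f_p)²), applied as η_lp·ARR to every member gene —
  this models genuine line-to-line differences in pathway activation (the
  reason some pathways are reproducibly "most variable" across lines) as
  opposed to per-gene technical noise;
* per-gene line noise Normal(0, (σ_line·f_p)²) and per-replicate
  measurement noise Normal(0, σ_meas²) complete the model.

Everything is seeded and reproducible; the returned ground truth records
group membership, the stem-program pathway set, and the planted
impairments with their expected PAS displacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, SampleTable
from .pathway_db import ALLOWED_ARR, GeneRole, Pathway, PathwayDB

__all__ = [
    "DesignError",
    "ImpairedLineSpec",
    "StudyDesign",
    "GroundTruth",
    "gen_pathway_db",
    "gen_study",
]


class DesignError(ValueError):
    """Invalid synthetic study design."""


@dataclass(frozen=True)
class ImpairedLineSpec:
    """A planted low-quality iPSC line.

    line_index
        Index of the line within the iPSC group (0-based).
    fraction
        Fraction of the stem-program (corridor) pathways dysregulated.
    shift_halfwidths
        Magnitude of each dysregulated pathway's PAS displacement, in units
        of the corridor half-width (the SD of PAS across ESC lines).
    """

    line_index: int
    fraction: float = 0.6
    shift_halfwidths: float = 3.0

    def __post_init__(self) -> None:
        if self.line_index < 0:
            raise DesignError("impaired line_index must be >= 0")
        if not 0 <= self.fraction <= 1:
            raise DesignError("impaired fraction must lie in [0, 1]")
        if self.shift_halfwidths < 0:
            raise DesignError("shift_halfwidths must be >= 0")


def _default_impaired() -> tuple[ImpairedLineSpec, ...]:
    return tuple(ImpairedLineSpec(i) for i in range(3))


def _default_arr_probs() -> dict[float, float]:
    return {1.0: 0.5, 0.5: 0.2, -1.0: 0.2, -0.5: 0.1}


@dataclass(frozen=True)
class StudyDesign:
    """Parameters of a synthetic study; defaults mirror the target compendium.

    Group sizes default to 20 ESC, 12 iPSC, 6 fibroblast and 5 EB lines with
    two replicates each; the pathway collection defaults to 271 pathways of
    8–25 genes (≈4500 gene roles).  Effects and noise are in log10 units.
    """

    n_esc: int = 20
    n_ipsc: int = 12
    n_fib: int = 6
    n_eb: int = 5
    replicates: int = 2
    n_pathways: int = 271
    genes_per_pathway: tuple[int, int] = (8, 25)
    arr_probs: Mapping[float, float] = field(default_factory=_default_arr_probs)
    stem_fraction: float = 0.7
    stem_effect: float = 0.5
    impaired: tuple[ImpairedLineSpec, ...] = field(default_factory=_default_impaired)
    baseline_log_mean: float = 2.5
    baseline_log_sd: float = 0.5
    line_sd: float = 0.05
    activity_sd: float = 0.1
    meas_sd: float = 0.05
    eb_attenuation: float = 0.3
    pathway_noise_spread: float = 1.2
    shared_variance_profile: bool = True
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("n_esc", "n_ipsc", "n_fib", "n_eb"):
            if getattr(self, name) < 0:
                raise DesignError(f"{name} must be >= 0")
        if self.replicates < 1:
            raise DesignError("replicates must be >= 1")
        if self.n_pathways < 1:
            raise DesignError("n_pathways must be >= 1")
        lo, hi = self.genes_per_pathway
        if not (1 <= lo <= hi):
            raise DesignError(f"invalid genes_per_pathway range {self.genes_per_pathway}")
        bad = [a for a in self.arr_probs if float(a) not in ALLOWED_ARR]
        if bad:
            raise DesignError(f"arr_probs keys not in {ALLOWED_ARR}: {bad}")
        if any(p < 0 for p in self.arr_probs.values()) or not np.isclose(
            sum(self.arr_probs.values()), 1.0
        ):
            raise DesignError("arr_probs must be non-negative and sum to 1")
        if not 0 <= self.stem_fraction <= 1:
            raise DesignError("stem_fraction must lie in [0, 1]")
        for name in (
            "baseline_log_sd",
            "line_sd",
            "activity_sd",
            "meas_sd",
            "pathway_noise_spread",
        ):
            if getattr(self, name) < 0:
                raise DesignError(f"{name} must be >= 0")
        for spec in self.impaired:
            if spec.line_index >= self.n_ipsc:
                raise DesignError(
                    f"impaired line_index {spec.line_index} out of range "
                    f"for {self.n_ipsc} iPSC line(s)"
                )

    def with_(self, **changes) -> "StudyDesign":
        return replace(self, **changes)


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: group per line, stem pathways, impairments."""

    group_of_line: Mapping[str, str]
    stem_pathways: tuple[str, ...]
    impaired: Mapping[str, Mapping[str, float]]  # line -> pathway -> PAS shift

    @property
    def impaired_lines(self) -> tuple[str, ...]:
        return tuple(self.impaired)


def gen_pathway_db(design: StudyDesign, seed: int | None = None) -> PathwayDB:
    """Generate a pathway collection with random sizes and ARR weights.

    Genes are disjoint across pathways (ids ``G00001``…), sizes are uniform
    over ``genes_per_pathway`` (inclusive), and roles are drawn from
    ``arr_probs``.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    lo, hi = design.genes_per_pathway
    arr_values = np.array(sorted(design.arr_probs), dtype=float)
    arr_p = np.array([design.arr_probs[a] for a in arr_values])
    pathways = []
    gene_counter = 0
    for i in range(design.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        arrs = rng.choice(arr_values, size=size, p=arr_p)
        members = []
        for arr in arrs:
            gene_counter += 1
            members.append(GeneRole(f"G{gene_counter:05d}", float(arr)))
        pathways.append(Pathway(f"PW{i + 1:03d}", members))
    return PathwayDB(pathways)


def _line_ids(design: StudyDesign) -> dict[str, list[str]]:
    return {
        "ESC": [f"ESC{i + 1:02d}" for i in range(design.n_esc)],
        "iPSC": [f"iPSC{i + 1:02d}" for i in range(design.n_ipsc)],
        "FIB": [f"FIB{i + 1:02d}" for i in range(design.n_fib)],
        "EB": [f"EB{i + 1:02d}" for i in range(design.n_eb)],
    }


def gen_study(
    db: PathwayDB, design: StudyDesign, seed: int | None = None
) -> tuple[ExpressionMatrix, SampleTable, GroundTruth]:
    """Simulate an expression study over a pathway collection.

    Returns the replicate-level expression matrix (strictly positive linear
    intensities), the sample table, and the planted ground truth.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    genes = list(db.all_genes())
    gene_index = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)
    pathway_names = list(db.names)

    # per-gene pathway assignment and ARR weight (genes are disjoint; a gene
    # appearing in several pathways keeps its first pathway's noise profile)
    gene_pathway = np.zeros(n_genes, dtype=int)
    gene_arr = np.zeros(n_genes)
    for pi, pathway in enumerate(db):
        for member in pathway.members:
            gi = gene_index[member.gene]
            gene_pathway[gi] = pi
            gene_arr[gi] = member.arr

    baseline = rng.normal(design.baseline_log_mean, design.baseline_log_sd, n_genes)

    # per-pathway variability multipliers: a property of the pluripotent
    # program (ESC/iPSC/EB), not of the homogeneous fibroblast controls,
    # whose noise stays at the unscaled baseline
    f_shared = rng.lognormal(0.0, design.pathway_noise_spread, len(pathway_names))
    if design.shared_variance_profile:
        f_ipsc = f_shared
    else:
        f_ipsc = rng.lognormal(0.0, design.pathway_noise_spread, len(pathway_names))
    f_flat = np.ones(len(pathway_names))
    profile_of_group = {"ESC": f_shared, "FIB": f_flat, "EB": f_shared, "iPSC": f_ipsc}

    # stem-program pathways and their per-gene shift
    n_stem = int(round(design.stem_fraction * len(pathway_names)))
    stem_idx = rng.choice(len(pathway_names), size=n_stem, replace=False)
    stem_idx = np.sort(stem_idx)
    stem_mask = np.isin(gene_pathway, stem_idx)
    stem_shift = np.where(stem_mask, design.stem_effect * gene_arr, 0.0)

    # analytic corridor half-width per pathway: SD of PAS across ESC lines
    # (per-gene noise adds variance σ_eff²·Σarr²; the coherent activity
    # effect adds (σ_act·f_p·Σarr²)², assuming all member genes flagged)
    sum_arr2 = np.zeros(len(pathway_names))
    np.add.at(sum_arr2, gene_pathway, gene_arr**2)
    sigma_eff = np.sqrt(
        (design.line_sd * f_shared) ** 2 + design.meas_sd**2 / design.replicates
    )
    half_width = np.sqrt(
        sigma_eff**2 * sum_arr2
        + (design.activity_sd * f_shared * sum_arr2) ** 2
    )

    # planted impairments: per-gene shift s_p * ARR with random sign per pathway
    lines = _line_ids(design)
    impaired_truth: dict[str, dict[str, float]] = {}
    impair_shift_of_line: dict[str, np.ndarray] = {}
    stem_list = [pathway_names[i] for i in stem_idx]
    for spec in design.impaired:
        line = lines["iPSC"][spec.line_index]
        n_hit = int(round(spec.fraction * len(stem_list)))
        hit = rng.choice(len(stem_list), size=n_hit, replace=False)
        shift_vec = np.zeros(n_genes)
        truth: dict[str, float] = {}
        for j in np.sort(hit):
            pi = int(stem_idx[j])
            if sum_arr2[pi] == 0:
                continue
            sign = float(rng.choice([-1.0, 1.0]))
            s_gene = spec.shift_halfwidths * half_width[pi] / sum_arr2[pi]
            member_mask = gene_pathway == pi
            shift_vec += np.where(member_mask, sign * s_gene * gene_arr, 0.0)
            truth[pathway_names[pi]] = sign * spec.shift_halfwidths * half_width[pi]
        impaired_truth[line] = truth
        impair_shift_of_line[line] = shift_vec

    group_shift = {
        "ESC": stem_shift,
        "iPSC": stem_shift,
        "EB": design.eb_attenuation * stem_shift,
        "FIB": np.zeros(n_genes),
    }

    columns: dict[str, np.ndarray] = {}
    rows = []
    group_of_line: dict[str, str] = {}
    for group in ("ESC", "iPSC", "FIB", "EB"):
        f_p = profile_of_group[group]
        gene_noise_sd = design.line_sd * f_p[gene_pathway]
        for line in lines[group]:
            group_of_line[line] = group
            line_effect = rng.normal(0.0, 1.0, n_genes) * gene_noise_sd
            activity = rng.normal(
                0.0, design.activity_sd * f_p, len(pathway_names)
            )
            activity_effect = activity[gene_pathway] * gene_arr
            log_line = (
                baseline
                + group_shift[group]
                + line_effect
                + activity_effect
                + impair_shift_of_line.get(line, 0.0)
            )
            for r in range(design.replicates):
                sample_id = f"{line}_r{r + 1}"
                meas = rng.normal(0.0, design.meas_sd, n_genes)
                columns[sample_id] = np.power(10.0, log_line + meas)
                rows.append({"sample_id": sample_id, "line_id": line, "group": group})

    matrix = ExpressionMatrix(
        pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    )
    table = SampleTable(pd.DataFrame(rows))
    truth = GroundTruth(
        group_of_line=group_of_line,
        stem_pathways=tuple(stem_list),
        impaired={k: dict(v) for k, v in impaired_truth.items()},
    )
    return matrix, table, truth
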