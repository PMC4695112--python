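"""Per-pathway statistics on PAS profiles.

Significance of group-level pathway dysregulation (one-sample t against 0
with Benjamini-Hochberg FDR control), variability ranking, overlap of
most/least variable pathway sets between groups, the deviation correlation
between two groups' per-pathway dispersion profiles, and hierarchical
clustering of PAS profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .pas import PASMatrix

__all__ = [
    "StatsError",
    "pathway_group_test",
    "permutation_group_test",
    "bh_fdr",
    "significant_pathways",
    "variability_rank",
    "shared_top",
    "deviation_correlation",
    "ClusterResult",
    "cluster_pas",
]


class StatsError(ValueError):
    """Invalid input to a pathway statistic."""


def pathway_group_test(pas: PASMatrix, group_lines: Iterable[str]) -> pd.DataFrame:
    """Test each pathway's PAS for a group of lines against 0.

    A two-sided one-sample t-test per pathway (null: the pathway is not
    differentially activated relative to the reference), with BH-adjusted
    q-values across pathways.  Returns a DataFrame indexed by pathway with
    columns ``mean_pas``, ``p_value``, ``q_value`` and attribute ``n``.
    """
    lines = list(dict.fromkeys(group_lines))
    if len(lines) < 3:
        raise StatsError(f"group test needs >= 3 lines, got {len(lines)}")
    sub = pas.subset_lines(lines).data
    means = sub.mean(axis=1)
    sds = sub.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = sps.ttest_1samp(sub, 0.0, axis=1).pvalue
    # zero-variance pathways: t undefined; exactly 0 everywhere is a perfect
    # null fit, otherwise the evidence against 0 is as strong as representable
    tiny = np.finfo(float).tiny
    degenerate = sds.to_numpy() == 0
    p = np.where(degenerate, np.where(means.to_numpy() == 0, 1.0, tiny), p)
    p = np.clip(p, tiny, 1.0)
    out = pd.DataFrame(
        {"mean_pas": means, "p_value": p, "q_value": bh_fdr(p)}, index=sub.index
    )
    out.attrs["n"] = len(lines)
    return out


def permutation_group_test(
    matrix,
    db,
    group_lines: Iterable[str],
    control_lines: Iterable[str],
    params=None,
    n_permutations: int = 1000,
    seed: int = 42,
    missing_genes: str = "warn",
) -> pd.DataFrame:
    """Label-shuffling permutation alternative to the t-test.

    The statistic per pathway is the mean PAS across the group's lines.  The
    null distribution is obtained by shuffling the case/control assignment
    among the pooled group and control lines and recomputing the statistic —
    this, unlike a per-line test, propagates the uncertainty of the control
    reference itself, which with few control lines correlates the case
    lines' PAS errors and makes the one-sample t-test anticonservative.
    The p-value includes the observed statistic (+1 correction).

    Parameters mirror :func:`pasqc.pas.compute_pas_matrix`; ``matrix`` must
    be replicate-collapsed to lines.
    """
    from .pas import BTIFParams, _membership_matrix

    if params is None:
        params = BTIFParams()
    group = list(dict.fromkeys(group_lines))
    controls = list(dict.fromkeys(control_lines))
    if len(group) < 3:
        raise StatsError(f"group test needs >= 3 lines, got {len(group)}")
    if not controls:
        raise StatsError("control line set is empty")
    if set(group) & set(controls):
        raise StatsError("group and control line sets must be disjoint")
    if n_permutations < 1:
        raise StatsError("n_permutations must be >= 1")
    pool = group + controls
    missing = [l for l in pool if l not in matrix.samples]
    if missing:
        raise StatsError(f"line(s) absent from the matrix: {missing[:5]}")

    logs = np.log10(matrix.data[pool]).to_numpy()
    weights = _membership_matrix(db, matrix.genes, missing_genes).to_numpy()
    n_ctrl = len(controls)

    def stat(perm: np.ndarray) -> np.ndarray:
        ctrl_cols = logs[:, perm[:n_ctrl]]
        case_cols = logs[:, perm[n_ctrl:]]
        mu = ctrl_cols.mean(axis=1)
        sd = ctrl_cols.std(axis=1, ddof=1) if n_ctrl > 1 else np.zeros(len(mu))
        band = np.maximum(params.k * sd, params.floor)
        d = case_cols - mu[:, None]
        contrib = np.where(np.abs(d) > band[:, None], d, 0.0)
        return weights @ contrib.mean(axis=1)

    identity = np.concatenate(
        [np.arange(len(group), len(pool)), np.arange(len(group))]
    )
    observed = stat(identity)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(weights.shape[0])
    order = np.arange(len(pool))
    for _ in range(n_permutations):
        rng.shuffle(order)
        exceed += np.abs(stat(order)) >= np.abs(observed)
    p = (exceed + 1.0) / (n_permutations + 1.0)
    out = pd.DataFrame(
        {"mean_pas": observed, "p_value": p, "q_value": bh_fdr(p)},
        index=pd.Index(db.names, name="pathway"),
    )
    out.attrs["n"] = len(group)
    return out


def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1, returned in the
    input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise StatsError("p-values must be a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise StatsError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def significant_pathways(
    results: pd.DataFrame, q_max: float = 0.05, p_max: float | None = None
) -> list[str]:
    """Pathways passing q < q_max (and optionally p < p_max), in input order."""
    mask = results["q_value"] < q_max
    if p_max is not None:
        mask &= results["p_value"] < p_max
    return results.index[mask].tolist()


def variability_rank(pas: PASMatrix, group_lines: Iterable[str]) -> pd.DataFrame:
    """Rank pathways by the sample SD of PAS across a group's lines.

    Rank 1 is the most variable pathway; ties are broken by ascending
    pathway name so the ranking is a deterministic permutation of 1..P.
    """
    lines = list(dict.fromkeys(group_lines))
    if len(lines) < 2:
        raise StatsError("variability needs >= 2 lines")
    sub = pas.subset_lines(lines).data
    sd = sub.std(axis=1, ddof=1)
    order = sorted(sd.index, key=lambda name: (-sd[name], name))
    rank = pd.Series(
        np.arange(1, len(order) + 1), index=pd.Index(order, name="pathway")
    )
    out = pd.DataFrame({"sd": sd, "rank": rank.reindex(sd.index)})
    out.attrs["n"] = len(lines)
    return out


def shared_top(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    k: int,
    end: Literal["most", "least"] = "most",
) -> tuple[int, list[str]]:
    """Overlap of the k most (or least) variable pathways of two rankings."""
    if not table_a.index.sort_values().equals(table_b.index.sort_values()):
        raise StatsError("variability tables must share one pathway universe")
    n = len(table_a)
    if not 1 <= k <= n:
        raise StatsError(f"k must be in [1, {n}], got {k}")

    def pick(table: pd.DataFrame) -> set[str]:
        if end == "most":
            return set(table.index[table["rank"] <= k])
        if end == "least":
            return set(table.index[table["rank"] > n - k])
        raise StatsError(f"end must be 'most' or 'least', got {end!r}")

    common = sorted(pick(table_a) & pick(table_b))
    return len(common), common


def deviation_correlation(pas_a: PASMatrix, pas_b: PASMatrix) -> float:
    """R² between two groups' per-pathway PAS dispersion profiles.

    The deviation of a pathway within a group is the sample SD of its PAS
    across the group's lines; the statistic is the squared Pearson
    correlation of the two deviation vectors over the shared pathway
    universe.  Mirrors the scatter of per-pathway ESC vs iPSC dispersion
    (with the reference-group matrix computed under the leave-one-out
    reference policy so its lines are not compared to themselves).
    """
    if not pas_a.pathways.sort_values().equals(pas_b.pathways.sort_values()):
        raise StatsError("PAS matrices must share one pathway universe")
    if len(pas_a.pathways) < 3:
        raise StatsError("deviation correlation needs >= 3 pathways")
    dev_a = pas_a.data.std(axis=1, ddof=1)
    dev_b = pas_b.data.std(axis=1, ddof=1).reindex(dev_a.index)
    if dev_a.std(ddof=0) == 0 or dev_b.std(ddof=0) == 0:
        raise StatsError("deviation vector has zero variance; R² undefined")
    r = np.corrcoef(dev_a.to_numpy(), dev_b.to_numpy())[0, 1]
    return float(r * r)


@dataclass(frozen=True)
class ClusterResult:
    """Dendrogram orders and merge trees for pathways (rows) and lines."""

    pathway_order: tuple[str, ...]
    line_order: tuple[str, ...]
    pathway_linkage: np.ndarray
    line_linkage: np.ndarray
    pathways: tuple[str, ...]
    lines: tuple[str, ...]


def cluster_pas(
    pas: PASMatrix,
    top_n: int | None = None,
    group_lines: Iterable[str] | None = None,
) -> ClusterResult:
    """Agglomerative clustering of the top-n most variable pathways and lines.

    Variability is measured across the matrix's lines (or ``group_lines`` if
    given); clustering uses Euclidean distance and average linkage on both
    axes, with scipy's deterministic tie-breaking by input order.
    """
    lines = (
        list(pas.lines)
        if group_lines is None
        else list(dict.fromkeys(group_lines))
    )
    sub = pas.subset_lines(lines)
    if top_n is not None:
        if top_n > len(pas.pathways):
            raise StatsError(
                f"top_n={top_n} exceeds pathway count {len(pas.pathways)}"
            )
        ranking = variability_rank(sub, lines)
        keep = ranking.index[ranking["rank"] <= top_n]
        frame = sub.data.loc[keep]
    else:
        frame = sub.data

    def link(values: np.ndarray) -> np.ndarray:
        if values.shape[0] < 2:
            return np.empty((0, 4))
        return hierarchy.linkage(pdist(values, metric="euclidean"), method="average")

    row_link = link(frame.to_numpy())
    col_link = link(frame.to_numpy().T)
    row_order = (
        frame.index[hierarchy.leaves_list(row_link)]
        if len(row_link)
        else frame.index
    )
    col_order = (
        frame.columns[hierarchy.leaves_list(col_link)]
        if len(col_link)
        else frame.columns
    )
    return ClusterResult(
        pathway_order=tuple(row_order),
        line_order=tuple(col_order),
        pathway_linkage=row_link,
        line_linkage=col_link,
        pathways=tuple(frame.index),
        lines=tuple(frame.columns),
    )
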