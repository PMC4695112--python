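"""ESC quality corridor and per-line iPSC quality scoring.

The corridor treats the ESC group as the gold standard: for each pathway the
"healthy range" of activation is the mean PAS across ESC lines plus/minus one
sample SD.  An iPSC line's quality score is the number of pathways whose PAS
falls inside this band (inclusive bounds); lines whose in-band fraction falls
below a threshold — by default 50% of the corridor's pathway count — are
flagged as potential outliers with impaired (or, occasionally, enhanced)
differentiation capacity.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .pas import PASMatrix

__all__ = ["QCError", "Corridor", "build_corridor", "quality_score", "flag_outliers"]


class QCError(ValueError):
    """Invalid input to the quality-control stage."""


class Corridor:
    """Per-pathway PAS band [mean - width*SD, mean + width*SD] from ESC lines."""

    def __init__(self, bounds: pd.DataFrame, source: str = ""):
        for col in ("lower", "upper"):
            if col not in bounds.columns:
                raise QCError(f"corridor bounds lack column {col!r}")
        values = bounds[["lower", "upper"]].to_numpy()
        if not np.isfinite(values).all():
            raise QCError("corridor bounds must be finite")
        if (bounds["lower"] > bounds["upper"]).any():
            raise QCError("corridor lower bound exceeds upper bound")
        self.bounds = bounds[["lower", "upper"]]
        self.source = source

    @property
    def pathways(self) -> pd.Index:
        return self.bounds.index

    def __len__(self) -> int:
        return len(self.bounds)

    def __repr__(self) -> str:
        return f"Corridor({len(self)} pathways; {self.source})"


def build_corridor(
    esc_pas: PASMatrix,
    pathway_subset: Sequence[str] | None = None,
    width: float = 1.0,
) -> Corridor:
    """Build the reference corridor from the ESC group's PAS matrix.

    ``width`` scales the SD half-width (1.0 reproduces the mean ± SD band).
    ``pathway_subset`` restricts the corridor, e.g. to pathways significantly
    dysregulated in the ESC group.
    """
    if len(esc_pas.lines) < 2:
        raise QCError("corridor needs >= 2 ESC lines")
    if width < 0:
        raise QCError("corridor width must be >= 0")
    frame = esc_pas.data
    if pathway_subset is not None:
        subset = list(dict.fromkeys(pathway_subset))
        missing = [p for p in subset if p not in frame.index]
        if missing:
            raise QCError(f"subset pathway(s) absent from PAS matrix: {missing[:5]}")
        if not subset:
            raise QCError("pathway subset is empty")
        frame = frame.loc[subset]
    mean = frame.mean(axis=1)
    half = width * frame.std(axis=1, ddof=1)
    bounds = pd.DataFrame({"lower": mean - half, "upper": mean + half})
    source = f"mean ± {width:g}·SD over {len(esc_pas.lines)} ESC line(s)"
    return Corridor(bounds, source)


def quality_score(
    ipsc_pas: PASMatrix, corridor: Corridor, threshold: float = 0.5
) -> pd.DataFrame:
    """Count, per line, the corridor pathways whose PAS lies inside the band.

    Bounds are inclusive so a zero-width corridor can still be satisfied at
    exact equality.  Returns a DataFrame indexed by line with columns
    ``n_within``, ``n_total``, ``fraction`` and ``passed`` (fraction >=
    threshold).
    """
    if not 0 <= threshold <= 1:
        raise QCError("threshold must lie in [0, 1]")
    missing = corridor.pathways.difference(ipsc_pas.pathways)
    if len(missing):
        raise QCError(
            f"corridor pathway(s) absent from PAS matrix: {missing[:5].tolist()}"
        )
    sub = ipsc_pas.data.loc[corridor.pathways]
    lower = corridor.bounds["lower"].to_numpy()[:, None]
    upper = corridor.bounds["upper"].to_numpy()[:, None]
    inside = (sub.to_numpy() >= lower) & (sub.to_numpy() <= upper)
    n_within = inside.sum(axis=0)
    n_total = len(corridor)
    report = pd.DataFrame(
        {
            "n_within": n_within,
            "n_total": n_total,
            "fraction": n_within / n_total,
            "passed": n_within / n_total >= threshold,
        },
        index=pd.Index(sub.columns, name="line_id"),
    )
    report.attrs["threshold"] = threshold
    report.attrs["corridor"] = corridor.source
    return report


def flag_outliers(report: pd.DataFrame, threshold: float = 0.5) -> list[str]:
    """Line ids with in-corridor fraction below the threshold, worst first."""
    if report.empty:
        raise QCError("quality report is empty")
    flagged = report.loc[report["fraction"] < threshold, "fraction"]
    return flagged.sort_values(kind="stable").index.tolist()
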