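"""Trend-line comparison of origin-mapping methods against the MO threshold.

Each origin-mapping method (DNA combing, MFA-seq, SNS-seq, microarray,
known ARS elements, A+T-rich islands, ...) yields a per-chromosome origin
count.  Plotting count against chromosome length and fitting an ordinary
least-squares line y = a*x + b gives one trend line per method; the MO
trend line is the threshold below which a method cannot account for
complete replication within S-phase.

The fold-over-minimum statistic is the ratio of a method's slope to the MO
slope — how many times more origins an organism uses than the minimum.
When MO is 1 for every chromosome the MO line is the constant y = 1 with
slope 0, and the ratio is reported as an explicit infinite marker (never a
float overflow; serialized as the string ``"inf"``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateTrendError, DomainError
from .karyotype_io import OriginProfile

__all__ = [
    "TrendLine",
    "FoldOverMinimum",
    "SufficiencyReport",
    "fit_trend",
    "fold_over_minimum",
    "sufficiency_report",
    "plot_comparison",
]


@dataclass(frozen=True)
class TrendLine:
    """An OLS line y = slope * x + intercept over (length bp, count) points."""

    method: str
    slope: float  # origins per bp
    intercept: float  # origins
    n_points: int
    constant_flag: bool = False  # all counts identical -> y = intercept

    def predict(self, length_bp: float) -> float:
        return self.slope * length_bp + self.intercept


@dataclass(frozen=True)
class FoldOverMinimum:
    """Ratio of a method's trend slope to the MO trend slope."""

    organism: str
    ratio: float  # math.inf when the MO line is flat

    def __post_init__(self) -> None:
        if not (self.ratio > 0):
            raise DomainError(f"fold-over-minimum ratio must be > 0, got {self.ratio}")

    @property
    def is_infinite(self) -> bool:
        return math.isinf(self.ratio)

    def __str__(self) -> str:
        return "inf" if self.is_infinite else format(self.ratio, "g")


@dataclass(frozen=True)
class SufficiencyReport:
    """Per-chromosome comparison of a method's counts against MO.

    ``table`` has one row per chromosome with columns ``chromosome``,
    ``count``, ``mo`` and ``deficit`` (count < MO).  Any deficit anywhere
    means the method alone cannot explain replication of the whole genome
    within the S-phase duration.
    """

    method: str
    table: pd.DataFrame

    @property
    def sufficient(self) -> bool:
        return not bool(self.table["deficit"].any())

    @property
    def deficit_chromosomes(self) -> tuple[str, ...]:
        return tuple(self.table.loc[self.table["deficit"], "chromosome"])


def fit_trend(points: Sequence[tuple[float, float]], method: str = "trend") -> TrendLine:
    """Fit y = a*x + b by ordinary least squares.

    Needs at least two points with at least two distinct x values.  If every
    count is identical the line is reported as the constant y = c with slope
    exactly 0 and ``constant_flag`` set.
    """
    pts = list(points)
    if len(pts) < 2:
        raise DomainError(
            f"trend fit for {method!r} needs >= 2 points, got {len(pts)}"
        )
    x = np.asarray([p[0] for p in pts], dtype=float)
    y = np.asarray([p[1] for p in pts], dtype=float)
    if np.unique(y).size == 1:
        return TrendLine(
            method=method,
            slope=0.0,
            intercept=float(y[0]),
            n_points=len(pts),
            constant_flag=True,
        )
    if np.unique(x).size < 2:
        raise DomainError(
            f"trend fit for {method!r}: all chromosome lengths identical, "
            "slope undefined"
        )
    # centred design keeps the normal equations well conditioned for bp-scale x
    xm, ym = x.mean(), y.mean()
    slope = float(((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum())
    intercept = float(ym - slope * xm)
    return TrendLine(
        method=method, slope=slope, intercept=intercept, n_points=len(pts)
    )


def fold_over_minimum(
    method_line: TrendLine, mo_line: TrendLine, organism: str = ""
) -> FoldOverMinimum:
    """Slope ratio method/MO; infinite marker when the MO line is flat."""
    if method_line.slope <= 0:
        raise DegenerateTrendError(
            f"method {method_line.method!r} has non-positive slope "
            f"({method_line.slope:g}); no meaningful fold over the minimum"
        )
    if mo_line.constant_flag or mo_line.slope == 0.0:
        return FoldOverMinimum(organism=organism, ratio=math.inf)
    return FoldOverMinimum(organism=organism, ratio=method_line.slope / mo_line.slope)


def sufficiency_report(
    profile: OriginProfile, mo_table: pd.DataFrame
) -> SufficiencyReport:
    """Flag chromosomes where a method maps fewer origins than the MO.

    ``mo_table`` is the output of :func:`orimin.origins.genome_mo_table`
    (columns ``chromosome`` and ``mo``).  Profile chromosomes must be a
    subset of the table's.
    """
    known = set(mo_table["chromosome"])
    unknown = set(profile.counts) - known
    if unknown:
        raise DomainError(
            f"profile {profile.method!r} has counts for chromosomes absent "
            f"from the MO table: {sorted(unknown)}"
        )
    rows = []
    for _, mo_row in mo_table.iterrows():
        name = mo_row["chromosome"]
        count = int(profile.counts.get(name, 0))
        mo = int(mo_row["mo"])
        rows.append(
            {
                "chromosome": name,
                "count": count,
                "mo": mo,
                "deficit": count < mo,
            }
        )
    return SufficiencyReport(
        method=profile.method,
        table=pd.DataFrame(rows, columns=["chromosome", "count", "mo", "deficit"]),
    )


def plot_comparison(
    mo_points: Sequence[tuple[float, float]],
    method_points: dict[str, Sequence[tuple[float, float]]],
    path: str,
    organism: str = "",
) -> None:
    """Scatter of counts vs chromosome length with one trend line per method."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    series = {"MO": mo_points, **method_points}
    for label, pts in series.items():
        x = np.asarray([p[0] for p in pts], dtype=float)
        y = np.asarray([p[1] for p in pts], dtype=float)
        color = "black" if label == "MO" else None
        sc = ax.scatter(x / 1e6, y, s=18, label=label, color=color)
        line = fit_trend(pts, method=label)
        grid = np.linspace(x.min(), x.max(), 50)
        ax.plot(
            grid / 1e6,
            line.slope * grid + line.intercept,
            color=sc.get_facecolor()[0],
            linewidth=1.2,
        )
    ax.set_xlabel("chromosome length (Mb)")
    ax.set_ylabel("origins")
    ax.set_title(organism or "origin counts vs chromosome length")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
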