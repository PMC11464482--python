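"""Statistics for the shell damage-repair assay.

Holes drilled in each valve are scored by the fraction of the initial
hole area covered by new shell. Holes within an animal-valve are
pseudo-replicates, so ratios are aggregated per animal first and treatment
summaries are computed over animals. Group comparisons use a pooled
two-proportion z-test (covered vs not), a two-tailed Student's t-test
(pooled variance by default, Welch by flag), and the flat-round growth
correlation is a Pearson r with a t-based p.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .formats import FormatError

__all__ = [
    "HoleRecord",
    "repair_ratio",
    "two_proportion_z",
    "students_t",
    "crystal_stats",
    "growth_correlation",
]


@dataclass(frozen=True)
class HoleRecord:
    """One drilled hole: initial and repaired area in mm^2."""

    animal_id: str
    valve: str  # flat | round
    hole_position: str  # Hp1 | Hp2 | Hp3
    initial_area: float
    repaired_area: float
    coverage_frac: float = 1.0  # full closure counts as covered

    def __post_init__(self) -> None:
        if self.valve not in {"flat", "round"}:
            raise FormatError(f"hole {self.animal_id}: bad valve {self.valve!r}")
        if self.initial_area <= 0:
            raise FormatError(
                f"hole {self.animal_id}/{self.hole_position}: initial_area <= 0"
            )
        if self.repaired_area < 0:
            raise FormatError(
                f"hole {self.animal_id}/{self.hole_position}: repaired_area < 0"
            )

    @property
    def ratio(self) -> float:
        """Repair ratio clipped to [0, 1] (overgrowth counts as closed)."""
        return min(self.repaired_area / self.initial_area, 1.0)

    @property
    def covered(self) -> bool:
        return self.repaired_area >= self.coverage_frac * self.initial_area


def repair_ratio(holes: Sequence[HoleRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-animal per-valve mean repair ratios and the per-valve summary.

    Returns (per-animal table with animal_id, valve, n_holes, mean_ratio,
    n_covered; per-valve summary with n_animals, n_holes, mean, sd,
    covered, total).
    """
    if not holes:
        raise FormatError("no holes supplied")
    rows = [
        {
            "animal_id": h.animal_id,
            "valve": h.valve,
            "ratio": h.ratio,
            "covered": h.covered,
        }
        for h in holes
    ]
    df = pd.DataFrame(rows)
    per_animal = (
        df.groupby(["animal_id", "valve"], sort=True)
        .agg(
            n_holes=("ratio", "size"),
            mean_ratio=("ratio", "mean"),
            n_covered=("covered", "sum"),
        )
        .reset_index()
    )
    summary = (
        per_animal.groupby("valve", sort=True)
        .agg(
            n_animals=("animal_id", "nunique"),
            n_holes=("n_holes", "sum"),
            mean=("mean_ratio", "mean"),
            sd=("mean_ratio", lambda x: x.std(ddof=1) if len(x) > 1 else 0.0),
        )
        .reset_index()
    )
    covered = df.groupby("valve", sort=True)["covered"].sum().reset_index()
    summary = summary.merge(covered, on="valve").rename(columns={"covered": "n_covered"})
    return per_animal, summary


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test; returns (z, two-sided p).

    z = (p1 - p2) / sqrt(pooled*(1-pooled)*(1/n1 + 1/n2)) with
    pooled = (x1+x2)/(n1+n2). Undefined when every or no observation is a
    success.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0 or not 0 <= x <= n:
            raise FormatError(f"bad counts x={x}, n={n}")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise FormatError(
            "pooled proportion is 0 or 1; the z statistic is undefined"
        )
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (x1 / n1 - x2 / n2) / se
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def students_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    mode: str = "pooled",
) -> tuple[float, float, float]:
    """Two-tailed t-test; returns (t, df, p). mode: 'pooled' or 'welch'."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise FormatError("each group needs at least 2 values")
    if mode not in {"pooled", "welch"}:
        raise FormatError(f"unknown mode {mode!r}")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        df = float(len(a) + len(b) - 2)
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), df, 0.0
    res = stats.ttest_ind(a, b, equal_var=(mode == "pooled"))
    return float(res.statistic), float(res.df), float(res.pvalue)


def crystal_stats(
    areas: Sequence[float] | None = None,
    counts_per_field: Sequence[float] | None = None,
    field_area: float = 25.0,
) -> dict:
    """Mean +/- SEM of crystal areas (um^2) and density (count / mm^2).

    SEM = SD/sqrt(n) with ddof = 1; each metric needs n >= 2.
    """
    out: dict = {}
    if areas is not None:
        a = np.asarray(areas, dtype=float)
        if len(a) < 2:
            raise FormatError("crystal areas need n >= 2 for a SEM")
        out["area_mean"] = float(a.mean())
        out["area_sem"] = float(a.std(ddof=1) / np.sqrt(len(a)))
        out["area_n"] = len(a)
    if counts_per_field is not None:
        c = np.asarray(counts_per_field, dtype=float)
        if len(c) < 2:
            raise FormatError("crystal counts need n >= 2 for a SEM")
        dens = c / field_area
        out["density_mean"] = float(dens.mean())
        out["density_sem"] = float(dens.std(ddof=1) / np.sqrt(len(c)))
        out["density_n"] = len(c)
    if not out:
        raise FormatError("supply areas and/or counts_per_field")
    return out


def growth_correlation(
    flat_areas: Sequence[float], round_areas: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation of repaired areas paired by animal; (r, p)."""
    x = np.asarray(flat_areas, dtype=float)
    y = np.asarray(round_areas, dtype=float)
    if len(x) != len(y):
        raise FormatError("paired vectors must have equal length")
    if len(x) < 3:
        raise FormatError("correlation needs n >= 3 pairs")
    if x.var() == 0 or y.var() == 0:
        raise FormatError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
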