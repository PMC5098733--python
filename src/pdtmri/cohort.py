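"""ROI-level summaries and group statistics.

Tumor-level readouts: ROI volume by integrating voxel volumes, mean/SD of
parameter maps over valid ROI voxels, the non-enhanced tumor fraction, and
treated-versus-control comparisons (Levene-gated independent t-tests and
paired t-tests, two-tailed throughout, per-comparison alpha = 0.05 with no
multiplicity correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ParameterMap
from .errors import GeometryError
from .protocol import VoxelGrid

__all__ = [
    "ROIMask",
    "RoiSummary",
    "GroupComparison",
    "tumor_volume",
    "roi_summary",
    "nonenhanced_fraction",
    "compare_groups",
    "cohort_records",
]

COHORT_COLUMNS = ("subject_id", "group", "timepoint", "metric", "value")


@dataclass
class ROIMask:
    """Boolean region-of-interest on a voxel grid (e.g. a manual tumor contour)."""

    grid: VoxelGrid
    inside: np.ndarray

    def __post_init__(self) -> None:
        self.inside = np.asarray(self.inside, dtype=bool)
        if self.inside.shape != self.grid.shape:
            raise GeometryError("ROI mask shape does not match grid")

    @property
    def n_voxels(self) -> int:
        return int(self.inside.sum())


def tumor_volume(mask: ROIMask) -> float:
    """ROI volume in mm^3: voxel count x dx*dy*(thickness + gap).

    An empty mask yields 0 with a warning rather than an error, so that
    fully regressed tumors still produce a row in longitudinal tables.
    """
    n = mask.n_voxels
    if n == 0:
        warnings.warn("tumor_volume: empty ROI mask, volume is 0", stacklevel=2)
        return 0.0
    return n * mask.grid.voxel_volume_mm3


@dataclass
class RoiSummary:
    mean: float
    sd: float
    n: int

    @property
    def defined(self) -> bool:
        return self.n > 0


def roi_summary(pmap: ParameterMap, mask: ROIMask) -> RoiSummary:
    """Mean/SD/count of a parameter map over valid voxels inside the ROI.

    Invalid voxels never contribute; if no valid voxel lies inside, the
    result is flagged undefined (n = 0, NaN statistics) rather than zero.
    """
    if pmap.grid.shape != mask.grid.shape:
        raise GeometryError("map and ROI grids do not match")
    sel = mask.inside & pmap.valid_mask
    n = int(sel.sum())
    if n == 0:
        return RoiSummary(mean=np.nan, sd=np.nan, n=0)
    vals = pmap.values[sel]
    return RoiSummary(
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if n > 1 else 0.0,
        n=n,
    )


def nonenhanced_fraction(enhanced: np.ndarray, mask: ROIMask) -> float:
    """Fraction of ROI voxels not showing contrast enhancement."""
    enhanced = np.asarray(enhanced, dtype=bool)
    if enhanced.shape != mask.grid.shape:
        raise GeometryError("enhanced map and ROI grids do not match")
    n = mask.n_voxels
    if n == 0:
        raise GeometryError("non-enhanced fraction of an empty ROI is undefined")
    return 1.0 - int((enhanced & mask.inside).sum()) / n


@dataclass
class GroupComparison:
    """Two-group comparison with all intermediate statistics retained.

    For an independent design, Levene's test (mean-centered) at alpha = 0.05
    decides between the pooled-variance and Welch t-test; a paired design
    runs the paired two-tailed t-test. ``degenerate`` flags a paired design
    with zero within-pair variance, where p is reported below machine
    resolution rather than from the t distribution.
    """

    design: str
    t_statistic: float
    p_value: float
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    variance_equal: bool | None = None
    levene_statistic: float | None = None
    levene_p: float | None = None
    degenerate: bool = False

    def summary(self) -> str:
        lines = [
            f"{self.design} two-tailed t-test  (n = {self.n_a}, {self.n_b})",
            f"  means: {self.mean_a:.4g} vs {self.mean_b:.4g}",
        ]
        if self.design == "independent":
            lines.append(
                f"  Levene W = {self.levene_statistic:.4g}, p = {self.levene_p:.4g} "
                f"-> {'equal' if self.variance_equal else 'unequal'} variances"
            )
        lines.append(f"  t = {self.t_statistic:.4g}, p = {self.p_value:.4g}")
        if self.degenerate:
            lines.append("  (degenerate: zero within-pair variance)")
        return "\n".join(lines)


def compare_groups(values_a, values_b, design: str = "independent") -> GroupComparison:
    """Levene-gated independent t-test, or paired t-test, two-tailed."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per group")

    if design == "independent":
        if np.allclose(a.std(ddof=1), 0.0) and np.allclose(b.std(ddof=1), 0.0):
            # both groups constant: Levene and the t denominator are undefined
            same = np.allclose(a.mean(), b.mean())
            return GroupComparison(
                design="independent",
                t_statistic=0.0 if same else float(np.sign(a.mean() - b.mean()) * np.inf),
                p_value=1.0 if same else float(np.finfo(float).tiny),
                n_a=a.size, n_b=b.size,
                mean_a=float(a.mean()), mean_b=float(b.mean()),
                variance_equal=True, levene_statistic=0.0, levene_p=1.0,
                degenerate=True,
            )
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            lw, lp = stats.levene(a, b, center="mean")
        equal_var = bool(lp >= 0.05)
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        return GroupComparison(
            design="independent",
            t_statistic=float(t),
            p_value=float(p),
            n_a=a.size,
            n_b=b.size,
            mean_a=float(a.mean()),
            mean_b=float(b.mean()),
            variance_equal=equal_var,
            levene_statistic=float(lw),
            levene_p=float(lp),
        )
    if design == "paired":
        if a.size != b.size:
            raise ValueError("paired design requires matched subjects (equal n)")
        d = a - b
        if np.allclose(d.std(ddof=1), 0.0):
            if np.allclose(d.mean(), 0.0):  # identical pairs: no effect at all
                return GroupComparison(
                    "paired", 0.0, 1.0, a.size, b.size,
                    float(a.mean()), float(b.mean()), degenerate=True,
                )
            # constant non-zero difference: effect certain at machine precision
            return GroupComparison(
                "paired",
                float(np.sign(d.mean()) * np.inf),
                float(np.finfo(float).tiny),
                a.size, b.size, float(a.mean()), float(b.mean()),
                degenerate=True,
            )
        t, p = stats.ttest_rel(a, b)
        return GroupComparison(
            "paired", float(t), float(p), a.size, b.size,
            float(a.mean()), float(b.mean()),
        )
    raise ValueError(f"unknown design {design!r}")


def cohort_records(rows) -> pd.DataFrame:
    """Tidy cohort table (subject_id, group, timepoint, metric, value).

    Enforces one value per (subject, timepoint, metric).
    """
    df = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    dup = df.duplicated(subset=["subject_id", "timepoint", "metric"])
    if dup.any():
        raise ValueError("duplicate (subject, timepoint, metric) rows in cohort table")
    return df
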