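"""Segmented-regression slope extraction and group slope comparisons.

Each cumulative-strain curve is split into protocol segments (by default
minutes 1–20 pre-treatment, 21–50 irradiation, 51–80 post-treatment), each
segment is fitted with an ordinary least-squares line, and the per-sample
slopes (%/min) are compared with two-sided t-tests: paired for
within-sample segment contrasts, two-sample for between-group contrasts
(Welch by default; a pooled-variance Student test is available via
``equal_var=True``).  Raw p-values are reported — no multiple-testing
correction — at the conventional α = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .timeseries import StrainCurve

__all__ = ["SegmentFit", "GroupComparison", "segment_slopes", "compare_slopes", "DEFAULT_SEGMENTS"]

DEFAULT_SEGMENTS: tuple[tuple[float, float], ...] = ((1.0, 20.0), (21.0, 50.0), (51.0, 80.0))


@dataclass
class SegmentFit:
    """OLS line fit of cumulative strain (%) vs time (min) on one segment."""

    segment: str
    t_lo: float
    t_hi: float
    slope: float  # %/min
    intercept: float  # %
    r2: float
    n_points: int
    stderr: float = float("nan")
    fitted: bool = True


@dataclass
class GroupComparison:
    """Two-sided t-test between two sets of per-sample segment slopes."""

    group_a: str
    group_b: str
    segment: str
    t_stat: float
    p: float
    df: float
    paired: bool
    slopes_a: np.ndarray = field(default_factory=lambda: np.array([]))
    slopes_b: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def segment_slopes(
    curve: StrainCurve,
    breaks: Sequence[tuple[float, float]] = DEFAULT_SEGMENTS,
) -> list[SegmentFit]:
    """Fit each closed time segment of a curve with an OLS line.

    Only valid curve points participate.  A segment with fewer than 3 valid
    points is returned with ``fitted=False`` and NaN coefficients and must
    be excluded from comparisons.
    """
    out: list[SegmentFit] = []
    for lo, hi in breaks:
        sel = (curve.t >= lo) & (curve.t <= hi) & curve.valid
        n = int(sel.sum())
        label = f"{lo:g}-{hi:g}min"
        if n < 3:
            out.append(
                SegmentFit(label, lo, hi, np.nan, np.nan, np.nan, n, fitted=False)
            )
            continue
        res = sps.linregress(curve.t[sel], curve.cum_strain[sel])
        r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
        out.append(
            SegmentFit(
                label,
                lo,
                hi,
                float(res.slope),
                float(res.intercept),
                r2,
                n,
                stderr=float(res.stderr),
            )
        )
    return out


def compare_slopes(
    slopes_a: Sequence[float],
    slopes_b: Sequence[float],
    paired: bool,
    group_a: str = "A",
    group_b: str = "B",
    segment: str = "",
    equal_var: bool = False,
) -> GroupComparison:
    """Two-sided t-test on per-sample slopes.

    ``paired=True`` runs a paired t-test (within-sample segment contrasts;
    requires matched ordering), ``paired=False`` a two-sample test — Welch
    by default, pooled-variance Student when ``equal_var=True``.  When both
    groups are constant with equal means the statistic is undefined; the
    comparison is reported as no difference (t=0, p=1) with a warning.
    """
    a = np.asarray(slopes_a, dtype=float)
    b = np.asarray(slopes_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    if paired and len(a) != len(b):
        raise ValueError("paired comparison requires equal sample counts")
    if paired:
        d = a - b
        if np.allclose(d.std(ddof=1), 0.0) and np.allclose(d.mean(), 0.0):
            warnings.warn("zero-variance identical pairs; reporting no difference")
            t_stat, p, df = 0.0, 1.0, float(len(a) - 1)
        else:
            res = sps.ttest_rel(a, b)
            t_stat, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    else:
        if (
            np.allclose(a.std(ddof=1), 0.0)
            and np.allclose(b.std(ddof=1), 0.0)
            and np.allclose(a.mean(), b.mean())
        ):
            warnings.warn("zero variance in both groups with equal means; reporting no difference")
            t_stat, p, df = 0.0, 1.0, float(len(a) + len(b) - 2)
        else:
            res = sps.ttest_ind(a, b, equal_var=equal_var)
            t_stat, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    if not np.isfinite(t_stat):
        warnings.warn("undefined t statistic; reporting no difference")
        t_stat, p = 0.0, 1.0
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        segment=segment,
        t_stat=t_stat,
        p=p,
        df=df,
        paired=paired,
        slopes_a=a,
        slopes_b=b,
    )
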