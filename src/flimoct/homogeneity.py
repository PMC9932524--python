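"""Biochemical homogeneity index of a construct lifetime map.

The region of interest is a ring centered on the construct centroid whose
area is half the total construct area (the inner half-area disk is excluded,
which also removes any central defect).  The homogeneity index is the
fraction of ROI pixels whose lifetime lies within a relative tolerance band
(default ±5%) around the ROI mean lifetime; a perfectly uniform ROI scores 1.
Channel-1 lifetime is the default input because it tracks collagen content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import config


@dataclass
class RingROI:
    centroid: tuple[float, float]
    inner_radius_px: float
    member_mask: np.ndarray     # (H, W) bool
    area_fraction: float


@dataclass
class HomogeneityResult:
    hi: float
    roi: RingROI
    mean_lifetime_ns: float
    tolerance: float
    channel: int
    n_valid: int
    n_excluded: int


@dataclass
class TimepointComparison:
    statistic: float
    pvalue: float
    direction: str              # "increase" | "decrease" | "none"
    mean_difference: float
    paired: bool


def foreground_centroid(mask: np.ndarray) -> tuple[float, float]:
    """Unweighted mean (row, col) of the foreground pixels."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask has no centroid")
    r, c = np.nonzero(mask)
    return float(r.mean()), float(c.mean())


def ring_roi(mask: np.ndarray,
             centroid: tuple[float, float] | None = None) -> RingROI:
    """Outer half-area ring of a foreground mask.

    The inner radius is the smallest radius containing at least half the
    foreground pixels; the ROI is everything at or beyond that radius, so the
    boundary shell belongs to the ROI.  Pixels excluded from the foreground
    (e.g. a central void) can never be ROI members.
    """
    mask = np.asarray(mask, bool)
    n = int(mask.sum())
    if n < 2:
        raise ValueError("mask too small for a ring ROI")
    if centroid is None:
        centroid = foreground_centroid(mask)
    rows, cols = np.nonzero(mask)
    d = np.hypot(rows - centroid[0], cols - centroid[1])
    order = np.sort(d)
    m = int(np.ceil(n / 2.0))
    inner = float(order[m - 1])
    member = np.zeros_like(mask)
    keep = d >= inner
    member[rows[keep], cols[keep]] = True
    return RingROI(centroid=centroid, inner_radius_px=inner,
                   member_mask=member,
                   area_fraction=float(member.sum()) / n)


def homogeneity_index(lt_map: np.ndarray, roi: RingROI,
                      tolerance: float = config.HI_TOLERANCE,
                      channel: int = config.HI_CHANNEL) -> HomogeneityResult:
    """Fraction of ROI pixels within (1 ± tolerance) x mean ROI lifetime.

    Missing (NaN) pixels are excluded from both the mean and the count, with
    the number excluded recorded.  Band edges are inclusive.  Returns a
    missing (NaN) index when no valid ROI pixel exists.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    vals = np.asarray(lt_map, float)[roi.member_mask]
    finite = np.isfinite(vals)
    n_excluded = int((~finite).sum())
    vals = vals[finite]
    if vals.size == 0:
        return HomogeneityResult(hi=np.nan, roi=roi, mean_lifetime_ns=np.nan,
                                 tolerance=tolerance, channel=channel,
                                 n_valid=0, n_excluded=n_excluded)
    mu = float(vals.mean())
    lo, hi_band = (1.0 - tolerance) * mu, (1.0 + tolerance) * mu
    inside = (vals >= lo) & (vals <= hi_band)
    return HomogeneityResult(
        hi=float(inside.sum()) / vals.size, roi=roi, mean_lifetime_ns=mu,
        tolerance=tolerance, channel=channel,
        n_valid=int(vals.size), n_excluded=n_excluded,
    )


def compare_timepoints(hi_week2, hi_week4, paired: bool = True) -> TimepointComparison:
    """Two-sided t-test of homogeneity-index change between time points.

    Paired by default (matched samples are imaged at both time points); an
    unpaired Welch test is available behind the flag.  Identical groups give
    statistic 0 and p = 1.
    """
    a = np.asarray(hi_week2, float)
    b = np.asarray(hi_week4, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two samples per group")
    if paired and a.size != b.size:
        raise ValueError("paired comparison requires equal sample counts")
    diff_mean = float(b.mean() - a.mean())
    if paired:
        d = b - a
        if np.allclose(d, d[0]):
            if d[0] == 0:
                return TimepointComparison(0.0, 1.0, "none", 0.0, True)
            # zero-variance nonzero shift: overwhelming evidence
            return TimepointComparison(np.inf if d[0] > 0 else -np.inf, 0.0,
                                       "increase" if d[0] > 0 else "decrease",
                                       diff_mean, True)
        res = stats.ttest_rel(b, a)
    else:
        if b.std(ddof=1) == 0 and a.std(ddof=1) == 0:
            if diff_mean == 0:
                return TimepointComparison(0.0, 1.0, "none", 0.0, False)
            return TimepointComparison(np.inf if diff_mean > 0 else -np.inf, 0.0,
                                       "increase" if diff_mean > 0 else "decrease",
                                       diff_mean, False)
        res = stats.ttest_ind(b, a, equal_var=False)
    direction = "increase" if diff_mean > 0 else ("decrease" if diff_mean < 0 else "none")
    return TimepointComparison(float(res.statistic), float(res.pvalue),
                               direction, diff_mean, paired)
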