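"""Multivariate analysis of FLIm parameter maps.

Pixel-wise Pearson correlation among the eight parameter maps of one image
(LT1-LT4, INTR1-INTR4), aggregation of per-image matrices across a batch,
and a per-pair significance test.  The aggregation averages coefficients
across all images irrespective of treatment or time point; significance of a
pair is a two-sided one-sample t-test of the Fisher-z transformed per-image
coefficients against zero, without multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .mapping import FLImMapStack

PARAMETER_ORDER: tuple[str, ...] = (
    "LT1", "LT2", "LT3", "LT4", "INTR1", "INTR2", "INTR3", "INTR4"
)


@dataclass
class CorrelationSummary:
    mean_matrix: np.ndarray   # (8, 8)
    sd_matrix: np.ndarray     # (8, 8), population sd (ddof=0)
    n_images: int
    p_matrix: np.ndarray      # (8, 8); NaN on the diagonal and when n < 3
    counts: np.ndarray        # (8, 8) images contributing per entry
    labels: tuple[str, ...] = PARAMETER_ORDER


def pixelwise_correlation_matrix(stack: FLImMapStack) -> np.ndarray:
    """Pearson r over the common valid-pixel set for every map pair.

    Requires at least 3 jointly valid pixels.  A map with zero variance gets
    NaN in its row and column (missing, not zero), with its diagonal kept at 1.
    """
    maps = stack.parameter_maps()
    valid = stack.valid_mask()
    if int(valid.sum()) < 3:
        raise ValueError("need at least 3 jointly valid pixels")
    data = np.stack([maps[k][valid] for k in PARAMETER_ORDER])
    sd = data.std(axis=1)
    flat = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data)
    r[flat, :] = np.nan
    r[:, flat] = np.nan
    np.fill_diagonal(r, 1.0)
    return r


def aggregate_correlations(matrices: Sequence[np.ndarray]) -> CorrelationSummary:
    """Element-wise mean and sd of per-image correlation matrices.

    Missing entries are excluded pairwise; the number of contributing images
    is recorded per entry.  The sd uses the population estimator so a single
    image yields sd = 0.
    """
    if len(matrices) == 0:
        raise ValueError("need at least one correlation matrix")
    arrs = [np.asarray(m, float) for m in matrices]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("correlation matrices differ in shape")
    cube = np.stack(arrs)
    counts = np.isfinite(cube).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(cube, axis=0)
        sd = np.nanstd(cube, axis=0, ddof=0)
    mean[counts == 0] = np.nan
    sd[counts == 0] = np.nan
    return CorrelationSummary(
        mean_matrix=mean, sd_matrix=sd, n_images=len(arrs),
        p_matrix=pairwise_significance(arrs), counts=counts,
    )


def pairwise_significance(matrices: Sequence[np.ndarray]) -> np.ndarray:
    """Two-sided one-sample t-test of Fisher-z coefficients against zero.

    Needs at least 3 images per entry; otherwise the p-value is missing.
    Degenerate zero-variance samples give p = 0 for a nonzero mean and p = 1
    for a zero mean.  Diagonal entries (self-correlation) are not tested.
    """
    arrs = [np.asarray(m, float) for m in matrices]
    k = arrs[0].shape[0]
    cube = np.stack(arrs)
    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            vals = cube[:, i, j]
            vals = vals[np.isfinite(vals)]
            if vals.size < 3:
                continue
            z = np.arctanh(np.clip(vals, -1 + 1e-12, 1 - 1e-12))
            if z.std(ddof=1) == 0:
                pv = 0.0 if z.mean() != 0 else 1.0
            else:
                pv = float(stats.ttest_1samp(z, 0.0).pvalue)
            p[i, j] = p[j, i] = pv
    return p
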