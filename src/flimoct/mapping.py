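"""Assembly of per-pixel deconvolution results into co-registered maps.

A raster scan becomes a :class:`FLImMapStack`: four lifetime maps, four
intensity-ratio maps, intensity and SNR maps, and a foreground mask, all on
the same grid.  Filtering by the channel-3 SNR gate removes a pixel from
every parameter map at once so the valid support of all maps is identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from . import config
from .deconv import (DeconvResult, LaguerreDeconvolver, channel_intensity_ratios,
                     laguerre_basis, subtract_pedestal)
from .phantom import RawFLImScan


@dataclass
class FLImMapStack:
    """Eight co-registered FLIm parameter maps plus support metadata.

    Missing pixels are NaN.  ``intr_maps`` sum to 1 at every valid pixel.
    """

    lt_maps: np.ndarray          # (4, H, W) ns
    intr_maps: np.ndarray        # (4, H, W)
    intensity_maps: np.ndarray   # (4, H, W)
    snr_maps: np.ndarray         # (4, H, W)
    foreground_mask: np.ndarray  # (H, W) bool
    pitch_um: float = config.PIXEL_PITCH_UM
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.foreground_mask.shape

    def valid_mask(self) -> np.ndarray:
        """Pixels finite in every one of the eight parameter maps."""
        ok = np.isfinite(self.lt_maps).all(axis=0)
        ok &= np.isfinite(self.intr_maps).all(axis=0)
        return ok

    def parameter_maps(self) -> dict[str, np.ndarray]:
        """The eight maps keyed LT1..LT4, INTR1..INTR4 (correlogram order)."""
        out = {}
        for c in range(4):
            out[f"LT{c + 1}"] = self.lt_maps[c]
        for c in range(4):
            out[f"INTR{c + 1}"] = self.intr_maps[c]
        return out


def assemble_map_stack(results: dict[tuple[int, int, int], DeconvResult],
                       shape: tuple[int, int],
                       pitch_um: float = config.PIXEL_PITCH_UM,
                       foreground_mask: np.ndarray | None = None) -> FLImMapStack:
    """Place per-pixel deconvolution results into parameter grids.

    ``results`` maps ``(row, col, channel)`` (channel 1-based) to a
    :class:`DeconvResult`.  Unscanned pixels stay missing; duplicate entries
    are rejected by construction of the dict key, and coordinates outside
    ``shape`` raise.
    """
    H, W = shape
    lt = np.full((4, H, W), np.nan)
    inten = np.full((4, H, W), np.nan)
    snr = np.full((4, H, W), np.nan)
    for (r, c, ch), res in results.items():
        if not (0 <= r < H and 0 <= c < W):
            raise ValueError(f"pixel ({r}, {c}) outside grid {shape}")
        if not 1 <= ch <= 4:
            raise ValueError(f"channel {ch} out of range 1..4")
        lt[ch - 1, r, c] = res.avg_lifetime_ns
        inten[ch - 1, r, c] = res.intensity
        snr[ch - 1, r, c] = res.snr

    intr = np.full((4, H, W), np.nan)
    have_all = np.isfinite(inten).all(axis=0)
    if have_all.any():
        v = inten[:, have_all]
        total = v.sum(axis=0)
        good = total > 0
        ratios = np.full_like(v, np.nan)
        ratios[:, good] = v[:, good] / total[good]
        intr[:, have_all] = ratios

    # a pixel missing in any channel is missing in all eight maps
    complete = np.isfinite(lt).all(axis=0) & have_all
    for arr in (lt, intr):
        arr[:, ~complete] = np.nan

    if foreground_mask is None:
        foreground_mask = complete
    meta = {"pitch_um": pitch_um,
            "channel_bands_nm": config.CHANNEL_BANDS_NM,
            "n_results": len(results)}
    return FLImMapStack(lt_maps=lt, intr_maps=intr, intensity_maps=inten,
                        snr_maps=snr, foreground_mask=foreground_mask,
                        pitch_um=pitch_um, meta=meta)


def segment_foreground(intensity_map: np.ndarray,
                       hole_fill_fraction: float = 0.02) -> np.ndarray:
    """Otsu-threshold construct segmentation on a total-intensity image.

    Keeps the largest connected component above the Otsu threshold and fills
    holes smaller than ``hole_fill_fraction`` of the component area, so a
    genuine central void persists as a hole.
    """
    img = np.asarray(intensity_map, float)
    if img.size == 0:
        raise ValueError("empty intensity map")
    finite = np.nan_to_num(img, nan=0.0)
    if finite.max() <= finite.min():
        raise ValueError("no foreground found (flat intensity image)")
    th = threshold_otsu(finite)
    fg = finite > th
    if not fg.any():
        raise ValueError("no foreground found above the Otsu threshold")
    lab = cc_label(fg)
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    comp = lab == largest
    area = int(comp.sum())

    filled = ndimage.binary_fill_holes(comp)
    holes = filled & ~comp
    hole_lab, n_holes = ndimage.label(holes)
    if n_holes:
        sizes = ndimage.sum_labels(np.ones_like(hole_lab, float), hole_lab,
                                   np.arange(1, n_holes + 1))
        small = np.flatnonzero(sizes < hole_fill_fraction * area) + 1
        comp = comp | np.isin(hole_lab, small)
    return comp


def snr_filter(stack: FLImMapStack,
               threshold: float = config.SNR_THRESHOLD,
               gate_channel: int = 3) -> FLImMapStack:
    """Mask out pixels whose gate-channel SNR falls below threshold.

    Channel 3 is the gate by default (the weakest channel); the same filter
    is applied to every parameter map so their valid supports stay identical.
    An empty survivor set is allowed and flagged in the metadata.
    """
    gate = stack.snr_maps[gate_channel - 1]
    drop = ~(gate >= threshold)       # NaN gate -> dropped
    lt = stack.lt_maps.copy()
    intr = stack.intr_maps.copy()
    lt[:, drop] = np.nan
    intr[:, drop] = np.nan
    meta = dict(stack.meta)
    meta["snr_threshold"] = threshold
    meta["snr_gate_channel"] = gate_channel
    meta["snr_survivors"] = int((~drop).sum())
    meta["snr_empty"] = bool(drop.all())
    return replace(stack, lt_maps=lt, intr_maps=intr, meta=meta)


def process_scan(scan: RawFLImScan,
                 order: int = config.LAGUERRE_ORDER,
                 alphas: tuple[float, ...] | None = None,
                 segment: bool = True) -> FLImMapStack:
    """Run the full per-pixel deconvolution over a raw scan.

    Demultiplexes every pixel, deconvolves each channel with its configured
    Laguerre basis (vectorized across pixels), assembles the eight parameter
    maps, and segments the construct foreground from total intensity.
    """
    if alphas is None:
        alphas = config.LAGUERRE_ALPHA
    H, W, _ = scan.waveforms.shape
    n_win = scan.window_samples
    dt = scan.dt_ns
    flat = scan.waveforms.reshape(H * W, -1)
    offsets = [int(round(o / dt)) for o in scan.offsets_ns]
    nb = config.BASELINE_SAMPLES
    irf = np.asarray(scan.irf.samples, float)

    lt = np.empty((4, H * W))
    inten = np.empty((4, H * W))
    snr = np.empty((4, H * W))
    for c in range(4):
        Y = subtract_pedestal(flat[:, offsets[c]:offsets[c] + n_win], c + 1, nb)
        basis = laguerre_basis(n_win, order, alphas[c])
        eng = LaguerreDeconvolver(irf, basis, dt_ns=dt)
        lts, intens, _ = eng.batch(Y)
        lt[c] = lts
        inten[c] = intens
        bsd = Y[:, :nb].std(axis=1)
        peak = Y.max(axis=1) - Y[:, :nb].mean(axis=1)
        with np.errstate(divide="ignore"):
            snr[c] = np.where(bsd > 0, peak / bsd, np.inf)

    lt = lt.reshape(4, H, W)
    inten = inten.reshape(4, H, W)
    snr = snr.reshape(4, H, W)

    total = inten.sum(axis=0)
    fg = segment_foreground(total) if segment else np.ones((H, W), bool)

    with np.errstate(invalid="ignore", divide="ignore"):
        tot = inten.sum(axis=0)
        intr = np.where(tot > 0, inten / np.where(tot > 0, tot, 1.0), np.nan)

    lt = np.where(fg[None], lt, np.nan)
    intr = np.where(fg[None], intr, np.nan)
    bad = ~np.isfinite(lt).all(axis=0) | ~np.isfinite(intr).all(axis=0)
    lt[:, bad] = np.nan
    intr[:, bad] = np.nan

    return FLImMapStack(
        lt_maps=lt, intr_maps=intr, intensity_maps=inten, snr_maps=snr,
        foreground_mask=fg, pitch_um=scan.pitch_um,
        meta={"order": order, "alphas": tuple(alphas),
              "channel_bands_nm": config.CHANNEL_BANDS_NM},
    )
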