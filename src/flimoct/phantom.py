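"""Synthetic construct phantoms and raw-signal rendering.

This module generates the ground truth against which the whole pipeline is
validated: a circular engineered-cartilage construct with a collagen-rich
periphery and cell-dominated interior, an optional central void, and an
optional subsurface cyst.  From a :class:`Phantom` it renders (a) raw
time-multiplexed FLIm raster scans — per-pixel multi-exponential decays
convolved with the instrument response and corrupted by shot plus additive
noise — and (b) swept-source OCT spectral interferograms from a layered
scattering slab.

The radial composition endpoints are solved so that the default ("week-4")
phantom reproduces measured construct lifetimes: channel 1 ≈ 3.12 ns at the
periphery vs ≈ 2.89 ns at the center, with channels 3-4 nearly flat.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy import ndimage, signal

from . import config


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FluorophoreProfile:
    """Effective emission of one endogenous fluorophore.

    ``channel_yields`` are relative time-integrated emission weights in the
    four spectral channels (CH1 375-410, CH2 450-485, CH3 532-565,
    CH4 595-660 nm); ``lifetimes_ns`` are effective mono-exponential decay
    constants per channel.
    """

    name: str
    channel_yields: tuple[float, float, float, float]
    lifetimes_ns: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        y = np.asarray(self.channel_yields, float)
        t = np.asarray(self.lifetimes_ns, float)
        if y.shape != (4,) or t.shape != (4,):
            raise ValueError("need exactly 4 channel yields and lifetimes")
        if np.any(y < 0) or not np.any(y > 0):
            raise ValueError("channel_yields must be >= 0 with at least one > 0")
        if np.any(t <= 0):
            raise ValueError("lifetimes must be positive")


def default_fluorophores() -> tuple[FluorophoreProfile, ...]:
    """Collagen / FAD / NADH-like library from the package configuration."""
    return tuple(
        FluorophoreProfile(name, tuple(d["channel_yields"]), tuple(d["lifetimes_ns"]))
        for name, d in config.FLUOROPHORE_LIBRARY.items()
    )


@dataclass(frozen=True)
class CollagenGradient:
    """Radial mixing rule: collagen weight rises monotonically outward.

    ``weight(r) = center + (edge - center) * r**exponent`` with the remaining
    (cellular) weight split between FAD and NADH at a fixed ratio.  Weights
    always sum to one.
    """

    center: float = config.COLLAGEN_WEIGHT_CENTER
    edge: float = config.COLLAGEN_WEIGHT_EDGE
    exponent: float = 2.0
    fad_fraction: float = config.CELLULAR_FAD_FRACTION

    def __call__(self, r_hat: np.ndarray) -> np.ndarray:
        r = np.clip(np.asarray(r_hat, float), 0.0, 1.0)
        w_col = self.center + (self.edge - self.center) * r ** self.exponent
        w_cell = 1.0 - w_col
        return np.stack(
            [w_col, self.fad_fraction * w_cell, (1.0 - self.fad_fraction) * w_cell],
            axis=-1,
        )


@dataclass(frozen=True)
class VoidSpec:
    """Central cavity: no fluorescence signal, no OCT scattering."""

    center_offset_mm: tuple[float, float] = (0.0, 0.0)
    radius_mm: float = config.VOID_RADIUS_MM


@dataclass(frozen=True)
class CystSpec:
    """Subsurface low-scattering ellipsoid (OCT only)."""

    center_offset_mm: tuple[float, float] = (0.0, 0.0)
    radius_lateral_mm: float = config.CYST_RADIUS_LATERAL_MM
    radius_axial_um: float = config.CYST_RADIUS_AXIAL_UM
    depth_um: float | None = None  # None -> slab mid-depth


@dataclass(frozen=True)
class NoiseSpec:
    additive_sd: float = config.ADDITIVE_NOISE_SD
    shot_scale: float = config.SHOT_NOISE_SCALE


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic construct experiment."""

    diameter_mm: float = config.CONSTRUCT_DIAMETER_MM
    pixel_pitch_um: float = config.PIXEL_PITCH_UM
    composition_profile: Callable[[np.ndarray], np.ndarray] = field(
        default_factory=CollagenGradient
    )
    fluorophores: tuple[FluorophoreProfile, ...] = field(
        default_factory=default_fluorophores
    )
    void_spec: VoidSpec | None = None
    cyst_spec: CystSpec | None = None
    heterogeneity_sd: float = config.HETEROGENEITY_SD_WEEK4
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    amplitude: float = config.SIGNAL_AMPLITUDE
    surface_depth_um: float = config.OCT_SURFACE_DEPTH_UM
    slab_thickness_um: float = config.OCT_SLAB_THICKNESS_UM
    surface_tilt_um_per_px: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0 or self.pixel_pitch_um <= 0:
            raise ValueError("diameter and pixel pitch must be positive")
        if self.heterogeneity_sd < 0:
            raise ValueError("heterogeneity_sd must be >= 0")
        if self.void_spec is not None:
            dr = float(np.hypot(*self.void_spec.center_offset_mm))
            if self.void_spec.radius_mm < 0:
                raise ValueError("void radius must be >= 0")
            if dr + self.void_spec.radius_mm > self.diameter_mm / 2:
                raise ValueError("void is not contained in the construct")
        if self.cyst_spec is not None:
            dr = float(np.hypot(*self.cyst_spec.center_offset_mm))
            if dr + self.cyst_spec.radius_lateral_mm > self.diameter_mm / 2:
                raise ValueError("cyst is not laterally contained in the construct")
            if self.cyst_spec.radius_axial_um > self.slab_thickness_um / 2:
                raise ValueError("cyst is axially larger than the slab")

    @property
    def grid_shape(self) -> tuple[int, int]:
        n = int(round(self.diameter_mm * 1000.0 / self.pixel_pitch_um))
        return (n, n)


@dataclass(frozen=True)
class IRFRecord:
    """Measured instrument response on the channel-window time base."""

    samples: np.ndarray
    dt_ns: float = config.DT_NS
    fwhm_ns: float = config.IRF_FWHM_NS

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, float)
        if self.dt_ns <= 0:
            raise ValueError("dt_ns must be positive")
        if np.any(s < 0) or s.sum() <= 0:
            raise ValueError("IRF samples must be >= 0 with positive sum")


def default_irf() -> IRFRecord:
    return IRFRecord(samples=config.default_irf_samples())


@dataclass
class Phantom:
    """Ground truth rendered from a :class:`PhantomSpec`."""

    spec: PhantomSpec
    composition_maps: np.ndarray        # (n_fluor, H, W), weights sum to 1
    true_lifetime_maps: np.ndarray      # (4, H, W) ns, NaN off foreground
    foreground_mask: np.ndarray         # (H, W) bool; False inside a void
    reflectivity_volume: np.ndarray     # (Nz, H, W) scattering amplitude
    surface_index: np.ndarray           # (H, W) int, first tissue voxel
    axial_pitch_um: float
    radius_px: float
    center_px: tuple[float, float]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.foreground_mask.shape


@dataclass
class RawFLImScan:
    """Raw raster scan: one multiplexed waveform per pixel."""

    waveforms: np.ndarray               # (H, W, RECORD_SAMPLES)
    irf: IRFRecord
    dt_ns: float
    offsets_ns: tuple[float, ...]
    window_samples: int
    pitch_um: float


# ---------------------------------------------------------------------------
# Phantom construction
# ---------------------------------------------------------------------------

def _smooth_unit_field(shape: tuple[int, int], sigma_px: float,
                       rng: np.random.Generator,
                       norm_mask: np.ndarray) -> np.ndarray:
    """Smooth Gaussian random field with unit sd over ``norm_mask``."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_px)
    sd = f[norm_mask].std()
    return f / sd if sd > 0 else f


def build_phantom(spec: PhantomSpec) -> Phantom:
    """Render ground-truth composition, lifetime, and scattering maps.

    The per-channel true lifetime at a pixel is the yield-weighted mean of the
    component lifetimes plus a smooth random field of standard deviation
    ``spec.heterogeneity_sd`` (scaled per channel).  The foreground mask is
    False outside the construct disk and inside any void.
    """
    H, W = spec.grid_shape
    ss = np.random.SeedSequence([spec.seed & 0x7FFFFFFF, 0xF1])
    rng_field, rng_speckle = (np.random.default_rng(s) for s in ss.spawn(2))

    center = ((H - 1) / 2.0, (W - 1) / 2.0)
    radius_px = spec.diameter_mm * 1000.0 / spec.pixel_pitch_um / 2.0
    rows, cols = np.mgrid[0:H, 0:W]
    r_px = np.hypot(rows - center[0], cols - center[1])
    disk = r_px <= radius_px

    weights = spec.composition_profile(r_px / radius_px)   # (H, W, F)
    if np.any(weights < -1e-12):
        raise ValueError("composition profile produced negative weights")
    weights = np.clip(weights, 0.0, None)
    weights /= weights.sum(axis=-1, keepdims=True)
    n_fluor = weights.shape[-1]
    if n_fluor != len(spec.fluorophores):
        raise ValueError("composition profile width != number of fluorophores")

    yields = np.array([f.channel_yields for f in spec.fluorophores])   # (F, 4)
    taus = np.array([f.lifetimes_ns for f in spec.fluorophores])       # (F, 4)

    # yield-weighted mean lifetime per channel
    wy = np.einsum("hwf,fc->chw", weights, yields)
    wyt = np.einsum("hwf,fc->chw", weights, yields * taus)
    lifetime = wyt / wy

    sigma_px = config.HETEROGENEITY_CORR_UM / spec.pixel_pitch_um
    fld = _smooth_unit_field((H, W), sigma_px, rng_field, disk)
    for c, scale in enumerate(config.HETEROGENEITY_CHANNEL_SCALE):
        lifetime[c] += spec.heterogeneity_sd * scale * fld
    lifetime = np.clip(lifetime, 0.2, None)

    mask = disk.copy()
    if spec.void_spec is not None and spec.void_spec.radius_mm > 0:
        vo = spec.void_spec
        vr = np.hypot(
            rows - (center[0] + vo.center_offset_mm[0] * 1000.0 / spec.pixel_pitch_um),
            cols - (center[1] + vo.center_offset_mm[1] * 1000.0 / spec.pixel_pitch_um),
        )
        mask &= vr > vo.radius_mm * 1000.0 / spec.pixel_pitch_um

    lifetime[:, ~mask] = np.nan

    refl, surface, dz = _build_reflectivity(spec, disk, rows, cols, center,
                                            rng_speckle)

    return Phantom(
        spec=spec,
        composition_maps=np.moveaxis(weights, -1, 0),
        true_lifetime_maps=lifetime,
        foreground_mask=mask,
        reflectivity_volume=refl,
        surface_index=surface,
        axial_pitch_um=dz,
        radius_px=radius_px,
        center_px=center,
    )


def _build_reflectivity(spec: PhantomSpec, disk: np.ndarray,
                        rows: np.ndarray, cols: np.ndarray,
                        center: tuple[float, float],
                        rng: np.random.Generator):
    """Layered scattering slab with speckle, surface line, and cavities."""
    from .oct import default_source  # local import avoids a cycle

    src = default_source()
    dz = src.axial_pitch_um
    nz = src.n_k_samples // 2
    H, W = disk.shape

    tilt_r, tilt_c = spec.surface_tilt_um_per_px
    surf_um = (spec.surface_depth_um
               + tilt_r * (rows - center[0]) + tilt_c * (cols - center[1]))
    surface = np.clip(np.round(surf_um / dz).astype(int), 0, nz - 1)

    zidx = np.arange(nz)[:, None, None]
    depth_um = (zidx - surface[None]) * dz
    thick = spec.slab_thickness_um
    inside = (depth_um >= 0) & (depth_um < thick) & disk[None]

    amp = np.where(inside,
                   np.exp(-config.OCT_ATTENUATION_PER_UM
                          * np.clip(depth_um, 0.0, None)),
                   0.0)
    amp *= rng.lognormal(0.0, config.OCT_SPECKLE_SD, amp.shape)

    def lateral_px(offset_mm):
        return (center[0] + offset_mm[0] * 1000.0 / spec.pixel_pitch_um,
                center[1] + offset_mm[1] * 1000.0 / spec.pixel_pitch_um)

    if spec.void_spec is not None and spec.void_spec.radius_mm > 0:
        vo = spec.void_spec
        vr_px = vo.radius_mm * 1000.0 / spec.pixel_pitch_um
        vc = lateral_px(vo.center_offset_mm)
        lateral = np.hypot(rows - vc[0], cols - vc[1]) <= vr_px
        amp[inside & lateral[None]] *= config.HYPO_SCATTER_FRACTION

    if spec.cyst_spec is not None:
        cy = spec.cyst_spec
        cdepth = thick / 2.0 if cy.depth_um is None else cy.depth_um
        cc = lateral_px(cy.center_offset_mm)
        rlat_px = cy.radius_lateral_mm * 1000.0 / spec.pixel_pitch_um
        d2 = (((depth_um - cdepth) / cy.radius_axial_um) ** 2
              + ((rows - cc[0])[None] / rlat_px) ** 2
              + ((cols - cc[1])[None] / rlat_px) ** 2)
        amp[(d2 <= 1.0) & inside] *= config.HYPO_SCATTER_FRACTION

    # specular surface line, added last: the construct's top surface is
    # intact even above interior cavities
    line = np.take_along_axis(amp, surface[None], axis=0)
    np.put_along_axis(amp, surface[None],
                      line + config.OCT_SURFACE_REFLECTION * disk[None], axis=0)

    return amp, surface, dz


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

STAGES = ("week2", "week4_invitro", "week4_invivo")


def preset_spec(stage: str, seed: int = 0) -> PhantomSpec:
    """Phantom preset for an imaging time point.

    ``week2`` is an immature construct: same composition gradient as week 4
    but with twice the lifetime heterogeneity, so the homogeneity index rises
    with maturation.  ``week4_invitro`` is the mature in-vitro construct with
    the central void.  ``week4_invivo`` is shrunken, void-free, and carries a
    subsurface cyst.
    """
    if stage == "week2":
        return PhantomSpec(heterogeneity_sd=config.HETEROGENEITY_SD_WEEK2,
                           void_spec=VoidSpec(), seed=seed)
    if stage == "week4_invitro":
        return PhantomSpec(heterogeneity_sd=config.HETEROGENEITY_SD_WEEK4,
                           void_spec=VoidSpec(), seed=seed)
    if stage == "week4_invivo":
        return PhantomSpec(diameter_mm=config.INVIVO_DIAMETER_MM,
                           heterogeneity_sd=config.HETEROGENEITY_SD_WEEK4,
                           void_spec=None, cyst_spec=CystSpec(), seed=seed)
    raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")


# ---------------------------------------------------------------------------
# FLIm rendering
# ---------------------------------------------------------------------------

def render_flim_scan(phantom: Phantom, irf: IRFRecord | None = None,
                     spec: PhantomSpec | None = None) -> RawFLImScan:
    """Render the raw time-multiplexed FLIm raster scan of a phantom.

    For each foreground pixel and spectral channel the fluorescence impulse
    response is the weighted sum of the component mono-exponentials, with all
    component lifetimes rescaled by a common per-pixel factor so the mixture
    mean equals the phantom's true lifetime (including the heterogeneity
    field).  The response is convolved with the IRF, placed at the channel's
    multiplex delay, and corrupted by shot plus additive Gaussian noise.
    Background pixels contain noise only.  Bit-identical under a fixed seed.
    """
    if irf is None:
        irf = default_irf()
    if spec is None:
        spec = phantom.spec
    if abs(irf.dt_ns - config.DT_NS) > 1e-12:
        raise ValueError("IRF sample interval does not match the scan time base")
    _check_windows(config.CHANNEL_OFFSETS_NS, config.WINDOW_SAMPLES,
                   config.RECORD_SAMPLES, config.DT_NS)

    H, W = phantom.grid_shape
    n_rec = config.RECORD_SAMPLES
    dt = config.DT_NS
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed & 0x7FFFFFFF, 0xF2]))

    mask = phantom.foreground_mask
    idx = np.flatnonzero(mask.ravel())
    npx = idx.size
    weights = phantom.composition_maps.reshape(len(spec.fluorophores), -1)[:, idx]
    signal_flat = np.zeros((H * W, n_rec))

    yields = np.array([f.channel_yields for f in spec.fluorophores])
    taus = np.array([f.lifetimes_ns for f in spec.fluorophores])

    for c in range(4):
        off = int(round(config.CHANNEL_OFFSETS_NS[c] / dt))
        nt = n_rec - off
        t_rel = np.arange(nt) * dt
        # per-pixel rescaling so the mixture mean matches the true lifetime map
        nominal = (weights * (yields[:, c] * taus[:, c])[:, None]).sum(0) / \
                  (weights * yields[:, c][:, None]).sum(0)
        target = phantom.true_lifetime_maps[c].ravel()[idx]
        g = target / nominal
        gain = config.CHANNEL_GAINS[c] * spec.amplitude
        chunk = np.zeros((npx, nt))
        for f in range(len(spec.fluorophores)):
            tau_px = g * taus[f, c]
            amp = gain * weights[f] * yields[f, c] / tau_px
            chunk += amp[:, None] * np.exp(-t_rel[None, :] / tau_px[:, None])
        signal_flat[idx, off:] += chunk

    # IRF convolution along time (kernel carries the onset delay)
    kernel = np.asarray(irf.samples, float)
    sig = signal.fftconvolve(signal_flat, kernel[None, :], axes=1)[:, :n_rec]

    noise_sd = np.sqrt(spec.noise.additive_sd ** 2
                       + spec.noise.shot_scale * np.clip(sig, 0.0, None))
    waveforms = sig + rng.standard_normal(sig.shape) * noise_sd

    return RawFLImScan(
        waveforms=waveforms.reshape(H, W, n_rec),
        irf=irf,
        dt_ns=dt,
        offsets_ns=config.CHANNEL_OFFSETS_NS,
        window_samples=config.WINDOW_SAMPLES,
        pitch_um=spec.pixel_pitch_um,
    )


def _check_windows(offsets_ns, window_samples, record_samples, dt):
    off = np.asarray([int(round(o / dt)) for o in offsets_ns])
    order = np.argsort(off)
    so = off[order]
    if np.any(np.diff(so) < window_samples):
        raise ValueError("channel windows overlap")
    if so[-1] + window_samples > record_samples:
        raise ValueError("channel window extends past the record")


# ---------------------------------------------------------------------------
# OCT rendering
# ---------------------------------------------------------------------------

def render_oct_fringes(phantom: Phantom, source=None, seed: int | None = None):
    """Render swept-source spectral interferograms of the phantom.

    Per A-line the fringe signal is ``envelope(k) * sum_z amplitude(z) *
    cos(2 k z)`` sampled uniformly in wavenumber, plus detector noise.
    Returns an :class:`flimoct.oct.InterferogramStack` whose lateral shape
    matches the phantom grid.
    """
    from .oct import InterferogramStack, default_source

    if source is None:
        source = default_source()
    nz, H, W = phantom.reflectivity_volume.shape
    if nz > source.n_k_samples // 2:
        raise ValueError("reflectivity grid deeper than the unambiguous range")
    if seed is None:
        seed = phantom.spec.seed
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0xF3]))

    z_um = np.arange(nz) * source.axial_pitch_um
    phase = 2.0 * source.k_per_um[:, None] * z_um[None, :]
    kernel_cos = source.envelope[:, None] * np.cos(phase)
    kernel_sin = source.envelope[:, None] * np.sin(phase)
    amp = phantom.reflectivity_volume.reshape(nz, -1)
    # random scatterer phase (sub-wavelength position jitter) develops true
    # speckle and decorrelates the lateral mean A-line
    phi = rng.uniform(0.0, 2.0 * np.pi, amp.shape)
    fringes = kernel_cos @ (amp * np.cos(phi)) - kernel_sin @ (amp * np.sin(phi))
    peak = np.abs(fringes).max()
    if peak > 0:
        fringes += rng.standard_normal(fringes.shape) * (
            config.OCT_FRINGE_NOISE * peak)
    return InterferogramStack(
        fringes=fringes.reshape(source.n_k_samples, H, W),
        source=source,
        lateral_pitch_um=phantom.spec.pixel_pitch_um,
    )


def make_week4_default(seed: int = 0) -> tuple[Phantom, RawFLImScan]:
    """Convenience: default week-4 in-vitro phantom and its rendered scan."""
    spec = preset_spec("week4_invitro", seed=seed)
    ph = build_phantom(spec)
    return ph, render_flim_scan(ph)
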