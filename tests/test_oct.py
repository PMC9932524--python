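"""Swept-source OCT reconstruction and hypoechoic-region detection."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.signal import find_peaks

import flimoct as F
from flimoct.oct import (NO_SURFACE, SourceSpectrum, assemble_volume,
                         axial_psf_fwhm, default_source,
                         detect_hypoechoic_regions, enface_projection,
                         reconstruct_ascan, render_point_reflectors,
                         resample_uniform_k)


@pytest.fixture(scope="module")
def source():
    return default_source()


# ---------------------------------------------------------------------------
# A-scan reconstruction
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("frac", [0.1, 0.3, 0.5, 0.7, 0.9])
def test_single_reflector_localization(source, frac):
    z = frac * source.max_depth_um
    prof = reconstruct_ascan(render_point_reflectors([z], [1.0], source), source)
    err_px = abs(prof.argmax() * source.axial_pitch_um - z) / source.axial_pitch_um
    assert err_px <= 1.0


def test_zero_input_gives_flat_floor(source):
    prof = reconstruct_ascan(np.zeros(source.n_k_samples), source)
    assert np.all(prof == prof[0])


def test_two_reflectors_resolved_at_3x_resolution(source):
    sep = 3 * source.theoretical_axial_fwhm_um
    fr = render_point_reflectors([500.0, 500.0 + sep], [1.0, 1.0], source)
    prof = reconstruct_ascan(fr, source, window=None, pad=4)
    peaks, _ = find_peaks(prof, height=-10)
    assert len(peaks) >= 2
    valley = prof[peaks[0]:peaks[1] + 1].min()
    assert prof[peaks[0]] - valley >= 3.0
    assert prof[peaks[1]] - valley >= 3.0


def test_reflector_beyond_range_rejected(source):
    with pytest.raises(ValueError):
        render_point_reflectors([source.max_depth_um * 1.1], [1.0], source)


def test_fringe_length_mismatch_rejected(source):
    with pytest.raises(ValueError):
        reconstruct_ascan(np.zeros(100), source)


def test_energy_monotone_in_reflector_amplitude(source):
    energies = []
    for amp in (1.0, 2.0, 4.0):
        fr = render_point_reflectors([600.0], [amp], source)
        lin = reconstruct_ascan(fr, source, log_compress=False)
        energies.append(float((lin ** 2).sum()))
    assert energies[0] < energies[1] < energies[2]


def test_resample_uniform_k_passthrough_equivalent(source):
    k = source.k_per_um
    z = 400.0
    fr = source.envelope * np.cos(2 * k * z)
    rs = resample_uniform_k(fr, k)
    assert np.allclose(rs, fr, atol=1e-9)


# ---------------------------------------------------------------------------
# volume assembly
# ---------------------------------------------------------------------------

def test_bscan_extraction_bookkeeping(source):
    nz = 16
    ascans = np.arange(4 * 4 * nz, dtype=float).reshape(4, 4, nz)
    vol = assemble_volume(ascans, axial_pitch_um=4.0)
    b = vol.bscan(2)
    assert b.shape == (nz, 4)
    assert np.array_equal(b[:, 1], ascans[1, 2])


def test_assemble_rejects_ragged():
    ragged = np.empty(2, dtype=object)
    ragged[0] = np.zeros(5)
    ragged[1] = np.zeros(7)
    with pytest.raises(ValueError):
        assemble_volume(ragged, axial_pitch_um=4.0)


def test_flat_surface_constant():
    ph = F.build_phantom(F.PhantomSpec(void_spec=None, seed=0))
    vol = F.reconstruct_volume(F.render_oct_fringes(ph))
    s = vol.surface_map[vol.surface_map != NO_SURFACE]
    assert s.max() - s.min() <= 2  # constant within +-1 pixel


def test_tilted_surface_linear_ramp():
    spec = F.PhantomSpec(void_spec=None, surface_depth_um=300.0,
                         surface_tilt_um_per_px=(0.0, 4.0), seed=0)
    ph = F.build_phantom(spec)
    vol = F.reconstruct_volume(F.render_oct_fringes(ph))
    fp = ndimage.binary_erosion(vol.surface_map != NO_SURFACE, iterations=2)
    cols = np.nonzero(fp[25])[0]
    row = vol.surface_map[25]
    slope, intercept = np.polyfit(cols, row[cols], 1)
    assert slope == pytest.approx(4.0 / vol.axial_pitch_um, rel=0.05)
    assert np.abs(row[cols] - (slope * cols + intercept)).max() <= 1.0


# ---------------------------------------------------------------------------
# en-face projection
# ---------------------------------------------------------------------------

def test_enface_constant_volume(source):
    vol = F.OCTVolume(log_magnitude=np.full((10, 3, 3), -7.0),
                      axial_pitch_um=4.0, lateral_pitch_um=100.0,
                      surface_map=np.zeros((3, 3), int))
    assert np.all(enface_projection(vol, (2, 8)) == -7.0)


def test_enface_linearity_of_mean(source):
    rng = np.random.default_rng(0)
    vol = F.OCTVolume(log_magnitude=rng.normal(size=(8, 4, 4)),
                      axial_pitch_um=4.0, lateral_pitch_um=100.0,
                      surface_map=np.zeros((4, 4), int))
    full = enface_projection(vol, (0, 8))
    halves = 0.5 * (enface_projection(vol, (0, 4)) + enface_projection(vol, (4, 8)))
    assert np.allclose(full, halves)
    with pytest.raises(ValueError):
        enface_projection(vol, (5, 5))


def test_enface_minimum_inside_void_footprint():
    ph = F.build_phantom(F.preset_spec("week4_invitro", seed=1))
    vol = F.reconstruct_volume(F.render_oct_fringes(ph))
    fp = ndimage.binary_erosion(vol.surface_map != NO_SURFACE, iterations=3)
    surf = int(np.median(vol.surface_map[fp]))
    ef = ndimage.gaussian_filter(enface_projection(vol, (surf + 6, surf + 200)), 1.0)
    idx = np.unravel_index(np.argmin(np.where(fp, ef, np.inf)), ef.shape)
    void_radius_px = 5.0
    assert np.hypot(idx[0] - 24.5, idx[1] - 24.5) <= void_radius_px


# ---------------------------------------------------------------------------
# hypoechoic detection
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", [0, 1, 2])
def test_homogeneous_slab_yields_no_detection(seed):
    ph = F.build_phantom(F.PhantomSpec(void_spec=None, seed=seed))
    vol = F.reconstruct_volume(F.render_oct_fringes(ph))
    assert detect_hypoechoic_regions(vol) == []


@pytest.mark.parametrize("seed", [0, 1])
def test_cyst_phantom_yields_single_region_inside_truth(seed):
    ph = F.build_phantom(F.preset_spec("week4_invivo", seed=seed))
    vol = F.reconstruct_volume(F.render_oct_fringes(ph))
    regions = detect_hypoechoic_regions(vol)
    assert len(regions) == 1
    r = regions[0]
    assert r.mean_contrast_db < 0
    cz = (ph.spec.surface_depth_um + ph.spec.slab_thickness_um / 2) / vol.axial_pitch_um
    H = ph.grid_shape[0]
    d2 = (((r.centroid[0] - cz) * vol.axial_pitch_um / 150.0) ** 2
          + ((r.centroid[1] - (H - 1) / 2) / 5.0) ** 2
          + ((r.centroid[2] - (H - 1) / 2) / 5.0) ** 2)
    assert d2 <= 1.0


def test_two_disjoint_cavities_detected_with_volumes():
    spec = F.PhantomSpec(
        void_spec=F.VoidSpec(center_offset_mm=(0.0, -1.2), radius_mm=0.4),
        cyst_spec=F.CystSpec(center_offset_mm=(0.0, 1.2)), seed=2)
    ph = F.build_phantom(spec)
    vol = F.reconstruct_volume(F.render_oct_fringes(ph))
    regions = detect_hypoechoic_regions(vol)
    assert len(regions) == 2
    dz = vol.axial_pitch_um
    expected = sorted([np.pi * 4 ** 2 * round(1000 / dz),
                       4 / 3 * np.pi * (150 / dz) * 5 * 5], reverse=True)
    for r, exp in zip(regions, expected):
        assert abs(r.volume_voxels - exp) / exp <= 0.3


# ---------------------------------------------------------------------------
# point-spread function
# ---------------------------------------------------------------------------

def test_axial_fwhm_near_coherence_length(source):
    measured = axial_psf_fwhm(source)
    theory = source.theoretical_axial_fwhm_um
    assert abs(measured - theory) / theory <= 0.30


def test_doubling_bandwidth_halves_fwhm(source):
    wide = SourceSpectrum(half_bandwidth_nm=source.half_bandwidth_nm * 2)
    ratio = axial_psf_fwhm(wide) / axial_psf_fwhm(source)
    assert ratio == pytest.approx(0.5, rel=0.10)


def test_rectangular_envelope_narrower_with_sidelobes(source):
    """A flat spectrum gives a narrower main lobe but higher sidelobes than
    the Gaussian envelope."""
    k = source.k_per_um
    z = 500.0
    pad = 8
    dzp = source.axial_pitch_um / pad

    def measure(fr):
        prof = reconstruct_ascan(fr, source, window=None, pad=pad,
                                 log_compress=False)
        pk = int(prof.argmax())
        half = prof[pk] / 2
        l = pk - int(np.argmax(prof[pk::-1] < half))
        r = pk + int(np.argmax(prof[pk:] < half))
        # highest secondary peak outside the main lobe
        lobe = 6 * (r - l)
        side = max(prof[:max(pk - lobe, 1)].max(initial=0),
                   prof[pk + lobe:].max(initial=0))
        return (r - l) * dzp, side / prof[pk]

    fwhm_rect, side_rect = measure(np.cos(2 * k * z))
    fwhm_gauss, side_gauss = measure(source.envelope * np.cos(2 * k * z))
    assert fwhm_rect < fwhm_gauss
    assert side_rect > side_gauss
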