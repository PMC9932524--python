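"""Decay deconvolution, lifetime estimation, SNR, and intensity ratios."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flimoct import config
from flimoct.deconv import (DecayRecord, LaguerreDeconvolver, average_lifetime,
                            channel_intensity_ratios, deconvolve_decay,
                            demultiplex_record, estimate_snr, laguerre_basis,
                            select_alpha, subtract_pedestal)

N = config.WINDOW_SAMPLES
DT = config.DT_NS


# ---------------------------------------------------------------------------
# deconvolve_decay
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("tau", [2.0, 3.0, 4.0, 6.0])
def test_noiseless_monoexponential_recovery(engine, mono_decay, tau):
    res = engine.deconvolve(DecayRecord(samples=mono_decay(tau)))
    assert abs(res.avg_lifetime_ns - tau) <= 0.03


def test_zero_lifetime_limit(irf):
    """Fitting the IRF itself (a delta impulse response) with a basis suited
    to fast decays yields a near-zero average lifetime."""
    eng = LaguerreDeconvolver(irf, laguerre_basis(N, 20, 0.5))
    res = eng.deconvolve(DecayRecord(samples=irf.copy()))
    assert res.avg_lifetime_ns < 2 * DT


def test_fir_nonnegative_under_noise(engine, mono_decay):
    rng = np.random.default_rng(3)
    y0 = mono_decay(3.0)
    for _ in range(20):
        y = y0 + rng.normal(0, y0.max() / 25, N)
        res = engine.deconvolve(DecayRecord(samples=y))
        assert res.fir.min() >= -1e-9


def test_constrained_matches_unconstrained_when_feasible(engine, mono_decay):
    """On noiseless input whose FIR is nonnegative the fast path and the
    constrained solver coincide."""
    y = mono_decay(3.0)
    a_fast, constrained = engine.coefficients(y)
    assert not constrained
    a_slow = engine._solve_constrained(y)
    resid_fast = np.linalg.norm(y - engine.design @ a_fast)
    resid_slow = np.linalg.norm(y - engine.design @ a_slow)
    assert abs(resid_fast - resid_slow) <= 1e-6 * max(resid_fast, 1e-30)


def test_bias_at_snr25_within_5_percent(engine, mono_decay):
    rng = np.random.default_rng(11)
    for tau in (2.0, 3.0, 4.0, 6.0):
        y0 = mono_decay(tau)
        Y = y0[None, :] + rng.normal(0, y0.max() / 25, (200, N))
        lts, _, _ = engine.batch(Y)
        assert abs(np.nanmean(lts) - tau) <= 0.05 * tau


def test_error_median_decreases_with_snr(engine, mono_decay):
    rng = np.random.default_rng(12)
    for tau in (2.0, 4.0):
        medians = []
        y0 = mono_decay(tau)
        for snr in (10, 25, 50, 100):
            Y = y0[None, :] + rng.normal(0, y0.max() / snr, (200, N))
            lts, _, _ = engine.batch(Y)
            medians.append(np.nanmedian(np.abs(lts - tau)))
        assert all(a > b for a, b in zip(medians, medians[1:]))


@given(scale=st.floats(min_value=1e-3, max_value=1e4))
@settings(max_examples=20, deadline=None)
def test_scale_invariance(scale):
    """Scaling a decay leaves the lifetime unchanged and scales intensity."""
    irf = config.default_irf_samples()
    eng = LaguerreDeconvolver(irf, laguerre_basis(N, 12, 0.88))
    t = np.arange(N) * DT
    y = np.convolve(irf, np.exp(-t / 3.0))[:N]
    r1 = eng.deconvolve(DecayRecord(samples=y))
    r2 = eng.deconvolve(DecayRecord(samples=scale * y))
    assert r2.avg_lifetime_ns == pytest.approx(r1.avg_lifetime_ns, rel=1e-6)
    assert r2.intensity == pytest.approx(scale * r1.intensity, rel=1e-9)


def test_invalid_inputs_rejected(default_basis, mono_decay):
    with pytest.raises(ValueError):
        LaguerreDeconvolver(np.zeros(N), default_basis)
    with pytest.raises(ValueError):
        DecayRecord(samples=np.full(N, np.nan))
    bad_irf = type("IRF", (), {"samples": config.default_irf_samples(),
                               "dt_ns": 0.05})()
    with pytest.raises(ValueError):
        deconvolve_decay(DecayRecord(samples=mono_decay(3.0)), bad_irf,
                         default_basis)


# ---------------------------------------------------------------------------
# demultiplex
# ---------------------------------------------------------------------------

def _multiplex(windows):
    rec = np.zeros(config.RECORD_SAMPLES)
    for c, w in enumerate(windows):
        off = int(round(config.CHANNEL_OFFSETS_NS[c] / DT))
        rec[off:off + N] = w
    return rec


def test_demultiplex_round_trip(mono_decay):
    windows = [mono_decay(tau) for tau in (3.4, 3.2, 2.7, 2.9)]
    recs = demultiplex_record(_multiplex(windows), subtract_baseline=False)
    assert [r.channel for r in recs] == [1, 2, 3, 4]
    for r, w in zip(recs, windows):
        assert np.allclose(r.samples, w)


def test_demultiplex_offsets_permute_channels(mono_decay):
    windows = [mono_decay(tau) for tau in (3.4, 3.2, 2.7, 2.9)]
    rec = _multiplex(windows)
    permuted = [config.CHANNEL_OFFSETS_NS[i] for i in (1, 0, 3, 2)]
    recs = demultiplex_record(rec, offsets_ns=permuted, subtract_baseline=False)
    assert np.allclose(recs[0].samples, windows[1])
    assert np.allclose(recs[1].samples, windows[0])


def test_demultiplex_truncation_flag(window_time, irf):
    slow = np.convolve(irf, np.exp(-window_time / 20.0))[:N]   # ~0.7 lifetimes
    fast = np.convolve(irf, np.exp(-window_time / 1.0))[:N]
    recs = demultiplex_record(_multiplex([slow, fast, fast, fast]))
    assert recs[0].meta["truncated"]
    assert not recs[1].meta["truncated"]


def test_demultiplex_rejects_overlap():
    with pytest.raises(ValueError):
        demultiplex_record(np.zeros(700), offsets_ns=(0.0, 5.0, 28.0, 42.0))
    with pytest.raises(ValueError):
        demultiplex_record(np.zeros(300))


def test_pedestal_subtraction_removes_bleed(mono_decay):
    """A decaying tail from the previous channel is removed using only the
    pre-onset baseline samples."""
    tau_prev = config.PEDESTAL_TAU_NS[1]
    t = np.arange(N) * DT
    signal = mono_decay(3.0)
    y = signal + 0.05 * signal.max() * np.exp(-t / tau_prev)
    clean = subtract_pedestal(y, channel=2)
    # residual limited by the tiny signal leakage into the baseline window
    assert np.abs(clean - signal).max() < 1e-2 * signal.max()
    assert np.abs(clean - signal).max() < 0.2 * np.abs(y - signal).max()


# ---------------------------------------------------------------------------
# average_lifetime
# ---------------------------------------------------------------------------

def test_average_lifetime_impulses():
    h = np.zeros(100)
    h[0] = 1.0
    assert average_lifetime(h, DT) == 0.0
    h = np.zeros(100)
    h[25] = 1.0
    assert average_lifetime(h, DT) == pytest.approx(2.0)


def test_average_lifetime_geometric():
    tau = 2.70
    n = 4000   # long record: truncation negligible, discretization <= dt/2
    h = np.exp(-np.arange(n) * DT / tau)
    assert abs(average_lifetime(h, DT) - tau) <= DT / 2


def test_average_lifetime_degenerate():
    assert np.isnan(average_lifetime(np.zeros(50), DT))
    with pytest.raises(ValueError):
        average_lifetime(np.array([1.0, -0.5]), DT)


# ---------------------------------------------------------------------------
# intensity ratios
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("intensities,expected", [
    ((1, 1, 1, 1), (0.25, 0.25, 0.25, 0.25)),
    ((2, 0, 0, 0), (1, 0, 0, 0)),
    ((3, 2, 1, 4), (0.3, 0.2, 0.1, 0.4)),
])
def test_intensity_ratio_examples(intensities, expected):
    assert np.allclose(channel_intensity_ratios(intensities), expected)


def test_intensity_ratio_all_zero_is_missing():
    assert np.all(np.isnan(channel_intensity_ratios((0, 0, 0, 0))))


@given(st.lists(st.floats(min_value=0, max_value=1e6), min_size=4, max_size=4))
@settings(max_examples=50, deadline=None)
def test_intensity_ratios_sum_to_one(vals):
    r = channel_intensity_ratios(vals)
    if np.all(np.isnan(r)):
        assert sum(vals) == 0
    else:
        assert abs(r.sum() - 1.0) < 1e-12
        assert np.all(r >= 0)


# ---------------------------------------------------------------------------
# SNR
# ---------------------------------------------------------------------------

def test_snr_definitional():
    base = np.tile([4.0, -4.0], 5)       # mean 0, sd 4
    s = np.concatenate([base, [100.0], np.zeros(50)])
    assert estimate_snr(s) == pytest.approx(25.0)


def test_snr_linear_in_amplitude():
    baseline = np.tile([1.0, -1.0], 5)    # zero mean, fixed sd
    sig = np.zeros(N)
    sig[40] = 50.0
    noise_part = np.concatenate([baseline, np.zeros(N - 10)])
    s1 = estimate_snr(sig + noise_part)
    s2 = estimate_snr(2 * sig + noise_part)
    assert s2 == pytest.approx(2 * s1, rel=1e-9)


def test_snr_pure_noise_is_small():
    rng = np.random.default_rng(5)
    snrs = [estimate_snr(rng.normal(0, 1, N)) for _ in range(1000)]
    assert np.median(snrs) < 5.0


def test_snr_zero_baseline_variance_is_inf():
    s = np.zeros(N)
    s[50] = 10.0
    assert estimate_snr(s) == np.inf


# ---------------------------------------------------------------------------
# alpha selection
# ---------------------------------------------------------------------------

def test_select_alpha_returns_grid_member(irf, mono_decay):
    rng = np.random.default_rng(2)
    Y = np.stack([mono_decay(3.0) + rng.normal(0, 0.01, N) for _ in range(20)])
    alpha = select_alpha(Y, irf, grid=(0.88, 0.94))
    assert alpha in (0.88, 0.94)
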