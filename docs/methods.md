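# Methods

This note records the models, estimators, and numerical choices behind the
package, what the synthetic generator does and does not emulate, and the
limitations a user should keep in mind.

## Signal model

A multispectral FLIm instrument excites autofluorescence with a ~600 ps
pulse, splits the emission into four bands (CH1 375–410, CH2 450–485,
CH3 532–565, CH4 595–660 nm), delays each band in optical fiber, and
digitizes the multiplexed train at 80 ps. We model each channel window as

    y(t) = [IRF * h](t) + ε(t),     h(t) = Σ_f A_f exp(−t / τ_f),

where *h* is the fluorescence impulse response of the fluorophore mixture at
that pixel and ε combines additive detector noise with signal-dependent
(shot-like) noise of variance σ² + κ·y. Channel windows are 175 samples
(14 ns) at fixed delays 0/14/28/42 ns; the IRF is a unit-area Gaussian of
600 ps FWHM with onset 1.6 ns into the window, leaving ten clean pre-onset
baseline samples.

Because a 3–3.5 ns decay has not fully vanished after 12 ns, each window
after the first rides on the exponential tail of its predecessor. The
demultiplexer removes this pedestal by fitting the known tail shape
(`PEDESTAL_TAU_NS`, the nominal lifetime of the preceding channel) to the
pre-onset baseline samples only — the fit never touches the signal region,
so it cannot absorb fluorescence. Without this step the recovered lifetimes
of channels 2–4 are biased low by up to 0.4 ns.

## Laguerre deconvolution

The impulse response is expanded on L = 12 discrete Laguerre functions of
scale α. The recursion generates functions orthonormal on the half-infinite
index set; we re-orthonormalize by QR over the finite record so the basis is
orthonormal to machine precision for any α. The coefficients minimize
‖y − C B a‖² with C the causal IRF convolution matrix, subject to
(B a) ≥ 0 at the sample points. The unconstrained projection is tried first;
when the response dips negative, the inequality-constrained problem is
reduced (LSI → LDP → NNLS, Lawson–Hanson) so one NNLS call solves it. At this
order and record length the fit residual is only weakly α-dependent; the
per-channel default α = 0.88 was fixed by a coarse grid search over
{0.88…0.98} minimizing mean residual on a rendered calibration batch, and
both L and α are configurable.

### Average lifetime and window truncation

The average lifetime is the first moment of the normalized response. Two
systematic errors afflict the naive discrete moment on a finite window: the
half-sample discretization offset (≈ dt/2) and window truncation, which for
τ = 6 ns on a 14 ns window biases the moment by −25%. The estimator
therefore:

1. evaluates the fitted response only where it is observable — trailing
   samples see less than half the IRF's cumulative weight and are excluded
   (their coefficients are weakly determined and can ring);
2. cuts the moment window where the response meets a floor
   max(2% of peak, 2× the propagated per-sample noise sd), so noise-dominated
   tail samples never enter the moment;
3. inverts the exact discrete geometric truncated-mean relation
   m(q, N) = Σ n qⁿ / Σ qⁿ for the decay ratio q, reporting −dt/ln q.

For a sampled mono-exponential this inversion is exact at any cut length;
noiseless recovery errors are < 0.1% for τ = 0.5–6 ns, and Monte-Carlo bias
at SNR 25 is ≤ 3% with median error decreasing monotonically in SNR. For
mixtures the mono-exponential inversion is an approximation; with component
lifetimes spanning ≤ 1 ns around 3 ns (the regime of cartilage
autofluorescence) the model bias is ≤ 0.07 ns. Strongly bimodal decays (a
large 0.8 ns component next to 3.4 ns) would be underestimated by ~0.2 ns —
a known limitation. The plain discrete moment remains available as
`average_lifetime` for use on complete responses.

The zero-lifetime limit (fitting the IRF itself) requires a basis matched to
fast decays; with α ≈ 0.5 and a higher order the estimator returns ~0 ns,
while the slow default basis cannot represent a delta sharply.

SNR is defined on the linear scale as peak amplitude over the standard
deviation of the pre-onset baseline; the channel-3 gate threshold of 25 is
applied to all eight parameter maps jointly so their valid supports are
identical. A dB convention would simply rescale the threshold; the choice is
isolated in `estimate_snr` and the config.

## Synthetic construct phantom

The generator emulates the study conditions, not a particular instrument
record. A 5 mm disk at 100 µm pitch mixes three effective fluorophores —
collagen (long-lived, dominating CH1–2), FAD (2.7 ns, dominating CH3), and a
small NADH-like 0.8 ns component — with the collagen weight rising
quadratically from center to rim. The per-channel effective lifetimes and
the two mixing endpoints are solved in closed form so the phantom's
channel-1/2 mean lifetimes equal measured construct values (rim 3.1171 /
3.3606 ns, center 2.8861 / 3.1878 ns) while channels 3–4 stay nearly flat
(~2.71 / 2.90 ns). The NADH yield share is kept below ~6% per channel: its
short lifetime otherwise pushes decays into the strongly bimodal regime
where the lifetime estimator's mixture bias would exceed the mapping error
budget.

Spatial heterogeneity is one shared Gaussian random field (300 µm
correlation length) scaled per channel (1, 1, 0.5, 0.5) — matrix remodeling
drives the collagen channels, cellular channels vary half as much — and
added to the true lifetime maps; decays are rendered with all component
lifetimes rescaled per pixel so the mixture mean equals the perturbed truth.
Presets: week 2 uses heterogeneity sd 0.20 ns, week 4 in vitro 0.10 ns (the
2× ratio is the study contrast), both with a 0.5 mm central void; week 4
in vivo shrinks the construct to 4 mm, drops the void, and adds a subsurface
cyst. Channel gains (1, 0.85, 0.45, 0.8) make channel 3 the weakest, and the
overall amplitude (1100 digitizer units against additive noise sd 1, shot
scale 0.05) was calibrated once so the median channel-3 SNR of foreground
pixels sits near 45–65 — comfortably above the gate, with ≥ 95% survival —
and then frozen.

What the generator does not emulate: laser power drift, detector
afterpulsing, fiber dispersion, real IRF asymmetry, sample tilt/defocus for
FLIm, motion, and any biochemical change beyond the collagen/cell gradient.
Passing tests therefore demonstrate the correctness and calibration of the
analysis chain under its stated noise model, not instrument-level accuracy
on real tissue.

## Homogeneity index

The construct centroid is the unweighted mean of foreground pixel
coordinates. The ring ROI takes the smallest radius containing at least half
the foreground pixels and keeps everything at or beyond it (boundary shell
included); on a digital disk of radius R the inner radius lands at R/√2 and
the area fraction within 0.01 of one half. A central void is excluded
automatically because it is never foreground. The index is the fraction of
valid ROI pixels within (1 ± 0.05)×(ROI mean lifetime), boundaries
inclusive; missing pixels are excluded and counted. The 5% tolerance is the
method's definition; the implementation exposes it because a ±10% variant
appears in longitudinal summaries of the same analysis, and the two differ
only by this constant. Channel 1 is the default input — the correlation
analysis shows it carries the collagen signal — and the week-2 → week-4
comparison uses a paired two-sided t-test because matched samples are imaged
at both time points (Welch's test is available for unpaired designs). The
index is scale-invariant (the band scales with the mean) and decreases
monotonically with added noise; it deliberately remains sensitive to
measurement noise, which is why the SNR gate precedes it.

## Multivariate correlation

Per image, Pearson r over the jointly valid pixels for all 28 map pairs;
maps with zero variance yield missing rows rather than zeros. Aggregation is
an unweighted element-wise mean and population sd across images (a single
image gives sd 0); a valid-pixel-weighted variant exists behind a flag.
Significance per pair is a two-sided one-sample t-test of Fisher-z
transformed per-image coefficients against zero, requiring ≥ 3 images, with
no multiple-testing correction — matching the stated analysis procedure.
Degenerate zero-variance samples map to p = 0 (nonzero mean) or p = 1.

## OCT simulation and reconstruction

The swept source is Gaussian with center 1310 nm and 110 nm FWHM, sampled
uniformly in wavenumber over twice the FWHM (1024 samples) so the envelope
is well contained; axial pitch is π/(N·δk) ≈ 3.87 µm of optical path with a
~2 mm unambiguous range. The phantom's scattering slab starts 155 µm deep,
is 1 mm thick, attenuates at 0.002 µm⁻¹, and carries multiplicative
log-normal speckle amplitude (sd 0.35) with a uniformly random phase per
scatterer — sub-wavelength position jitter — which develops true speckle and
decorrelates the lateral mean A-line. Voids are low-scattering cylinders,
cysts low-scattering ellipsoids (5% of surrounding amplitude); the specular
surface line is added after cavity attenuation because the construct's top
surface is intact above interior defects.

Reconstruction subtracts the mean A-line (DC/background), applies a Hann
window, and takes the FFT magnitude with −60 dB log compression.
`axial_psf_fwhm` measures on the unapodized reconstruction because the
coherence-length formula 2 ln2/π · λ₀²/Δλ describes the source-limited
amplitude PSF; the Hann window broadens it ~2.5×. The measured width runs
~12% above theory (residual envelope truncation), and halves when the
bandwidth doubles. Surface detection is per A-line: a column joins the
sample footprint when its peak reaches −15 dB of the volume maximum, and the
surface is the first sample within 10 dB of the column peak.

Hypoechoic detection smooths the log volume (σ = 1.5 voxels), erodes the
lateral footprint by 2σ (boundary columns blend with the dark background),
restricts to the slab interior with a 6-voxel axial margin, and thresholds
at 6 dB below the per-depth median of the tissue — a depth-referenced
baseline that is robust to attenuation, where a global median falsely flags
the deep slab. Connected components of ≥ 50 voxels are reported with mean
contrast against a 2-voxel dilated shell, sorted by volume. At these
defaults, 20/20 cyst phantoms yield exactly one detection and 20/20
homogeneous slabs yield none. Depth axes report optical path; divide by the
refractive index (default 1.38) for geometric depth.

## Reproducibility and problem sizes

Every random draw derives from explicit seeds (phantom field, speckle, FLIm
noise, OCT noise are independent substreams of the spec seed); identical
configurations reproduce outputs bit-exactly. The default problem sizes —
50×50 pixels per FLIm scan, 175 samples per channel window, 1024 wavenumber
samples with 40×40 lateral A-lines per OCT volume, five samples per cohort —
are the package's standard study conditions; a full two-time-point
experiment runs in seconds on one core, and all sizes scale through the
spec/config objects.

## Known limitations

- The truncated-mean lifetime inversion assumes a near-mono-exponential
  tail; strongly bimodal mixtures are biased low (see above).
- The homogeneity index has no noise correction beyond the SNR gate; a
  noise-aware variant would deconvolve the estimator variance from the band
  count.
- OCT rendering treats each A-line independently (no lateral beam profile,
  no transverse PSF), so lateral resolution is the scan pitch.
- The hypoechoic detector assumes one connected tissue slab; stacked or
  folded constructs would need a per-column tissue mask.
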