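# flimoct

Nondestructive optical monitoring of tissue-engineered cartilage, as a tested,
fully synthetic analysis pipeline.

Self-assembled cartilage constructs mature by depositing extracellular matrix
(collagen, GAGs), but the standard quality-control assays — histology,
biochemistry, mechanics — destroy the sample. Two label-free optical
modalities can track maturation *in situ*: multispectral **fluorescence
lifetime imaging (FLIm)**, whose autofluorescence decay rates report
fluorophore identity (collagen vs. cellular NADH/FAD) independent of
concentration, and **swept-source optical coherence tomography (OCT)**, whose
depth-resolved backscatter reveals structural defects (voids, cysts). This
package implements the complete analysis chain for such a bimodal instrument
and a synthetic construct-phantom generator that stands in for the instrument,
so every stage can be validated against known ground truth.

Intended users: biomedical-optics and tissue-engineering researchers who want
the analysis (decay deconvolution, parameter maps, homogeneity statistics,
OCT reconstruction and defect detection) as an importable, testable library.

## What it computes

**FLIm decay analysis.** Each pixel's measured waveform is the fluorescence
impulse response *h(t)* convolved with the instrument response (IRF). *h* is
expanded on discrete orthonormal Laguerre functions *b_j*,

    h(t) = Σ_j a_j b_j(t; α),    y = IRF * h + noise,

and the coefficients are found by least squares with *h* constrained
nonnegative (an active-set solve via the least-distance-programming reduction
to NNLS). The **average lifetime** is the expectation of the normalized
response, τ = Σ t h(t) / Σ h(t); because the acquisition window spans only a
few lifetimes, the pipeline evaluates the moment up to the fitted response's
noise-floor crossing and inverts the exact discrete geometric truncated-mean
relation, removing the truncation bias (< 0.1% error on noiseless
mono-exponentials, ≤ 5% bias at SNR 25 for τ = 2–6 ns). **Intensity ratios**
are each channel's integrated intensity over the four-channel sum.

**Maps and gating.** Per-pixel results become eight co-registered maps (LT1–4,
INTR1–4) plus intensity/SNR maps; pixels below SNR 25 in channel 3 (the
weakest channel) are removed from *all* maps so their supports stay identical.

**Multivariate correlation.** Pixel-wise Pearson correlation among the eight
maps per image, averaged across images, with a Fisher-z one-sample t-test per
pair.

**Biochemical homogeneity index (HI).** A ring ROI centered on the construct
centroid whose area is half the construct (the inner half-area disk — and any
central defect — is excluded). With μ the ROI mean channel-1 lifetime,

    HI = #{ pixels with lifetime in [(1−0.05) μ, (1+0.05) μ] } / #ROI pixels,

so HI = 1 for a perfectly uniform ROI. Longitudinal change is tested with a
paired t-test across matched samples.

**OCT.** Fringes sampled uniformly in wavenumber from a 1310 nm / 110 nm-FWHM
swept source are reconstructed by background subtraction, apodization, and
FFT; volumes yield B-scans, en-face projections, and a per-A-line surface map.
Hypoechoic regions (voids, cysts) are connected components more than 6 dB
below the per-depth tissue median, size-filtered.

**Synthetic constructs.** `preset_spec("week2" | "week4_invitro" |
"week4_invivo")` emulate the study conditions: a 5 mm construct at 100 µm
pitch with a collagen-rich rim (channel-1 lifetime ≈ 3.12 ns at the edge vs
≈ 2.89 ns at the center), a central void in vitro, twice the lifetime
heterogeneity at week 2, and a shrunken construct with a subsurface cyst
in vivo.

## Worked example

```python
import flimoct as F

cfg = F.ExperimentConfig(timepoints=("week2", "week4_invitro"),
                         n_samples=5, seeds=(1, 2, 3, 4, 5))
result = F.run_experiment(cfg)
print(result.hi_table)
print(result.hi_comparisons[("week2", "week4_invitro")])
```

prints (seeds 1–5):

```
    timepoint  sample  seed    hi  mean_lifetime_ns  n_valid
        week2       0     1 0.613             3.019      956
        ...
week4_invitro       0     1 0.838             3.021      956
        ...
paired t-test week2 -> week4: t = 13.51, p = 1.74e-04, direction = increase
```

Each `hi` is the fraction of ring-ROI pixels within ±5% of the ROI mean
channel-1 lifetime: about 0.5 for the heterogeneous immature constructs,
rising to about 0.8 after maturation, with the paired t-test confirming a
significant increase — the quantitative signature of ECM deposition evening
out across the construct. The scripts in `examples/` walk through each
capability (map recovery, homogeneity tracking, correlograms, OCT defect
detection) and print a short interpretation with their numbers.

## File formats

Raw scans and OCT volumes are stored in HDF5 (dense float64 arrays:
`/scan/waveforms` of shape `(rows, cols, samples)`, `/irf/samples`, and a
`/meta` group with the time base, channel delays, and pixel pitch). Parameter
maps round-trip through HDF5 at full precision; `export_map_tiff` additionally
writes a multi-page 32-bit TIFF with a JSON sidecar (band labels, units) for
viewers. Homogeneity, correlation, and hypoechoic-region tables are CSV.
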