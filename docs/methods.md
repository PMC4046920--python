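# Methods

## The measurement problem

In direct-repeat EGFP recombination reporter mice, a homologous
recombination (HR) event restores a functional EGFP cassette. Two readouts
quantify HR load: (i) fluorescent foci in freshly excised, compressed
(~0.5 mm) whole organs imaged at ×1 magnification — each focus marking one
(possibly clonally expanded) event — and (ii) the frequency of fluorescent
cells among disaggregated tissue measured by flow cytometry, down to the
order of 10⁻⁶. Both signals sit barely above structured background:
tissue autofluorescence varies smoothly across an organ, detection adds
shot and read noise, and in flow the autofluorescent population is within
a decade of dim EGFP⁺ cells. The package's job is to make both
measurements reproducible and conservative: for frequency estimates near
the spontaneous rate a false positive is worse than a false negative.

## Foci-counting pipeline

**Preprocessing.** 3×3 median filter (radius 1, edge replication). The
kernel is minimal on purpose: small transit-cell foci have σ ≈ 1–3 px at
10 µm/px and heavier smoothing erodes them below the detection threshold.

**Candidate detection.** Extended maxima transform: regional maxima
(8-connected, plateaus included) of the h-maxima transform, computed as
morphological reconstruction by dilation of `I − h` under `I`. A dome
survives iff its height above its highest saddle exceeds `h`. Degenerate
flat regions (the whole background is one giant "maximum" under this
definition) are removed by an area cap of 1% of the tissue area rather
than an intensity floor. Default `h` = 3 × the robust noise SD
(1.4826·MAD) of the median-filtered tissue pixels, so stringency
transfers across exposure settings; with the default noise model this
puts `h` ≈ 65 counts, far above the high-frequency noise (so focus-free
tissue yields almost no candidates) and below the dimmest default focus
after filtering.

**Per-focus model.** Isotropic 2-D Gaussian `b + A·exp(−r²/2σ²)` fit by
bounded least squares over a window of radius max(5 px, 3×initial σ,
window implied by the candidate's own region area), capped at 30 px and
clipped (and flagged) at borders. Initialization from moments; bounds keep
the solver off the degenerate broad-Gaussian mode (σ → ∞, b → −∞) that
can otherwise shadow a genuine narrow peak; `converged` requires solver
success, σ < the window size, and A > 0. Isotropy is deliberate: focus
irregularity is carried by shape features downstream, not by anisotropic
fitting, and large plateau-like clonal foci are fit loosely (high
normalized residual), which itself is an informative feature.

**Adaptive threshold and segmentation.** Threshold `b + f·A` with
`f = 0.5` (half maximum). Half maximum is the standard scale-free choice
and makes two closed forms available for testing: the contour radius
`σ√(2 ln 2)` and the enclosed fraction of the full Gaussian integral
`2πAσ²`, exactly `1 − f = 0.5`. The region is the 8-connected
super-threshold component containing the seed within the fit window; an
empty region rejects the candidate.

**Features.** area, equivalent diameter, eccentricity, solidity,
circularity `4πA/P²` (perimeter by skimage's weighted even/odd step
convention; single-pixel regions have circularity 1 by convention), peak /
mean / integrated intensity (integrated is background-subtracted by the
fitted `b`), local background, SNR `(peak − b)/noise SD`, fitted σ, and
normalized fit residual `rmse/A`. All background-subtracted features are
invariant to adding a constant to the frame.

**Classification.** Two sequential binary RBF-SVMs (noise vs. focus, then
small vs. large), rather than one 3-class machine, mirroring the two
decisions the counting procedure actually makes. Features standardized;
(C, γ) selected on a 4×4 grid (C ∈ {0.1, 1, 10, 100},
γ ∈ {0.01, 0.1, 1, 10}) by stratified 5-fold cross-validation with a fixed
fold seed. The default model is trained entirely on simulator-labeled
data: focus examples matched to planted ground truth on three
high-density images, noise examples harvested from focus-free images
detected at a *lowered* threshold (1.3× noise SD) so spurious domes near
the decision boundary are represented. Conservative mode shifts the
stage-1 decision threshold to the 99.9th percentile of the noise-class
decision values (floored at 0); on focus-free default simulations it
accepts nothing. Models serialize to versioned JSON (support vectors,
dual coefficients, intercept, standardization) and predict through an
explicit kernel sum, so saved models are portable and reload
bit-reproducibly.

**Quantification.** Counts are summed over all tiles of an organ before
dividing by the summed tissue area — a whole-organ frequency, invariant
under repartitioning, not a mean of per-tile frequencies. Cohorts are
compared with the two-tailed Mann–Whitney U test: exact when
n₁+n₂ ≤ 12 and tie-free, otherwise the normal approximation with midrank
tie correction and continuity correction (exact enumeration deliberately
refuses tied data). Frequencies are overdispersed across animals, so no
parametric alternative is offered.

## Flow gating

The discriminant `d = log₁₀(green) − k·log₁₀(orange)` is calibrated on an
autofluorescent-only (wild-type) reference: `k` from the principal axis of
the log-channel covariance, the threshold from the (1 − FPR) quantile of
`d` — empirical if the reference holds ≥ 10/FPR events, else Gaussian tail
extrapolation (exact for the generator, whose log channels are bivariate
normal; adequate for real data to the extent the discriminant tail is
near-normal — a stated assumption, checked against held-out reference
data in the tests). Default target FPR 10⁻⁶ matches the assay's detection
floor. The live gate excludes the low-scatter debris cluster (Otsu split
on log FSC, with a guard against bisecting a unimodal population) and
applies a [0.05, 0.995] quantile box per scatter axis. Intervals are
exact Clopper–Pearson.

## Synthetic data: what it emulates, and what it does not

Images: homogeneous tissue (default 500 counts) on a dark slide, a smooth
Gaussian random field for sample autofluorescence (SD 20 counts,
correlation length 20 px, renormalized to the exact in-tissue SD),
Poisson shot noise (gain 0.5 counts/photon-equivalent) and Gaussian read
noise (SD 10), quantized to 16 bits. Small foci: isotropic Gaussians,
amplitude 150–400, σ 1–3 px, random elliptical stretch up to 1.5×. Large
foci: near-round discs (axis ratio ≥ 0.9), diameter 5–15 px (50–150 µm —
crypt/acinar-clone scale at the default 10 µm/px), edges blurred at 1 px,
amplitude 300–800. Per-class counts are Poisson(density × area); preset
densities anchor to the reported organ-level medians: spontaneous
pancreas 140/cm² (100 small + 40 large), induced pancreas 400/cm²
(300 small + 100 large). Flow: log-normal scatter with a 10% low-scatter
debris cluster, bivariate-normal log fluorescence (SD 0.3 dex, green–orange
correlation 0.9), EGFP⁺ events shifted 30× on green — cleanly separable,
as in the two-channel reference plots; positives are planted among
non-debris events. All defaults are overridable and every draw is
seed-deterministic.

Not emulated: optical PSF/defocus through compressed tissue, vignetting
and flat-field structure, tile seams, multichannel counterstains, spectral
spillover, focus clustering beyond Poisson spatial randomness, and
animal-level biological variability of image content (the count-level
cohort simulator adds lognormal between-animal dispersion, CV 0.6, chosen
as typical of the strong overdispersion of per-animal foci frequencies).
Passing round trips therefore demonstrate the algorithmic chain is
correct and calibrated under the stated noise model, not that the
classifier transfers to real tissue — on real data the SVM is meant to be
retrained from expert annotations via the same API.

## Numerical and design choices

- 8-connectivity everywhere (maxima, components, segmentation).
- Candidate seeds are component argmax pixels, ties broken by smallest
  (row, col); all coordinates 0-based (row, col); areas in cm² via
  (pixel_size_µm · 10⁻⁴)², centralized in one helper.
- Tissue-mask derivation (median smoothing radius 15 px → Otsu → closing
  radius 5 px → hole fill → largest component) runs on a 4× downsampled
  image: the outline is low-frequency and full-resolution heavy medians
  cost seconds per frame for no accuracy gain. A user mask always
  overrides; uniform images raise instead of guessing.
- Mosaics abut tiles with no overlap or registration (automated-stage
  acquisition with known grid placement).
- Round-trip problem sizes: ten 1 cm² organs per density for the counting
  round trips (median reported), 5×10⁶-event samples and a 10⁷-event
  held-out wild-type simulation for the flow contracts; the classifier
  trains once on five 512² frames (~600 labeled candidates).

## Known limitations

- Merged foci are separated only insofar as the extended maxima split
  them; at 400/cm² this costs ~3–5% of counts (no mixture fitting).
- The Gaussian model under-describes large plateau foci by design; their
  acceptance rests on the classifier, not on fit quality.
- Exact Mann–Whitney is limited to n₁+n₂ ≤ 12 tie-free; integer count
  data with ties silently use the corrected normal approximation.
- Gaussian tail extrapolation below ~10⁻⁴ FPR is unverifiable from small
  references by construction; the package records which calibration mode
  produced a gate.
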