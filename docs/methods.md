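# Methods

This note documents the models, parameter choices and numerical details
behind `qus`, in the order data flows through the package.

## Synthetic RF model

Each tissue scan line is a filtered compound-Poisson process:

1. **Scatterer train.** Point scatterers are deposited at uniformly random
   depths with density ρ (default 500 mm⁻³) over an effective beam
   cross-section of line pitch × elevation (0.3 mm × 0.3 mm).  Amplitudes
   are gamma distributed with mean 1 and a configurable coefficient of
   variation (default 0.3) — positive, with controllable variance.  At the
   default sampling (35 MHz, c = 1.54 mm/µs) this yields ≈1 scatterer per
   sample and ≈10 per axial resolution cell, safely incoherent; the
   generator warns when a configuration drops below one per cell.
2. **Transfer function.** The train is shaped in the frequency domain by
   the pulse spectrum times a tissue transfer function whose dB magnitude
   is linear across the band: `true_midband + true_slope·(f − f_ref)`.
3. **Noise and quantization.** White Gaussian noise is added at a fixed
   SNR (default 40 dB relative to signal RMS), then the frame is quantized
   to int16 with a fixed gain (16384 counts per unit amplitude — the
   quartz-flat echo peaks at half scale).  The gain is never adaptive, so
   multiplying tissue amplitudes by *a* moves the measured midband by
   exactly 20·log₁₀(a) and leaves the slope alone.

**Exact recoverability.** The Hamming-windowed periodogram of a stationary
line is, in expectation, the line's power spectrum *convolved* with the
window's power kernel, while the deterministic calibration echo suffers no
such smoothing.  A transfer function designed naively from the target line
therefore reads back flattened (by more than 1 dB/MHz at the control
group's slope).  The generator instead designs the filter against the
exact expectation model,

    E[tissue periodogram](f) = (σ²/N) · (|G|² ⊛ |W|²)(f),

and sharpens it with a few multiplicative (Richardson–Lucy-style)
deconvolution iterations inside the usable band, so the expected measured
calibrated spectrum equals the target line at every in-band frequency.
The level is normalized at the nominal scatterer statistics, which keeps
physics visible: doubling the scatterer density raises the measured
midband by 10·log₁₀(2) ≈ 3.0 dB rather than being renormalized away.

Diffraction, beamforming, attenuation and elevational focusing are
deliberately out of the generative model: the study chain applies no
attenuation compensation, and a 1-D convolution model is the simplest one
for which the spectral ground truth is exact and recoverable.

**Dynamic-range limit.** What the chain can recover is bounded by the
in-band dynamic range |SS|·bandwidth against the additive-noise and 16-bit
quantization floors.  At the default band (4.2–7.8 MHz) and SNR, both
study arms (−10.66 and −5.49 dB/MHz) are recovered within 0.5 dB/MHz and
1 dB averaged over 100 seeds; slopes steeper than ≈ −12 dB/MHz
progressively saturate at the band edges and read back biased toward
zero — with 16-bit amplitude semantics this is measurement physics, not an
implementation artifact, and narrower bands or higher SNR extend the
range.  One visible consequence: when per-sample slopes are drawn from the
control group's normal (SD 2.96), the steep tail picks up a convex bias,
so full-RF cohort group means sit ≈0.5–0.9 dB/MHz above the generative
means while feature-level statistics are exact.

## Spectral analysis

* Depth maps to sample index as floor(2·depth/c·fs); gates are 0-based,
  half-open.  The nominal gate is 175 samples (3.85 mm), chosen so that
  6.0 MHz lies exactly on the gate's frequency grid — otherwise the band
  center lands up to half a bin off the reference frequency and slope ×
  offset leaks into the midband.
* The symmetric L-point Hamming window is applied once per segment; line
  spectra are averaged in linear power before dB conversion (the unbiased
  estimator), power dB = 10·log₁₀(mean |DFT|²), so amplitude doubling is
  +6.02 dB.
* The analysis band is the contiguous interval around the reference peak
  where the reference stays within `band_threshold_db` of its maximum.
  The default is 10 dB (≈4.2–7.8 MHz for the default pulse): a −15 dB band
  would span ≈49 dB of calibrated dynamic at the control group's slope and
  run into the 16-bit floor at the upper edge.  The threshold is
  configurable.
* SS/MBF come from ordinary least squares of calibrated magnitude on
  frequency; MBF is the fitted value at the band center; per-ROI
  parameters (three ROIs, one shared band derived from the reference) are
  averaged arithmetically; spectra are never pooled across ROIs.
* Degenerate inputs: all-zero segments floor at −300 dB with a warning;
  bands narrower than three bins, monotone references without an interior
  peak, and ROIs outside the frame are rejected with explicit errors.

## Histology

* HSI conversion uses the standard arccos hue formulation scaled to 0–255,
  I = (R+G+B)/3, S = 255·(1 − min/mean) with S = 0 for achromatic pixels.
  (The commercial package the protocol came from does not publish its
  exact formula; the printed 0–255 / 0–120 thresholds carry over.)
* Components are 8-connected; the filters apply the published thresholds
  verbatim: area ≥ 50 px and bounding-box width/height in [0.5, 2].
  `area_min` is in pixels, as printed, with no physical calibration — the
  generator's default of 1 µm/px makes a 7 µm nucleus ≈154 px.
* **Split objects** is a watershed on the Euclidean distance transform,
  computed per component.  Seeds are the connected *cores* of the distance
  map — pixels above `split_core_fraction` (default 0.6) of the
  component's distance maximum.  For a single convex nucleus the distance
  map is concave, so its superlevel set is one connected core and the
  component passes through unchanged; the operation is therefore
  idempotent and cannot oversplit convex objects at any threshold.  Two
  touching convex nuclei separate whenever the saddle between them falls
  below the threshold (true for overlaps up to ≈20% of radius); very
  unequal touching nuclei (radius ratio < 0.6) can evade a second core and
  stay merged — the residual ≲1% undercount on dense fields.
* The synthetic H&E generator paints dark blue-purple ellipses
  (intensity ≤ 120 after HSI conversion, aspect within the gates by
  construction) on a pink, smoothly textured eosin background
  (intensity > 170).  A stated fraction of nuclei is placed as touching
  pairs, oriented diagonally so the merged bounding box also respects the
  aspect gates, overlapping by 10% of radius and drawn near-circular so
  the constructed saddle geometry is what split-objects actually sees.
  All other nuclei keep a guaranteed clearance.  Placement is rejection
  sampling; an infeasible density raises an error reporting the achievable
  maximum.  What the generator does **not** emulate: stain variability,
  chromatin texture, out-of-focus blur, anisotropic clustering, cut nuclei
  at section boundaries — so exact-count results here bound segmentation
  logic, not real-slide performance.

## Statistics

* t-tests are pooled-variance Student's by default (Welch available);
  degenerate zero-variance input returns (0, 1) for equal means and is
  rejected otherwise.  Normality is checked by a one-sample KS test
  against a normal with estimated parameters (the common software default;
  conservative), variance homogeneity by Levene with mean centering.
* The LOOCV classifier is a two-class linear discriminant with pooled
  covariance and equal priors, written in closed form (≈15 lines of linear
  algebra) and cross-checked in the test suite against scikit-learn's
  `LinearDiscriminantAnalysis` (100% prediction agreement).  Treated is
  the positive class; ties break toward control; a singular pooled
  covariance falls back to its diagonal with a warning.
* The cohort simulator draws SS and MBF independently within each group
  (the within-group feature correlation is not published; zero is the
  default and configurable).  Under that parameterization the Monte-Carlo
  mean LOOCV metrics are ≈84% accuracy, ≈87% sensitivity, ≈82%
  specificity — accuracy and sensitivity land close to the published
  87.5%/83.3%, while specificity sits below the published 91.7% because a
  symmetric pooled-covariance boundary favors the tighter (treated) group;
  the published split of errors is one small-sample realization of the
  same model.
* The B-mode proxy is the analytic-signal envelope, log-compressed with a
  fixed (never per-image) dB-to-gray mapping, so brightness comparisons
  across frames are meaningful.  Gray-intensity values are on the proxy's
  own scale; only directions, not absolute units, are comparable to
  scanner screenshots.

## Problem sizes

Defaults re-enact the study: 12 + 12 samples, 120-line frames over 30 mm
depth, three 40-line ROIs, ten 512 px fields per sample.  Monte-Carlo
checks in the test suite use 10–100 seeds per contract and 1500–5000
replicates for classifier and null-calibration statistics; the acceptance
script uses 4000 LOOCV replicates.  A full default experiment writes ≈35 MB
of artifacts and runs in well under a minute on one core.

## Known limitations

* The generative RF model has no depth-dependent effects; ROI placement
  away from the focus is exercised by the API but carries no physical
  meaning in the simulation.
* Recovery contracts hold in the incoherent regime only (≥1 scatterer per
  resolution cell; the generator warns otherwise) and within the
  dynamic-range bound above.
* Absolute p-values, correlations and gray-scale means from the animal
  study are data-dependent quantities that the simulator parameterizes
  rather than reproduces; only their signs/directions are contracted.
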