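# Methods

## Signal model

All synthesis and simulation rests on the steady-state spin-echo amplitude

    A(TE, TR) = ρ (1 − 2 e^{−(TR − TE/2)/T1} + e^{−TR/T1}) e^{−TE/T2}

with TE, TR, T1, T2 in milliseconds and ρ in arbitrary units (receiver gain,
B0 and temperature enter only as a common scale absorbed into ρ; no absolute
calibration is attempted). The simplified form
`A ≈ ρ (1 − e^{−TR/T1}) e^{−TE/T2}` is exposed for analysis; it agrees with
the full model to first order in TE/TR.

Magnitude images are non-negative, so the forward evaluation clamps at zero
by default (`clamp_negative=False` returns the signed value). In fact the
clamp is a safety net only: with the enforced invariant TE < TR, the
saturation factor `1 − e^{−(TR−TE/2)/T1}(2 − e^{−TE/(2T1)})` is strictly
positive — writing x = TE/(2T1), negativity would require
(TR − TE/2)/T1 < ln(2 − e^{−x}), but ln(2 − e^{−x}) < x for every x > 0
while (TR − TE/2)/T1 > x whenever TR > TE. A property test asserts this on
a broad random grid.

Assumptions inherited from the model: ideal 90°–180° pulses, single-
compartment mono-exponential relaxation, no B1/slice-profile effects, no
flow or diffusion weighting.

## Relaxometry estimators

**T1 (variable-TR series, TE fixed, ≥ 4 distinct TRs).** Along TR the full
model is exactly `A = C1 + C2 e^{−TR/T1}`. (An equivalent parameterization
writes the exponential as b^{C3} with b = e^{−TR}; that form underflows for
TR in milliseconds, so the fit uses the stable exponential form directly.)
Trust-region nonlinear least squares with analytic Jacobian; initialization
C1 = max signal, C2 = min − max, T1 seeded by log-linearizing C1 − A with a
fallback to the median TR; T1 bounded to [1, 20000] ms; at most 200 model
evaluations. Constant series raise a degenerate-fit error; non-convergence
raises a fit-failure error.

**T2 (variable-TE series, TR fixed, ≥ 3 points with positive signal).**
Ordinary least squares of ln A on TE after excluding non-positive signals;
T2 = −1/slope, requiring a negative slope. Two optional refinements, both
enabled by default at the map level and off by default for the scalar
operation (which then matches the classical log-linear recipe exactly):

- *Saturation correction.* The full model's saturation factor depends on TE
  through TE/2, so the plain log-linear fit is biased whenever TR is not
  much longer than T1 (up to ~8% at T1 = 2000 ms, TR = 2000 ms over the
  standard TE grid). When the pixel's T1 is already known from the TR
  series, `ln S(TE; T1, TR)` is subtracted before the regression, which
  makes noiseless recovery exact for every tissue.
- *Signal weighting.* Log-transforming an exponential turns homoscedastic
  signal noise into noise of variance σ²/A²; weighting the log-domain
  residuals by A² (the delta-method weights) stops noise-dominated long-TE
  points from dominating the line. Without it, per-pixel T2 error at 1%
  noise is several-fold larger for short-T2 tissues.

**ρ (variable-TR series, T1 and T2 fixed at their estimates).** With design
factors `x_i = (1 − 2 e^{−(TR_i − TE/2)/T1} + e^{−TR_i/T1}) e^{−TE/T2}`, the
model `A_i = ρ x_i` has the unique least-squares solution
ρ = Σ A_i x_i / Σ x_i² (zero intercept). A noise-driven negative estimate is
clamped to 0.

`compute_parameter_maps` runs the three fits per masked pixel; any pixel
whose fit fails is dropped from the output mask and counted in the log
rather than raising, so whole-map computation always completes. Per-pixel
residual RMS grids are returned as fit-quality maps.

## Segmentation

Intensity-only fuzzy C-means: minimize Σ_i Σ_k u_ik^m (x_i − c_k)² with
Σ_k u_ik = 1 by alternating the closed-form membership and centroid
updates. Defaults m = 2, tol = 1e−5 on the maximum centroid shift,
max_iter = 300 — standard FCM practice. Centroids initialize at the
intensity quantiles (i + ½)/k jittered by a seeded normal perturbation
(reproducible and well spread); explicit initial centroids can be supplied.
Pixels coinciding exactly with a centroid receive crisp membership. The
objective is recorded each iteration and is non-increasing (asserted in
tests). Requesting more clusters than distinct intensities is a degenerate
case and raises. Cluster → region selection is a user rule (brightest /
darkest / rank / seed pixel / index) because organ identity cannot be
inferred from intensities alone; an optional largest-4-connected-component
filter removes speckle.

## CT features and mapping surfaces

Windowed statistics use only in-mask pixels inside the centered window
(default 5 × 5), so features near the region boundary are not contaminated
by out-of-region tissue; pixels with fewer than `min_count` (default 6)
in-mask window pixels are dropped. σ is the sample (n − 1) standard
deviation — conventional for such small samples. Moments are accumulated on
mean-centered values to keep the variance subtraction well conditioned.

The three surfaces (μ, σ) → T1, T2, ρ are scattered-data interpolants over
the training pixels' feature pairs: piecewise-linear on a Delaunay
triangulation (default) or nearest-neighbor. Duplicate (μ, σ) keys are
averaged before triangulation — interpolation needs single-valued nodes,
and averaging is the natural resolution of the residual one-to-many
ambiguity. Collinear training features make triangulation impossible and
raise a degenerate-geometry error suggesting nearest mode. Queries outside
the convex hull fall back to the nearest node by default (configurable to
mark such pixels invalid instead). Node evaluation reproduces training
values to machine precision in both modes, so regenerating the training
slice's own maps is exact by construction. Models serialize to JSON
(points, values, mode, fallback, provenance).

## Similarity metrics

Regions are vectorized in deterministic row-major order. The slope is the
OLS fit of the synthetic vector (dependent) on the real vector
(independent), reported with its intercept so the opposite convention is
recoverable. PRD = 100·√(Σ(real − syn)² / Σ real²); the square root and
percent scale follow the metric's name and conventional usage. Optional
scale normalization multiplies the synthetic vector by
Σ(real·syn)/Σ syn² first, removing a global gain difference; it is off by
default so gain mismatches remain visible.

## Digital phantom

The phantom emulates a single-organ slice as a scanner presents it: each
tissue has constant intrinsic values, a mean CT number, and a within-tissue
CT texture whose sample sd over the region equals `hu_texture_sd` exactly
(a seeded Gaussian random field smoothed to a 2-pixel correlation length so
5 × 5 windows see a tissue-characteristic σ). CT acquisitions are repeated
(default 9) with independent 10 HU Gaussian noise and averaged, reducing
residual noise by √9. MR series use the full signal model plus Gaussian
noise (default) or Rician magnitude noise; the default noise level in the
bundled studies is 1% of the peak series signal (SNR ≈ 100, a realistic
post-averaging figure and within the ≤ 2% regime the end-to-end properties
are stated for).

Tissue-tissue interfaces carry partial-volume blending (`edge_blend`,
default 0.8 px): pixels within about one pixel of a contact boundary hold a
volume-weighted mix of the adjacent tissues' parameters and HU. No
finite-resolution scanner produces an infinitely sharp interface, and
without this the interface band dominates every similarity metric: windows
straddling a boundary yield intermediate (μ, σ) while training values and
truth would both be binary, making the mapped value there an essentially
random pick between the two tissues. Interior pixels and tissues not in
contact are unaffected, and blending can be disabled.

The default tissue set is a liver partition with two inserts at 1.5 T
literature-plausible values — liver parenchyma (T1 586, T2 54, ρ 720,
55 HU, texture 4), dense lesion (T1 1060, T2 79, ρ 780, 30 HU, texture 6),
cyst (T1 1400, T2 220, ρ 950, 8 HU, texture 3). HU means are spaced at
least ~4 windowed-μ standard deviations apart; local statistics that cannot
identify tissue would contradict the premise the mapping rests on, and
hypodense lesions and fluid-density cysts genuinely sit 25–45 HU below
parenchyma. Variants "A" and "B" share the tissue set with different
geometry, emulating two nearby slices of one phantom.

What the phantom does **not** emulate: CT beam hardening and reconstruction
kernels, k-space MR acquisition, B0/B1 inhomogeneity, motion, registration
error (outputs are perfectly co-registered by construction), and
within-tissue biological heterogeneity beyond the CT texture (the MR
parameters are piecewise constant). Passing the end-to-end properties
therefore shows the pipeline is correct and statistically efficient under
the model's own assumptions; it does not show robustness to registration
error or to tissues whose (μ, σ) signatures overlap.

## Problem sizes and reproducibility

The bundled studies use 128 × 128 slices (≈ 6900 fitted pixels, about 10 s
for a full study on one CPU); the pipeline demo and unit tests use 36–96
pixel grids. Every stochastic stage draws its seed deterministically from a
single top-level seed (numpy SeedSequence), so identical configuration
implies bit-identical outputs; no global RNG state is used anywhere.

## Known limitations

- The T2 estimator's defaults at map level (saturation correction +
  weighting) depart from the classical unweighted log-linear recipe; the
  scalar operation defaults reproduce the classical behavior for
  comparability.
- The mapping is organ- and protocol-specific: a model trained on one
  region does not transfer to another organ or scanner protocol.
- Out-of-hull queries are answered by nearest-node fallback, which is
  constant extrapolation; far-from-training features silently receive
  boundary values unless `fallback="invalid"` is chosen.
- Proton density is relative; comparisons across acquisitions with
  different gain require the scale-normalized PRD.
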