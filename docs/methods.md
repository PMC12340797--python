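# Methods

## Aggregate area measurement

Calcium-phosphate sheet aggregates are hyper-electron-dense, so in a
bright-field cryo-EM micrograph they are darker than their surroundings.
Each candidate aggregate is delimited by a binary region mask (drawn by
hand on real data; generated on phantoms), and only the pixels *inside*
the mask enter the statistics. Multiplying mask and image — which would
zero the background and poison the region minimum — is deliberately not
done; the mask selects, it does not multiply.

For the masked intensities the per-region threshold is

    t = (max − min) − k·σ,   k = 1.5 (configurable `std_multiplier`),

with σ the **population** standard deviation (ddof = 0): it is a
descriptive statistic of all pixels in the drawn region, not a sample
estimate of a larger population. Intensities are flipped to positive
contrast (v′ = max − v) and anchored at zero (v″ = v′ − min v′); pixels
with v″ ≥ t are aggregate. For a two-level (aggregate/background) region
with aggregate fraction f and contrast c this places t = c·(1 − 1.5·√(f(1−f)))
strictly between the two levels for every f ∈ (0,1), so noiseless
recovery is exact regardless of how generously the mask is drawn. The
measured area is invariant under any affine intensity rescaling
a·v + b (a > 0), which makes the choice of camera gain and offset
irrelevant.

Degenerate case: a constant region gives t = 0 and all v″ = 0, so under
the ≥ rule the whole region counts as foreground. Area is the count of
all foreground pixels in the mask — no connected-component filtering —
converted as area_nm² = area_px · (pixel_size_Å/10)². The default pixel
size is 3.21 Å/px, the acquisition setting the measurement was designed
for.

Whether the original analysis thresholded raw dark-on-light intensities
or an inverted image is not documented; the positive-contrast convention
used here selects the dense phase for bimodal regions (the threshold sits
in the upper part of the anchored range) and is recorded in output
metadata. Likewise population vs sample σ is an open choice; population
is the default and `ddof` is not exposed because the difference is
negligible at region sizes of 10³–10⁴ px.

## LDSAED radial profiles

The q axis is linear in pixel radius and anchored so that q at half the
image width equals the Nyquist spatial frequency (1.75 Å⁻¹ for the 670 mm
camera length). Camera length is carried as metadata only — no detector
geometry model is fitted. Default binning is one bin per pixel of radial
extent (128 bins for a 256 px frame), giving a d-resolution of ~0.11 Å at
d = 2.85 Å.

Beam centering starts from the intensity-weighted centroid of the central
quarter of the frame and refines it by maximizing the Pearson correlation
between the frame and its 180°-rotation about the candidate center
(powder-like patterns are inversion-symmetric through the beam center),
over a ±5 px grid at 0.5 px steps. On phantoms this recovers the true
center to < 0.25 px; a constant frame (no refinable structure) falls back
to the centroid.

Profiles are normalized by their mean intensity over the q band
0.094–0.113 Å⁻¹, which contains no diffraction feature of interest, so
separately exposed frames become mutually comparable. The target profile
is then divided bin-by-bin by a background profile from a nearby
aggregate-free region; structure shared by both — most importantly the
vitreous-ice halos at d ≈ 3.71 and 2.15 Å — divides out to ratio ≈ 1.
Both frames are normalized first, then divided; whether the original
scripts normalized before or after dividing is not documented, and this
order is recorded in the output. Bins unoccupied in either profile or
with background below 10⁻⁶ of the band mean are masked, never
interpolated.

Band detection smooths the ratio with a 3-bin moving average over
unmasked bins (the bands of poorly ordered material are broad; a
single-bin argmax would be noise-dominated), picks the maximum inside the
d window 2.5–3.2 Å, resolves ties to the lowest-d bin, and calls the band
present when the smoothed peak ratio exceeds 1.05. Bins below
q = 0.03 Å⁻¹ are excluded everywhere (beam-stop/saturated region).

## Statistics

**Fisher's exact test.** The two-sided p-value sums, over the
hypergeometric distribution conditioned on the observed margins, the
probabilities of all tables at most as probable as the observed one. The
reported odds ratio is the sample cross-product a·d/(b·c) (+∞ when
b·c = 0 < a·d), with the conditional MLE available as an option; the 95%
CI comes from inverting the conditional exact (noncentral hypergeometric)
test. The method behind any particular published CI is rarely stated, so
the CI method is recorded in the result rather than assumed comparable.
A table with a zero margin carries no information about association and
returns p = 1 by convention.

**Wilcoxon rank-sum.** The statistic is the rank sum of the first sample
on midranks. The exact null distribution is used for untied samples with
min(n) ≤ 10; otherwise a normal approximation with tie-corrected variance
and continuity correction — experimental group sizes (~94–107 per
condition) are squarely asymptotic. Empirical type-I error under a shared
log-normal null is 0.050 ± 0.003 at α = 0.05 (recomputed by the
acceptance script over 5000 simulated pairs).

**Benjamini–Hochberg.** The step-up FDR adjustment is applied across
exactly the family of tested pairs (all C(4,2) = 6 pairwise tests of one
four-condition experiment); adjusted p-values are returned in input order
and preserve the raw ordering.

## Phantoms

The phantom generators define the test conditions; every generator is a
pure function of (spec, seed).

*Micrographs.* Thin plates seen edge-on project as fiber-like curves, so
each aggregate is rendered as random-walk strokes of constant width —
default 1.85 nm, the true plate thickness, with an `apparent_width_nm`
option up to ~7 nm for tilted/defocused plates — inside a non-overlapping
elliptical membrane-bounded region kept clear of the image border. Walks
continue until strokes fill roughly a third of the ellipse, comparable to
a hand-drawn mask around a dense tangle. Strokes are depressed by
`aggregate_contrast` (default 40 on a background of 100) and additive
Gaussian noise (default σ = 4, i.e. 10% of contrast) is applied last; an
optional Gaussian blur stands in for defocus. No image physics (CTF,
multislice scattering, 3D projection) is simulated, and no
noise/contrast statistics for the real micrographs are published — the
defaults are chosen for testability, not fidelity. Passing tests
therefore demonstrate the correctness of the measurement rules, not
performance on real detector noise. Ground truth records the exact
pre-noise depressed pixel set per aggregate; with `rect_stroke_px` a
single axis-aligned rectangle replaces the walks for exact-area unit
tests.

*Diffraction frames.* Radially symmetric intensity
bg + Σ A·exp(−(q − 1/d)²/(2σ_q²)) about a configurable off-center beam,
with band widths specified as Gaussian σ in d-space and converted to
q-space at the band center (σ_q = σ_d/d²). Default ice halos sit at 3.71
and 2.15 Å; Poisson noise is optional. A band whose center exceeds the
Nyquist frequency is rejected. The flat background is a simplification —
real diffraction backgrounds decay with q — which the background-ratio
step removes by construction.

*Group areas.* Log-normal draws parameterized by the median (the
log-normal median is exp(μ), so the target median is hit exactly in
distribution) and the log-scale spread, default 0.6, a realistic skew for
aggregate-area data spanning roughly one decade. The published
per-condition medians (99,318 / 88,134 / 66,782 / 56,475 nm²) are used as
the default scales in examples and in the acceptance script.

## Problem sizes and numerical choices

Phantom images are 256×256 px throughout (area phantoms: 60 regions per
condition set; diffraction: single frames), which resolves every effect
the tests assert while keeping the full suite and the acceptance script
at a few minutes on one CPU. Tolerances: normalization-band mean equals 1
to 1e−9; threshold oracle agreement to 1e−12 relative; Fisher p-values to
1e−9 relative against exact-integer enumeration. Center refinement step
is 0.5 px (half the tolerance asserted on phantom recovery). All
floating-point I/O is float32 MRC; measurement runs in float64.

## Known limitations

- The micrograph phantoms use additive Gaussian noise only; dose-limited
  counting statistics, detector MTF, and CTF oscillations are not
  modeled.
- The centering search assumes the true center within ±5 px of the
  centroid; a heavily clipped or vignetted frame can defeat the centroid
  initializer.
- `read_micrograph` supports single-section MRC modes 0/1/2/6 and plain
  TIFF; stacks and compressed MRC are out of scope.
- Band detection reports the single strongest peak in the window; it does
  not decompose overlapping bands or fit profile shapes.
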