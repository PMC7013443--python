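# Methods

## Imaging model

The rig is a single RGB machine-vision camera, NIR-cut filter removed and a
515 nm long-pass filter added, mounted nadir at `H = 600 mm` over the crop
bed. Three LED bands (650, 850, 525 nm) flash simultaneously during one
exposure, so each 8-bit channel records a mixture of the three band
reflectances through the sensor's quantum efficiencies. `weedseg` models
this with a 3×3 channel-mix matrix (rows: R, G, B channels; columns: 650,
850, 525 nm) whose default is the estimated QE of the sensor at those
wavelengths, column-scaled by the per-band LED duty cycles (red 20%, NIR
50%, green 50% — the balanced-response setting; equal duty cycles let the
red response dominate). The effective response matrix is shared between the
detection pipeline's interpretation of a frame and the synthetic renderer's
forward model.

Geometry: at 600 mm the field of view is 0.54 × 0.54 m; the working frame
is 512 px square, giving the ground resolution 512/540 ≈ 0.9481 px/mm.
(The sensor itself is 2048 px; the working resolution implies 4× binning,
so frame size is an explicit geometry field, not an assumption.)
`focal_px` defaults to `px_per_mm × height_mm` by pinhole consistency and
is a calibration input otherwise. Pixel coordinates are (row, col) from the
top-left; the row axis is the direction of travel; physical coordinates are
millimetres on the ground plane with origin at the nadir point.

## RGNIR index and segmentation

The index is computed exactly as specified by its defining expression,
including the asymmetric `+rc` in the denominator; a profile flag
(`red_correction_sign`) selects the symmetric subtraction for users who
read that term as a misprint. Channel arithmetic is signed float; pixels
with zero denominator evaluate to the soil constant `L` (no measurable
reflectance ⇒ soil baseline). The index image is min–max scaled onto
[0, 255] with round-half-up — a parameter-free monotone map, so the Otsu
class structure is unchanged — and histogrammed into 256 bins.

Multi-level Otsu enumerates **all** strictly increasing threshold tuples
(1–3 thresholds; a suffix dynamic programme for 4) and maximises the
between-class variance, equivalently Σₖ Mₖ²/Wₖ with class weight Wₖ and
first moment Mₖ taken in O(1) from prefix sums over the histogram. Ties
break to the lexicographically smallest tuple. Classes are
`[0,t₁], (t₁,t₂], …, (tₙ,255]`.

The default is three classes (two thresholds). Which classes are
"vegetation" is decided adaptively: the plant/soil boundary is taken as the
threshold whose adjacent class means are furthest apart, and all classes on
its bright side form the mask. The naive alternative — always the top
class — fails whenever the third Otsu level splits the vegetation peak
rather than the soil peak, keeping only the brightest half of each plant.
An explicit `vegetation_classes` set in the profile overrides the adaptive
rule.

## Classification and targets

Connected components (8-connectivity by default) of the vegetation mask
with area ≥ 4 px (speckle floor; real one-to-three-leaf weeds are two
orders of magnitude larger at this resolution) become plant objects.
Classification is pure size exclusion: `area ≥ size_threshold_px` ⇒ crop,
else weed. `edge_rule="exclude"` drops objects touching the frame border
entirely — a partially visible crop otherwise classifies as a weed and
draws a dose.

Each weed yields one target at its centroid. Flags, in precedence order:
`out_of_band` (centroid within `band_margin_px` of the top/bottom edge),
`ignored` (within `ignore_radius_mm = 20` of a crop centroid — dosing there
risks crop damage), `careful` (within `caution_radius_mm = 40`, or the weed
touches a frame edge), else `treat`. Distances are centroid-to-centroid in
ground millimetres, parallax-corrected when heights are known. The
published zone description assigns yellow/red rings at 2 cm/4 cm with the
inner region ignored; because the colour-to-radius assignment conflicts
with the stated damage rationale (the careful ring would sit inside the
ignore ring), both readings are supported: the default nests
ignore-inside-careful (20/40 mm), and `zone_assignment="literal"`
suppresses everything within the outer radius.

## Kinematic stereo

Two consecutive frames from the moving platform form a stereo pair with
baseline `b` (default 21 mm: 90 fps at the 5 km/h design speed; the profile
checks `b ≈ speed × interval` within 5% when both are given). The
greyscale used for flow is the RGNIR index after texture enhancement —
adding the Laplacian-filtered image (3×3 kernel `{0,1,0;1,−4,1;0,1,0}`,
weight 1.0, clipped to the input range) boosts the high-spatial-frequency
content that dense flow needs on low-texture crop beds. Enhancement
increases the Laplacian-magnitude variance on images with fine detail; a
strictly band-limited image concentrated where the filter response
`|1 + λ|` < 1 can instead lose variance, which is why the corresponding
test uses sharp-featured inputs.

Dense flow is pyramidal iterative Lucas–Kanade (radius 12, 10 warps,
Gaussian weighting, prefilter) behind a translation contract: a pure shift
of 2–20 px is recovered to within 0.5 px median. An integer
phase-correlation prewarp registers the bulk ground translation first;
without it the pyramid can lose lock above ~28 px displacement. Any flow
routine meeting the contract could be substituted.

Heights: disparity `d` (median along-track flow over a window centred on
the object; the window scales with object size, ~0.7× the equivalent
radius, clipped to 5–31 px, so one local flow blip cannot dominate) gives
depth `Z = b·f/d` and height `h = H − Z`, clamped to [0, H]. Position:
`r_true = r_app (H − h)/H` about the nadir point. The per-pixel normalised
parallax error is `r_app·h/H` over the frame half-width; at an assumed
150 mm plant height and a 5% tolerance the usable along-track band without
correction is ~20% of the frame — the correction is what makes the full
frame targetable. The baseline can also be recovered from data as
`median(ground flow)·H/f` (`estimate_baseline`); the pipeline nevertheless
uses the configured baseline because the smoothed flow halo around raised
objects biases the ground median measurably.

## Synthetic scenes

The renderer is the test bed standing in for undeposited field imagery. A
scene is a soil plane plus discs (weeds, debris) and 3–5-lobe rosettes
(crops) with ground positions, heights and per-band reflectances. Raised
objects are drawn at apparent positions magnified by `H/(H − h)` about the
displaced nadir, so rendered pairs exercise the stereo model; projection is
orthographic-plus-per-object-parallax, not a full ray trace. Channel
values are `gain × 255 × E·ρ` (E the effective response, ρ the per-pixel
band reflectance stack), plus optional Gaussian sensor noise, clipped and
quantised to 8 bits.

Reflectance priors (all per-scene config): vegetation (0.05, 0.45, 0.35)
at (650, 850, 525) nm — red-edge-dark at 650, NIR-bright, fairly bright
green; soil (0.28, 0.32, 0.24), a flat slowly rising spectrum; debris
soil-like with jitter. The green value is deliberately at the bright end
of leaf optics: through this particular channel-mix matrix, the NIR band
contributes almost equally to all three channels, so index contrast is
driven by the 650/525 asymmetry and dimmer-green priors leave soil and
vegetation indistinguishable in the normalised index.

Texture: soil carries a band-limited random field anchored in ground
coordinates (it translates with the ground between frames) with
**spectrally non-uniform** amplitude (band gains 2.0/0.2/1.0 at an RMS
amplitude of 0.15) — a spectrally flat texture would cancel in the
normalised index and leave the flow estimator nothing to track. Objects
carry their own texture field in object-local coordinates so it moves with
them. Amplitudes are a deliberate compromise: strong enough for sub-pixel
flow, weak enough that the soil and vegetation index distributions stay
separated for Otsu.

`random_scene` emulates trial conditions: crops on a jittered along-track
row; weed count Poisson(density × area) — at the densest trial field's
150 weeds/m² over a 0.54 m frame this is ≈44 weeds/frame — uniform weed
positions, one-to-three-leaf radii 5–14 mm, optional debris. Optional
`min_separation_mm`/`edge_margin_mm` rejection sampling produces the
well-separated scenes that the end-to-end recovery checks require.
Everything derives from one seed; identical spec + seed renders
bit-identically.

What the renderer does **not** model: perspective distortion, shadows,
BRDF/specularity, leaf overlap between distinct plants, wind motion,
illumination non-uniformity. Passing tests therefore demonstrate the
internal consistency of the pipeline against its own forward model and its
analytic geometry, not field performance; the published field rates depend
on imagery that was never deposited and are explicitly out of scope.

## Calibration and evaluation

A `CalibrationProfile` holds every tunable (index weights, background,
segmentation, size threshold, zones, geometry, stereo, spectral model) and
round-trips bit-exactly through versioned YAML with schema validation;
unknown keys are rejected by name. `capture_background` turns a dark
(black-box) frame into per-pixel or scalar channel corrections.
`tune_profile` replaces the interactive in-field tuning screen with a
deterministic exhaustive grid search over (α, β, γ, L, size threshold); the
objective is the mean of weed recall (lenient: multiple-target weeds count
as found) and crop recall under the evaluation matcher, weights
configurable, first-best-in-grid-order tie-break.

Evaluation matches detections to truth greedily by nearest neighbour
within 20 mm — the micro-dose footprint diameter: a detection within it
still treats the weed. Truth weeds are categorised weed / crop / multiple
(≥2 matched detections, typically one per leaf) / missed; truth crops
crop / weed / missed; unmatched detections overlapping debris are debris
false positives. Reported rates: strict weed identification (multiples
excluded — the headline), lenient, multiple-target share, debris share of
all detections, crop misidentification. Zero denominators report as
undefined (`None`), never as 0.

## Problem sizes and numerical choices

Tests and the acceptance script run on a 256 px quarter-frame at the
production resolution (fov 270 mm), scenes of ~5–15 objects, 10-scene
end-to-end batches, and ~100 histograms for the exhaustive-search
cross-check; these sizes keep the whole suite around a minute while
exercising every code path at full numerical fidelity. Known limitations:
height accuracy degrades as `Z²/(b·f)` — at b = 10 mm one 0.2 px flow error
is ~10 mm of height — so small-baseline height estimates on adversarial
texture draws can exceed the nominal ±20% envelope; the pipeline reports
what it measures and leaves interpretation to the caller.
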