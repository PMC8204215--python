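# Methods

This note documents the models, conventions and parameter choices behind
`octneck`, in the order data flows through the pipeline.

## Coordinate conventions

Frames are indexed 0-based with the origin at the top-left pixel; x runs
along columns, y along rows. Angles are radians in [0, 2π),
counter-clockwise from +x with +y along increasing row index. Polar frames
put A-line 0 at θ = 0 and radial sample 0 at the catheter centre; the
Cartesian pixel pitch defaults to the radial sample spacing (isotropic
grid). Remapping uses bilinear interpolation with out-of-frame samples read
as 0 — the simplest defensible choice, declared so results are reproducible.
Bilinear remapping is exact for (bi)linear intensity fields and O(h²·|f″|)
otherwise; the test suite checks rotation equivariance at 1e-6 on an affine
field and at 5e-3 on a smooth Gaussian field.

## Neck surface and gap areas

The ostium is annotated manually: per-frame wall control points (≥ 3 outside
the ostium), an inclusive neck frame range, and one angular interval that
may wrap across θ = 0. The wall radius is the periodic linear interpolation
of the control points; across the ostium, where the wall is absent, the
radius is bridged by the same interpolation, because the device sits at the
level of the missing wall.

Gap areas are measured on the curved neck surface using the cylindrical-
patch area element: each (frame, angle) cell has area
`(frame_pitch/1000) · (radius/1000) · Δθ` mm². Arc length at the wall is
the physically correct width of a coverage cell; whether areas should
instead be measured on a flattened plane is not externally constrained, so
the curved-surface choice is recorded here as the package's convention.
Total neck area is invariant under angular grid refinement (exactly so for
grid-aligned interval edges, to O(1/n) otherwise).

Angular intervals are half-open `[t0, t1)`; a zero-width interval is empty.
One interval per ostium is supported (a saccular ostium is a single
opening); the annotation schema stores a list for forward compatibility.

## Segmentation

Per A-line, a deterministic cascade:

1. **Surface** — the smallest radius where (a) the gradient of the
   moving-average-smoothed profile is ≥ `surface_gradient_min`, (b) the raw
   intensity is ≥ `tissue_intensity_min`, and (c) the cumulative raw sum up
   to (excluding) that radius is ≤ `cumsum_lumen_max` of the A-line total.
   The raw (not smoothed) intensity is used in (b) so a sharp step is
   localised exactly at the step sample; cue (c) vetoes surfaces behind
   bright proximal haze (uncleared blood). Everything proximal is LUMEN; an
   A-line with no qualifying sample is entirely LUMEN.
2. **Strut vs tissue** — if a sample within `strut_standoff_samples` of the
   surface exceeds `device_intensity_min`, the contiguous bright run from
   that sample (capped at `strut_max_samples`) is a strut *candidate*. The
   standoff absorbs partial-volume blur at the strut's leading edge, where
   interpolation can trigger the surface one sample early at sub-threshold
   intensity. The candidate is confirmed as DEVICE only if the run distal to
   it is a *complete shadow*: mean intensity ≤ max(`shadow_ratio_max` × strut
   peak, `shadow_noise_floor`). Metallic struts fully block the beam; tissue
   never casts a complete shadow. The shadow interval itself is labelled
   LUMEN (signal void), so artifacts cannot masquerade as coverage. An empty
   distal interval (strut at the A-line end) is vacuously a shadow.
3. **Tissue** — otherwise the surface and distal samples are CLOT_TISSUE
   until the smoothed intensity attenuates below `tissue_intensity_min`.
   The attenuation search starts past the smoothing window so dark lumen
   samples proximal to the surface cannot truncate the band; tissue bands
   thinner than the smoothing half-width are therefore over-labelled by up
   to `smoothing_halfwidth + 1` samples.

Defaults (fractions of the intensity ceiling; all overridable via config or
`octneck params`): `surface_gradient_min` 0.05 per sample,
`device_intensity_min` 0.6, `tissue_intensity_min` 0.25, `shadow_ratio_max`
0.1, `shadow_noise_floor` 0.05, `cumsum_lumen_max` 0.15,
`smoothing_halfwidth` 2 samples, `strut_max_samples` 10 (~100 µm at 10 µm
spacing, the physical scale of a metallic strut), `strut_standoff_samples`
2. These were tuned on phantoms; the prototype imaging system publishes
none. The classifier is deterministic: identical inputs give identical
labels, and raising `device_intensity_min` can only shrink the DEVICE set
(shorter bright runs make the shadow test strictly harder).

## Coverage and the 1 mm² rule

A neck cell is *covered* iff a DEVICE pixel lies within ±`band_halfwidth_um`
(default 100 µm) of the wall radius along that cell's A-line — a strut must
sit at the ostium level to disrupt flow. At follow-up timepoints neointimal
tissue counts as coverage via the `include_tissue` flag; the day-0 default
counts DEVICE only, so acute thrombus is never mistaken for mechanical
coverage. Gaps are connected components of uncovered cells under
8-connectivity (diagonal uncovered runs are physically contiguous openings),
wrapping in θ for full-circumference necks and never across more than ±1
frame. The prediction rule is strictly greater-than: a largest gap of
exactly the threshold area (default 1.0 mm²) predicts occlusion.

## Statistics

* Occlusion grades are dichotomised GOOD = grade 1 (fully occluded) vs BAD =
  grades 2–3 (any residual filling).
* Fisher's exact test is two-sided under the probability-ordering
  convention (sum of hypergeometric probabilities of all margin-fixed tables
  no more probable than the observed one), stated explicitly because
  conventions differ. The implementation delegates to
  `scipy.stats.fisher_exact`; the test suite cross-checks it against a full
  enumeration oracle.
* Mann–Whitney U is reported as U₁ = #(a > b) + ½·ties. The default method
  enumerates every relabelling of the pooled sample (total n ≤ 12, i.e.
  C(11,7) = 330 splits for the study) and doubles the smaller tail
  probability, capped at 1 — valid under ties, where the textbook exact
  distribution is not. Larger samples use the tie-corrected normal
  approximation.
* Bland–Altman agreement: bias = mean paired difference, limits of agreement
  = bias ± 1.96 × sample SD (n−1 denominator). 1.96 gives the conventional
  95% limits; the midpoint of the limits equals the bias by construction.

## Phantom generator

The phantom emulates the geometry and first-order optics of a pullback
through a treated aneurysm; it is not a wave-optics simulation.

* **Geometry** — straight tubular vessel of constant radius (default
  1000 µm) with a saccular ostium (default 20 frames × 120°); 256 A-lines ×
  128 radial samples × 60 frames at 10 µm radial spacing and 100 µm frame
  pitch. This reduced scale keeps a full study's worth of phantoms at
  desk-scale runtime; all dimensions are configurable.
* **Optics** — the wall is a bright band (0.5 of the ceiling at the surface)
  with exponential depth attenuation (0.04 per sample, i.e. ~µm⁻¹·10⁻²
  scale typical of soft tissue at OCT wavelengths). Struts are thin arcs at
  the ostium radius rendered at 1.3× the ceiling before clipping — specular
  metallic reflections saturate the detector — and trail an exactly-zero
  shadow to the frame edge. Speckle is unit-mean multiplicative gamma noise
  with contrast 0.3 (the standard first-order OCT speckle model at a
  realistic post-processing contrast); an optional uniform residual-blood
  haze models incomplete contrast clearing. Everything is deterministic
  given the seed.
* **Edge conventions** — radial class edges sit half a radial sample inside
  the nominal radius and angular strut/ostium edges snap to polar-cell
  boundaries. This makes ground truth exact on the sampling grid: the
  noise-free surface index is exactly `round(R/Δr)` on every A-line, and the
  rasterised designed-gap area is unambiguous (the truth label volume and
  `true_gap_area_mm2` are rendered from the same geometry before noise).
* **Study fixtures** — `make_study_fixture` sizes a roughly physically
  square, cell-aligned gap to each requested area (rasterisation error at
  most one cell row) and emits case records whose 180-day outcome follows
  the >1 mm² association.

What the phantom does **not** model — and hence what passing tests do not
show about real data: catheter eccentricity and non-circular lumens,
guidewire artifacts, coil masses, multiple scattering, flow/contrast
dynamics, motion, and the expert review step of a clinical workflow (the
package offers parameter overrides instead). Phantom-recovery results bound
algorithmic error under the stated noise model, not in-vivo accuracy.

## Numerical and degenerate-input choices

* Gap ties in `find_gaps` sort by first occurrence after area (descending).
* An all-zero A-line, or one whose total intensity is 0, has no surface.
* `detect_shadow` with the strut at the last sample returns a vacuous
  complete shadow with an empty interval.
* Volumes are unsigned 16-bit on disk (multi-page TIFF + JSON sidecar);
  read(write(v)) is bit-exact. DICOM is out of scope — no public vendor
  dialect exists for this device class.
* Angular membership tests use a 1e-9 tolerance so snapped interval edges
  are stable under floating-point round-trips.
* Study reports serialise with sorted keys and no timestamps; re-runs on
  identical inputs are byte-identical and embed the config hash and seed.

## Problem sizes used by the bundled analyses

The test suite and `scripts/acceptance.py` run the seven observed gap
magnitudes at the default phantom scale (20 and 3 noise seeds per area,
respectively), 100-trial flood-fill and 200-table Fisher oracle fuzzes, and
a 500-replicate bias-recovery simulation (δ + N(0, 0.015²), n = 7) — sizes
chosen to exercise every code path at interactive runtimes.
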