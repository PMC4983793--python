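# Methods

## The measurement problem

A FLIP experiment produces single-channel fluorescence micrographs of
protein A/G agarose beads after an immunoprecipitation of a YFP-tagged
target. The diagnostic feature is spatial, not photometric: captured
protein sits on the bead surface, so in the image plane through a bead's
equator it appears as a bright annulus at the perimeter, while nonspecific
background binding distributes through the bead volume and appears as a
uniform glow. Whole-image mean fluorescence conflates the two, scales with
the number of beads in the field, and is inflated by any bright
contaminant. The per-bead ring-minus-body statistic isolates the surface
signal, and averaging per bead (rather than pooling pixels) makes the
image-level value independent of bead count and bead size.

## Segmentation

Pipeline: Gaussian smoothing (default σ = 2 px) → automatic histogram
threshold → raw-intensity trim → hole filling → boundary smoothing →
connected-component labelling → per-region shape scores.

Numerical choices that matter, and why:

- **Threshold.** The lowest of the 3-class multi-Otsu thresholds separates
  background from the *dimmest* foreground class. A plain 2-class Otsu can
  land above a control bead's dark rim (dimmer than the bead body, brighter
  than background), which would amputate the rim from the mask and silently
  turn a negative control signal into zero. When the histogram has fewer
  than three distinct grey levels the code falls back to 2-class Otsu. A
  fixed threshold can be supplied instead.
- **Raw-intensity trim.** Thresholding the smoothed image alone dilates the
  mask outward by a blur halo (up to ~2 px), which both breaks radius
  recovery and, worse, pushes background pixels into the rim band.
  Intersecting with `raw > threshold` pins the boundary to the true edge;
  all intensity statistics are computed on raw pixels only.
- **Boundary smoothing.** The raw trim leaves a ragged outline where the
  rim contrast is low relative to noise; raggedness inflates the measured
  perimeter and collapses circularity, causing false clump rejections. The
  binary mask is smoothed (Gaussian on the float mask, σ = 1.5 px, re-cut
  at 0.5) — a position-preserving operation on a straight or gently curved
  boundary. Set `mask_smooth_sigma = 0` to disable.
- **Shape filters.** Retained beads must satisfy circularity
  (4πA/P² ≥ 0.80), solidity (≥ 0.90), axis ratio (major/minor < 2.0) and
  equivalent radius within [5, 100] px. All three shape scores are needed:
  a digitised 2:1 ellipse measures circularity ≈ 0.81 and solidity ≈ 0.98,
  so the axis-ratio cut is what actually rejects moderately elongated
  contaminants; touching bead pairs measure circularity ≈ 0.7 with high
  solidity and near-unit axis ratio, which is the signature used to label
  them `clump` rather than `non_spherical`. Clumps are rejected, never
  split: each bead is treated as a single entity or not at all.
- **Border policy.** Beads touching the image border have an incomplete
  rim and are rejected by default (configurable).
- **Coordinates.** 0-based, row-major, pixel centres at integer positions;
  region labels are renumbered in (row, col) centroid order so output is
  deterministic.

Degenerate inputs: a constant image yields an empty region list; a fully
saturated image yields an empty list plus a warning; a blank condition
raises a distinct no-beads error rather than reporting zero signal.

## Ring/body quantification

The rim band is defined by Euclidean distance to background within the
bead mask: ring = depth ≤ t, body = depth > t + g, with
t = max(2 px, 0.15 · equivalent radius) and guard g = 1 px. The guard gap
absorbs the sub-pixel disagreement between the EDT depth and true radial
distance on a digitised disc (up to ~0.5 px) so partial-rim pixels
contaminate neither region. The defaults keep the body non-empty for beads
of radius ≥ 5 px; a bead too small for rim + guard + body raises an error
naming the bead. The per-bead difference is signed and never clipped —
zero-clipping of negative FLIP values is purely a display convention in
the screening report.

Replicates (duplicate pictures of separate bead aliquots) merge as the
mean of their signals, with the range (max − min) reported as the
variability ("var."). By default the pipeline merges raw replicate signals
per role and then subtracts the merged control.

No intensity normalisation is applied across images: FLIP assumes constant
acquisition settings within an experiment, so raw units are comparable
only within one experiment. Output tables carry the configuration hash and
package version.

## Calibration and planning

The standard curve is an ordinary least-squares line through
(ng YFP, fluorescence) points of a recombinant-YFP dilution series
(typically 0–500 ng), with the blank (0 ng) fitted as an ordinary point
rather than subtracted. Lysate mass is the curve inverse
(F − intercept)/slope; implied masses outside the fitted range are flagged
extrapolated, negative implied masses are floored at zero and flagged.
Curves refuse to mix plate/gain contexts, since autogain readings are only
comparable within a plate. Planning rules: large-volume format 700 µl at
≥ 0.5 ng/µl (≥ 350 ng YFP per IP); miniaturised format 100–120 µl at
≥ 0.3 ng/µl; exceeding the minimum is recommended for weak antibodies.
A linear (not four-parameter logistic) model is used because the dilution
series is linear over this range.

## Screening

The IP-efficiency index scales both immunoblot bands to whole-reaction
equivalents before the ratio:
% tot. lysate = 100 · (IP band / fraction of IP loaded) /
(input band / fraction of lysate loaded). It is therefore invariant to gel
exposure and to how much of each reaction was loaded; values above 100 %
are reported with a flag rather than clamped. The FLIP call is positive
iff the corrected signal exceeds zero; tiers annotate the empirical
separation between true positives (mostly > 1.0) and false positives
(< 0.6) and are descriptive, not filters. The IP/IB call is an input — the
blot pass/fail judgement is the operator's — and concordance is tallied as
a 2×2 table with rate (TP+TN)/total.

## Synthetic scenes

The generator renders what the analysis consumes: filled discs of uniform
body intensity with an annular rim (rim thickness 0 = uniform bead),
ellipse and polygon contaminants, overlapping bead pairs (union of discs,
max intensity on shared pixels), additive Gaussian noise and optional
Poisson shot noise, clipped to the 8- or 16-bit range. A scene's seed
fully determines its pixels. Ground truth records the label image and each
bead's true ring mean, body mean and difference.

Default study conditions used by the tests and the acceptance script,
chosen once as representative of the assay: 224×224 to 320×320 frames,
background 10, bead radius 15–25 px, positive beads rim 1000 / body 200
(difference 800), dark-edged controls rim 100 / body 300 (difference
−200), uniform controls body 500 (difference 0), Gaussian σ up to 50
(5 % of the positive rim intensity). In the noisy-recovery study the bead
rim is drawn 4 px thick against a 3 px measurement band with a 2 px guard,
so both measurement regions sit strictly inside their true regions even
when noise shifts the segmented boundary sub-pixel — with band = rim
thickness, any boundary shift mixes regions and biases the estimate. That
study uses uniform-glow controls, the common background phenotype; a
dark-edged rim of contrast 90 over background under σ = 50 noise is below
the segmentation contrast limit, and its inward boundary bias is a
property of the imaging conditions, not of the estimator (the dark-edge
sign behaviour is verified noiselessly instead).

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about real data: optical point-spread blur, depth-of-field
and focus variation, intensity gradients across the field, autofluorescent
debris with bead-like shape, bead-size polydispersity within a field,
photobleaching, and multi-layer bead stacking. Results on synthetic scenes
validate the arithmetic and the filtering logic, not microscope-specific
robustness.

## Known limitations

- Touching beads are rejected, not split; densely packed fields lose most
  of their beads to clump rejection (the QC report flags this).
- The two-region model ignores radial structure finer than ring/body;
  there is no subpixel rim localisation.
- Circularity depends on the digitised perimeter and is scale-dependent
  for very small regions; radius bounds should be kept well above 3 px.
- Intensities are arbitrary units; cross-experiment comparison requires
  identical acquisition settings by design.
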