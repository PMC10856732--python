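# Methods

## Registration model

Each fundus image is mapped to a canonical frame by the unique
orientation-preserving similarity transform fixed by two point
correspondences: the optic disc and the macula. Writing points as complex
numbers, the transform `T(z) = a·z + b` has `a = (d′ − m′)/(d − m)` and
`b = m′ − a·m`, where `(d, m)` are the source landmarks and `(d′, m′)`
the canonical targets for the image's laterality. Four degrees of freedom
(uniform scale, rotation, 2-D translation) are exactly determined; shear
and reflection are excluded by construction, so anatomy is never
mirrored by registration — laterality is instead handled by an explicit
flip at the aggregation stage. Records whose landmarks are closer than
one source pixel are rejected as degenerate rather than producing extreme
scales.

### Canonical frame

The frame fixes only relative geometry by convention — 250 px horizontal
disc–macula separation, macula 25 px below the disc (disc–fovea angle),
1100 × 1100 px canvas — leaving absolute placement open. We place the
right-eye targets at disc (675, 537) and macula (425, 562): the
disc–macula midpoint sits near the canvas centre, and the left-eye
targets, defined as the exact mirror under `x′ = 1099 − x`, then land on
integer coordinates (disc (424, 537), macula (674, 562)). This makes the
later mirror-combination exact at the landmarks. Coordinates are 0-based,
x rightward, y downward, pixel centres at integers. The convention that
the right eye's disc lies to the image-right of the macula (erect fundus
photograph) can be inverted with the `disc_side` config flag for sources
using the opposite convention.

### Warping

Masks are binary, so warping uses inverse-mapping nearest neighbour:
each canvas pixel centre is pulled back through `T⁻¹` and takes the
nearest source pixel's value, 0 outside the frame. Bilinear interpolation
would require an arbitrary re-binarization threshold; nearest neighbour
keeps outputs strictly 0/1 and is deterministic. The cost is sub-pixel
jitter at mask boundaries, bounded in the tests by a ≥ 95 % foreground
round-trip recovery for scales in [0.8, 1.25].

## Aggregation

Warped masks are summed per feature into integer count matrices,
separately for left and right eyes. Laterality combination mirrors the
left matrix with a full-canvas horizontal flip and adds it to the right
matrix. Because the canonical frames of the two lateralities are exact
mirrors, the full-canvas flip coincides with a flip about the macula
column at the landmarks while never mapping pixels off-canvas, and —
being a bijection of the canvas — conserves total mass exactly.

Display normalization maps counts `v` to `⌊255·v / max⌋` (all-zero
matrices stay zero): integer output, maximum exactly 255. Normalization
happens last, after combination, matching the order in which matrices are
assembled. Severity stratification uses post-audit grades; ungraded
images are excluded from stratified maps but contribute to all-severity
maps.

## Overlap statistics

Dice coefficients are computed on binarized supports, not weighted
counts: the scientific question is *where* features occur, not how
often. The absolute variant uses every pixel with count ≥ 1. The trimmed
variant thresholds each matrix at the value best approximating the
median of its cumulative frequency distribution: over candidates
`t ∈ {1..max}`, retained mass `R(t) = Σ v·[v ≥ t]` is computed and the
`t` minimizing `|R(t) − R(1)/2|` chosen, ties broken toward smaller `t`
(retaining more data). "Cumulative frequency" is ambiguous between count
mass and pixel counts; both are implemented (`trim_statistic ∈ {mass,
pixels}`), with mass the default since each annotation, not each pixel,
is an observation. Each matrix is trimmed at its own threshold by
default (a shared-threshold option exists). Degenerate inputs where all
thresholds tie (uniform matrices, a single occupied pixel) resolve to
the smallest threshold by the tie rule; the exhaustive search is
normative. Dice of two empty supports is defined as 0 with a warning
rather than NaN. No significance testing is attached to Dice values.

## ICDR grade audit

The rule ladder in `min_consistent_grade` maps feature findings to the
least consistent ICDR grade (see README). Two deliberate restrictions:

* the "4-2-1" severe-hemorrhage criterion needs an "extensive in four
  quadrants" judgement that presence flags cannot encode; an optional
  `severe_hemorrhage_quadrants` count enables it, otherwise hemorrhages
  cap at moderate;
* audits only raise grades. A nominated grade above the annotation
  minimum is legitimate (graders may see features the annotations omit),
  so it is left unchanged.

Venous-beading quadrants, when derived from spatial annotations rather
than supplied, would be defined by horizontal/vertical lines through the
canonical disc position; the shipped pipeline conservatively assigns two
quadrants when beading is annotated at all, which is the reading implied
by the documented audit cases.

## Synthetic data generator

The generator emulates the acquisition variation that motivates
colocation: per-image jitter in scale (0.8–1.25 on top of resolution
scaling), rotation (±5°), translation (±40 px), source resolution
(900–1400 px square) and laterality (right-eye fraction 0.51, a balanced
clinic mix). The synthetic camera is itself a similarity transform from
canonical to source coordinates; landmarks are the canonical targets
pushed through it, so registration must invert the camera exactly — a
structural self-check used in the tests.

Lesions are filled disks (radius 2–9 px depending on feature, scaled by
camera scale) with Poisson counts per image and centres drawn from
per-feature Gaussian mixtures defined in canonical right-eye coordinates
and mirrored for left eyes. Default mixtures qualitatively follow DR
anatomy — diffuse microaneurysms; exudates at and temporal to the fovea;
cotton wool spots in a peridisc arc sparing the temporal macula;
hemorrhages broadly over the posterior pole; venous beading on the
proximal arcades. Default Poisson rates (microaneurysms 25, exudates 20,
hemorrhages 15, cotton wool spots 5, venous beading 1.5 per image)
reflect typical lesion multiplicity in affected eyes and give the
recovery validation below adequate counting statistics. These defaults
are illustrative; they are not fitted to any measured frequency map.

What the generator deliberately does **not** model: lesion morphology
(disks only — the analysis uses location frequency, not shape), vessel
trees, photometric content, grader disagreement, or spatial correlation
between features within an eye. Passing tests therefore demonstrate that
the geometry, bookkeeping and statistics of the pipeline are correct,
not that real DR lesions follow the default densities.

### Recovery validation

Generating 200 eyes from the default exudate density and running the
full pipeline (warp → accumulate → mirror-combine) yields a combined
count matrix whose Pearson correlation with the true density, smoothed
by the mean-radius lesion-disk kernel, exceeds 0.8 (seeded run; observed
≈ 0.86). The ceiling on this correlation is set by Poisson counting
noise: an ideal draw from the model's own mean field gives ≈ 0.85–0.86
at these rates, so the pipeline sits at the attainable limit.

## Numerical choices

* Closed-form complex-ratio solution for the transform; verified in
  tests against an independent least-squares similarity estimator.
* Landmark mapping error after registration ≤ 1e-6 px over 1,000 random
  records (floating-point exactness of the closed form).
* Count matrices are int64; CSV persistence round-trips exactly.
* All randomness flows from a single integer seed through one
  `numpy.random.Generator`; generation order is fixed, so datasets and
  pipeline outputs are byte-reproducible.
* Problem sizes in the shipped tests (200 eyes for recovery, 6–12 eyes
  for end-to-end contracts, 1,000-case oracle fuzzing) were chosen to
  make each check statistically meaningful while keeping the default
  suite fast.

## Known limitations

* Two-landmark similarity registration cannot correct lens distortion or
  spherical-projection effects; peripheral positions are approximate.
* Quantitative overlap values on real datasets depend on annotation
  conventions (pixel masks vs bounding boxes) — box-derived supports are
  rectangles and inflate overlap relative to pixel masks.
* The trim threshold is discrete; for matrices with few distinct values
  the retained mass can sit far from 50 %.
* Heatmaps are counts of annotated images, not prevalence estimates: no
  correction is made for how many images could have shown a feature at a
  given canvas location (field-of-view coverage varies across images).
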