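# Methods

This note documents the models, conventions and numerical choices the
package makes, what its synthetic data do and do not emulate, and the
design decisions taken where several readings were defensible.

## Stimulus model

A frame is a grid of square dots anchored at the top-left corner and
placed row-major; cells in the last row/column are clipped when the
frame dimensions are not multiples of the dot size (statistically
equivalent to any other anchoring).  Each cell's tone is drawn by
rejection sampling from the raw generator stream: a raw value is
accepted when it is below `floor(max/k)·k`, which removes modulo bias
exactly.  Rendering a frame consumes exactly `ceil(W/d)·ceil(H/d)`
index draws; the whole sequence is a pure function of `(config, seed)`.

Default profile: 1920×1200 px, 7-px dots (1.89 mm at 0.27 mm/px dot
pitch), five tones, 60 fps, 60 frames.  The frame interval is exactly
`1/fps` (16.67 ms at 60 fps).  Frames are written as single-channel
8-bit PNG (the dots are achromatic, so one channel is lossless), plus
binary PGM for dependency-free round trips.

**Palette.**  The five tones are stored as explicit 8-bit levels
(255, 191, 127, 64, 0) paired with their nominal design ratios
(1.0, 0.75, 0.5, 0.25, 0.0).  Levels are not derived by rounding
`ratio × 255` because no single rounding rule produces all of 191, 127
and 64 from those ratios; the explicit level set is canonical.

**Generators.**  Production: Marsaglia xorshift32 with the canonical
shift triple (13, 17, 5) — the textbook parameterization; the first
two outputs from seed 1 are 270369 and 67634689.  Seed 0 (a fixed
point of the xorshift map) is remapped to the documented constant
123456789 rather than rejected.  Demonstration: a configurable LCG
with a RANDU-style preset (a = 65539, c = 0, m = 2³¹).

**Display geometry.**  `eccentricity_deg` uses the half-extent
convention — the angle from fixation (screen centre) to a screen edge,
`atan((extent/2)/distance)` — under which a 51.84 × 32.4 cm panel at
30 cm spans 40.8° × 28.4°, and 34.6 cm of width is needed for a
central 30° field.  `predict_luminance` is a plain gamma model
`white·(level/255)^γ`; it ignores the panel's black-level offset and
under-predicts dark tones by ~10–15 %, which is adequate for sanity
checks but not calibration.

## Homogeneity QC

Within-frame statistics use the population SD convention (image-tool
style); across-frame spreads use the sample (n−1) convention
("mean ± SD over 60 images").  Analytic references for the default
five-tone stimulus: level mean 127.4, level SD σ = 90.09, SE of a
frame mean ≈ σ·d/√N = 90.09·7/√2,304,000 ≈ 0.415, per-level count
expectation N/5 = 460,800 per frame.

`temporal_average` is a linear mean of `round(shutter·fps)` frames
(12 frames for a 1/5-s exposure at 60 fps) — a linear surrogate for a
long-exposure photograph; camera nonlinearity is irrelevant to the
artifact it reveals.

**Stripe statistic.**  The averaged image is reduced to dot-cell means
(full cells only); the statistic is the variance of per-cell-column
means (and symmetrically per-row), with a permutation null obtained by
shuffling the cell values.  The reported z/p belong to the more
extreme axis; because of that selection the combined p is used for
*flagging* only, while the per-axis permutation p is the exchangeable,
uniformly distributed quantity.  The two-sided p uses absolute
deviation from the null mean with the +1 finite-sample correction.

**Artifact demonstration conditions.**  With the five-tone palette the
RANDU LCG does *not* reliably stripe: the dot index is the raw value
mod 5, which mixes all state bits.  The artifact appears under
specific stimulus conditions — notably the number of tones.  The
demonstration configuration therefore uses a four-tone palette: with
k = 4 and a power-of-two modulus the index is the two lowest state
bits, which for a multiplicative LCG have period 2, so dot tones
alternate deterministically and every even-width frame shows column
stripes (z ≈ 74 on a 28×20-cell frame) while xorshift stays
homogeneous (|z| < 4) on the same seeds.  This is a qualitative
generator-pathology demonstration, not a claim about any particular
historical implementation.

## 30-2 classification

The 76-point layout ships as JSON in temporal-positive coordinates
(+x temporal, +y superior), so OS charts are mirrored on load and all
logic is laterality-free; the blind spot is always (+15, ±3).  The
edge set is the 24-point outer rim (points missing at least one
orthogonal 6° neighbour) — the same ring removed when the 24-2 pattern
is derived from the 30-2; the nasal edge is the rim's nasal extreme
column (x = −27, two points per hemifield).

Cluster rule: connected components of points depressed at p < 5 % on
the pattern-deviation plot under **8-adjacency** (diagonals count, the
usual clinical contiguity reading), evaluated per hemifield with no
adjacency across the horizontal meridian, blind-spot points excluded.
The counted size is the number of non-edge members plus at most two
nasal-edge members; other rim points keep a component connected but
never add to its size.  A component qualifies with counted size ≥ 3
and ≥ 1 member at p < 1 %.  PD probability categories are modelled as
the instrument's four significance bins (<5, <2, <1, <0.5 %) with
"stricter-than" comparisons, so the ≥5 % bin is never significant and
<0.5 % satisfies the <1 % requirement.

The abnormality decision is the disjunction {qualifying cluster, PSD
p < 5 %, GHT outside normal limits}; PSD and GHT are consumed as
instrument outputs, never computed.  When the PD map is withheld
(severe depression) the cluster branch is skipped — PSD/GHT still
decide — and direct cluster queries raise an input error.

Stage boundaries −6 and −12 dB both belong to M2; M4 is keyed solely
on the withheld PD map.  The axial-length surrogate is
`24 + 0.333·|ES|` mm.

## Agreement scoring

Shadow hemifield flags are the union of region quadrants.  Blind-spot
exclusion requires *all four* marks: isolated, temporal, straddling
the horizontal meridian, centroid within 15° ± 5° (the tolerance is a
parameter).  Categories, with `coincide` = number of hemifields
abnormal in both tests: no reproducible drawing → NoResponse;
coincide = 0 → NoAgreement; flags identical (and coincide ≥ 1) →
Agreement; otherwise → PartialAgreement.  In particular a drawing that
adds a hemifield the perimeter calls normal, while the abnormal
hemifield coincides, scores PartialAgreement — the definition keys on
coincidence of abnormal areas; this reading is a documented choice,
not the only possible one.  Normal fields (no abnormal hemifield) are
outside the category space: a reproducible drawing there counts
against specificity, a NoResponse as a correct negative.

**M4 convention.**  A field with the PD map withheld has no per-
hemifield cluster flags, yet severely depressed eyes were scored in
practice.  The package treats such fields as abnormal in both
hemifields (`m4_hemifield_flags`).  Under that convention NoAgreement
is impossible for M4 — any drawn shadow coincides somewhere — so the
synthetic generator raises a generation error for that combination.

## Statistics

* McNemar: exact binomial form on the discordant pairs, two-sided by
  doubling (matches 0.0156/0.0625/0.5000 on discordant counts 7/5/2
  vs 0); the chi-square approximation is never used.
* Binomial preference test: equal-tails exact p at p₀ = ½.
* Chi-square: Pearson, no continuity correction; adjusted residual
  `(O−E)/√(E(1−rᵢ/N)(1−cⱼ/N))`.  Homogeneous-subset letters are
  reproduced with a residual rule (cells not significantly high at
  |r| < 1.96 share subset "a", not significantly low share "b") —
  a heuristic that reproduces the published groupings, not a full
  pairwise post-hoc procedure.
* Confidence intervals: Clopper–Pearson exact (Beta quantiles).  This
  choice reproduces the published intervals (e.g. 79.8–99.3 % for
  31/33), which Wald/Wilson intervals do not.
* Specificity: share of normal eyes with no reproducible shadow.

The preference table emits computed rates; for the shipped fixture the
total CG-better share is 94/134 = 70.1 % (one published table prints
70.9 % for that cell, inconsistent with its own marginals and the
accompanying text, so the computed value stands).

## Synthetic data

`expand_from_counts` is deterministic: outcomes are laid out in fixed
order and analog detections are paired onto the leading CG-detected
slots.  Any pairing consistent with the marginals yields identical
statistics; the fixture's paired structure (no analog-only detections,
b = CG-detected − both per stage) is validated on load, not assumed.

`simulate_cohort` draws per-stage multinomials over paired outcome
categories with a seeded NumPy generator; preferences are drawn
independently within the both-detected stratum, because no published
cross-tabulation of preference by outcome category exists.

`synth_vf_and_shadow` grows a random connected cluster of non-edge
points per flagged hemifield (sizes 3/6/10 for M1/M2/M3, all members
at p < 5 % with one at p < 1 %), samples MD uniformly inside the
stage's interval, and builds a shadow record matching the target
category.  It emulates the *logical* shape of real data — cluster
contiguity, hemifield structure, blind-spot drawings — but not defect
depth, point-wise correlation structure, arcuate morphology, or
response noise; passing tests therefore validate the classification
and scoring chain, not clinical realism.

## Problem sizes and tolerances

Tests run the full 1920×1200×60-frame sequence where image statistics
are asserted (a few seconds), and 30×30-cell frames elsewhere.  The
stochastic acceptance bands are analytic: mean-of-means within
127.4 ± 0.30 (5.5 SE of the 60-frame mean), sd-of-means in
[0.30, 0.55] (the SD estimator's sampling range at n = 60 around
0.415), per-level count means within ±1,600 of 460,800.  Oracle
equivalence tests (cluster detection vs graph components, exact tests
vs pmf enumeration, agreement vs truth table) are exhaustive or use
1,000 seeded random instances.

## Known limitations

* No real-time presentation, video encoding, or hardware capture; the
  stimulus is produced as frame files.
* GHT and PSD logic, SITA thresholding and OCT processing are consumed
  as inputs, never computed.
* The histogram *shape* classification of analog noise stills
  (bell vs trapezoid) is a visual judgment and is not automated.
* The blind-spot exclusion operates on the examiner's region
  annotations (isolated/temporal/straddling flags), not on digitized
  drawings.
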