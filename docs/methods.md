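# Methods

This note documents the models, parameter choices, and limitations of the
facetriad pipeline in the order data flows through it.

## Synthetic face generator

The generator exists so that every downstream stage can be validated
against planted ground truth. It emulates, at toy-image scale, the three
properties of real face corpora the analyses depend on:

1. **Expression signal in three channels.** Each of the six expressive
   classes displaces landmark groups (shape), shifts region colors, and
   changes the surface-noise statistics (texture). Displacement directions
   follow textbook action tendencies — anger lowers and draws in the brows,
   fear raises them and widens the eyes, happiness raises the lip corners,
   surprise raises the brows and drops the jaw. Magnitudes (2–5 reference
   pixels on a 128-px canvas) are free parameters chosen so that classes
   are cleanly separable at zero noise yet overlap realistically at the
   default idiosyncrasy level; they are modelling conveniences, not
   empirical claims about real expressions. Texture signatures combine an
   amplitude change with a per-emotion correlation scale/anisotropy of the
   band-limited noise, because a single amplitude scalar cannot carry a
   7-class signal.
2. **A gender covariate and a tunable gender–emotion confound.** Male faces
   get small constant shape/color/texture offsets. Independently, a
   *confound specification* moves one gender's **neutral** faces toward a
   chosen emotion's fields; the default plants male neutrals halfway
   (scale 0.5) toward anger and female neutrals halfway toward fear — a
   subtle resemblance rather than a full expression, which is the regime
   the downstream mediation and classification analyses are designed to
   detect. The applied per-landmark fields are stored in the cohort
   manifest so recovery tests compare against the generator's own record.
3. **Rating and trial tables with known structure.** Trait ratings are
   linear in latent dominance/affiliation plus Gaussian noise; masculinity
   and femininity are constructed as near-perfect mirror images
   (reproducing the strongly negative correlation typical of normed rating
   sets). Trial tables plant an exact, manifest-recorded number of
   low-variance participants (response SD ≈ 0.1) and out-of-range reaction
   times (20 ms / 20,000 ms).

All randomness derives from one seed; each face consumes an independent
counter-keyed substream (`default_rng([seed, face_index])`), making cohorts
order-independent and byte-reproducible.

**What the generator does not emulate:** photorealism, 3D pose, lighting,
identity covariance between channels, occlusions, or the distribution of
any real face database. Passing tests therefore demonstrate that the
*pipeline machinery* is correct and sensitive to planted effects of
realistic size — not that the same effect sizes hold on real faces.

## Triad feature extraction

- **Normalisation** is a closed-form similarity alignment: eye-midpoint to
  the origin, eye line horizontal, interocular distance 1. This gives exact
  translation/rotation/scale invariance without iterative Procrustes
  fitting, which a fixed template does not need.
- **Structure** features are the 84 normalised coordinates plus six named
  distances (brow–eye gaps, mouth width/curvature, eye–mouth distance,
  nose length). The distances are redundant with the coordinates but make
  the features that classic overgeneralization manipulations target
  directly inspectable.
- **Color** statistics use CIELAB (perceptual uniformity) for per-region
  mean/SD, raw RGB means per region, and eye/mouth-vs-cheek contrasts
  computed on linear Rec.709 luminance of the [0,1] RGB values — linear
  luminance is used for the contrasts so that an additive channel shift of
  δ moves the feature by exactly δ. Eye and mouth interiors are excluded
  from cheek statistics so skin measures stay skin-only.
- **Texture** features are mean-absolute response and response SD of a
  Gabor bank (orientations 0°/45°/90°/135°, wavelengths 4/8/16 px) over
  the interior mask, on luminance mean-centred within the mask (a constant
  image scores exactly zero). Kernels come from scikit-image; convolution
  is FFT-based for speed. Masks smaller than the largest kernel support
  are rejected rather than silently zero-padded.

## Emotion models

The base learner is scaler + multinomial logistic regression
(scikit-learn), with a config hook for gradient-boosted trees. Calibrated
class probabilities are all the downstream math needs; model capacity is
deliberately modest. Neutral is a seventh training class; the face-space
projection later consumes only the six expressive probabilities. Each
metric model's ensemble weight is its held-out accuracy (stratified
internal split, test faces never seen in fitting); the combined output is
renormalised by the weight sum so it stays on the simplex.

## Face space

Default loadings (dominance; affiliation): anger (1; −1.5), disgust
(0.6; −1), happy (1; 2), fear (−0.5; 0.5), sad (−1; 0.1), surprise
(−0.5; 0.1). The six probabilities are *not* renormalised after dropping
neutral: a mostly-neutral face should sit near the origin, and rescaling
would erase exactly the "distance from neutral" the selection step uses.
Angle convention: x = affiliation, y = dominance, θ = atan2(D, A) wrapped
into [0, 360). Quadrant windows are inclusive on both ends with a strict
distance cut E > 0.15; the quadrant-IV window is 280–350°, chosen by
symmetry with the other three windows. Ranking ties are broken lexically
by face id for reproducibility.

## Morphing

A transform is a two-image blend: landmarks averaged pointwise, both
images warped onto the average shape by per-triangle affine maps over a
Delaunay triangulation computed once on the mean template and reused
(re-triangulating per face could flip topology between warps), bilinear
sampling, pixels outside all triangles passed through, output clipped to
[0, 1]. At α = 0.5 with a near-average base this coincides, up to the
base's own deviation from the mean, with prototype-difference transforms
used in psychophysics tooling; the two-image formulation was chosen
because it is exactly invertible at the endpoints (α = 0 and 1 recover
base and donor to interpolation error). Manual artifact inspection is
replaced by automated QC flags (landmark bounds, pixel range, degenerate
output). Donors are sampled without replacement per base × category, with
replacement only when a gender-matched pool is too small (flagged).

## Statistics

- **Mediation** standardises all three variables (including a binary
  gender predictor — the convention is stated rather than assumed, since
  "standardised betas" is ambiguous for binary x), estimates a from m~x,
  b and c′ from y~x+m, c from y~x, and reports ab = a·b with a percentile
  CI over case-resampled bootstrap replicates (default 10,000; percentile
  rather than BCa). Point estimates and SEs come from statsmodels OLS;
  bootstrap replicates use the closed-form correlation identities for
  standardised two-predictor OLS, which makes 10⁷ replicate-regressions
  feasible in seconds. The decomposition c = c′ + ab is exact for
  standardised OLS and asserted on every call.
- **Correlations** are plain Pearson r with two-sided p-values, α = 0.05,
  no multiple-testing correction; zero-variance cells are NaN.
- **Preprocessing** drops participants with response SD < 0.4, then trials
  with RT < 50 ms or > 10,000 ms, then shifts responses by −1 to 0–6. The
  shift is guarded by a range check (applied only while the table minimum
  is ≥ 1), making the step idempotent.
- **Mixed-model contrasts** for transformed-vs-base ratings are a thin
  wrapper over statsmodels MixedLM (participant random intercept,
  attractiveness covariate); nothing is re-implemented there.

## Problem sizes and numerical choices

Test and demo cohorts use 128-px images, 8–36 faces per emotion × gender
cell (112–504 faces), 200–400 neutral evaluation faces, and 300–1,000
bootstrap replicates; these sizes were chosen so planted effects are
estimated with comfortable margins while the whole suite runs in about a
minute. Tolerances: geometric identities to 1e−9, warp fidelity to 1 gray
level, contrast recovery to ±0.02, planted landmark recovery to ±0.5 px at
n = 200. Degenerate inputs (coincident eye centers, collinear landmarks,
zero-area warp triangles, constant mediation columns, empty regions) are
rejected with specific messages rather than propagated as NaN.

## Known limitations

- The feature definitions are this package's own fixed choices; other
  reasonable structure/color/texture parameterisations exist.
- The generator's emotion geometry is group-level (whole-group offsets),
  so within-group shape changes (e.g. asymmetric brow raise) are not
  representable.
- Classifier accuracies on synthetic cohorts say nothing quantitative
  about accuracy on photographic face databases.
- The percentile bootstrap can undercover slightly at small n; BCa was
  deliberately not implemented.
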