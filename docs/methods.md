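# Methods

This note records the models implemented in `graytex`, the conventions that
downstream code depends on, the numerical choices made where the design was
genuinely open, and what the synthetic-data tests do and do not establish.

## Coordinate system

**Convention (version 1).** The 2×2 glider positions are indexed row-major:
`A1` top-left, `A2` top-right, `A3` bottom-left, `A4` bottom-right. A texture
group is a coefficient vector `s ∈ Z_G^4 \ {0}` in canonical form: the
support's bounding box touches row 0 and column 0 (translation invariance
identifies translated supports), and `s` is the lexicographic minimum of its
orbit under multiplication by units of `Z_G` (for prime `G` this makes the
first nonzero coefficient 1; scaling by a unit `u` only relabels
`h ↦ u⁻¹h`, so it carries no information). Enumerating canonical vectors
gives, for `G = 3`: one first-order, eight second-order, sixteen
third-order and eight fourth-order groups; at `G − 1` independent
probabilities each, a 66-dimensional space, and 10 dimensions for `G = 2`.

**Names** are order letter (γ, β, θ, α) plus one symbol per glider position
(`+` for 1, `-` for `G−1`, `0` for absent; trailing zeros dropped):
`beta(++)` horizontal sum, `beta(+0+)` vertical sum, `beta(+00-)`
main-diagonal difference, `beta(0+-)` anti-diagonal difference. The
published compact notation is ambiguous for the diagonal pairs, so the
explicit form is used everywhere; display-only aliases would be cosmetic.

**Flattening order** — groups sorted by (order, support in raster order,
coefficients lexicographically), `h = 0..G−1` within each group — is fixed
and versioned (`COORDINATE_VERSION`), because every covariance, model file
and direction vector depends on it. The flattened vector keeps all `G`
probabilities per group (each triplet sums to 1); the rank deficiency is
harmless because all direction vectors live in the per-group sum-zero
subspace, and a full-rank 66-dimensional projection (`independent_coords`)
is used where an invertible representation matters (the blur-rejection
mixture).

**Analysis.** `analyze` glides the *minimal* bounding shape of each group's
support (a 1×2 window for a horizontal pair, etc.); with `boundary='valid'`
this matches the published procedure and differs from gliding the full 2×2
block only through edge effects of order `1/R`. `boundary='periodic'` wraps,
which makes coordinates exactly translation invariant and enables bit-exact
oracles: gliding analysis equals marginalization of the wrapped 2×2 block
histogram, exactly (probabilities are integer counts over placements).

**Block-distribution duality.** `coords_from_block_probs` marginalizes a
block distribution onto each group; `block_probs_from_coords` inverts it via
characters of `Z_G^4`: every nonzero `s` is a unit multiple of a translated
canonical vector, so each Fourier coefficient of the block distribution is a
character sum of one group's probability triplet. Reconstruction with
negative entries beyond 1e−9 raises an infeasibility error — the requested
coordinates are inconsistent with any translation-invariant block
distribution (e.g. all-other-groups-uniform with one pair group saturated).

**Plane geometry.** Simple planes embed a group's probability simplex with
the orthonormal basis `e_x = (2,−1,−1)/√6` (toward the `p0` vertex; angles
0°, 120°, 240° point at the vertices) and `e_y = (0,1,−1)/√2`; contrast is
Euclidean distance from the origin, so a vertex sits at `√(2/3)`. Mixed
planes use saturation units: coordinate `t` on axis `(g, h)` means
`p_h = 1/3 + 2t/3` with the group's other probabilities equal, so `t = 0`
is the unbiased texture and `t = 1` full saturation; a unit coordinate is
`√(2/3)` in Euclidean length for every angle, so the two conventions differ
by a single constant per plane kind, which the global threshold scale
absorbs. `plane_point` never clips: feasibility is the synthesizer's (or
the reader's) concern, since measured thresholds may legitimately fall
outside the simplex in low-sensitivity directions.

## Texture synthesis

**Single group.** The patch is seeded i.i.d. uniform and swept in raster
order; wherever a glider placement has its last (raster-order) support cell
at the current position, `h` is drawn from the target distribution and the
cell solved as `x = s_last⁻¹(h − Σ_others s_i A_i) mod G`. Each placement of
the minimal glider then carries an independent draw from the target, all
remaining degrees of freedom stay uniform, and degenerate targets (a
probability of 1) are reproduced exactly. Recurrences that only look at
earlier rows or earlier columns are vectorized; the two wavefront cases
(one θ support and α) fall back to a per-cell loop.

A logical caveat: fixing a pair group near saturation *necessarily* moves
some fourth-order coordinates (if all horizontal sums are ≡ 0, the 2×2 sum
is ≡ 0 too — no distribution can avoid it). First-order and the other
second-order groups remain exactly at `1/G` under this construction, which
is what the round-trip and entropy tests assert; "all other coordinates
unbiased" holds in full only near the origin.

**Two groups (mixed planes).** The same sequential fill with *tilted*
conditionals: a cell constrained by group `c` is sampled with weight
`exp(λ_c)` on the level that realizes the constrained statistic value. The
tilts are calibrated by a damped fixed-point iteration (synthesize a 72×72
calibration patch, measure the realized axis probabilities, update
`λ_c ← λ_c + 0.7·clip(logit(v) − logit(q), ±1.5)`, stop at residual
< 0.012 or 30 iterations). The calibration RNG is derived from a hash of
the constraint targets, so the tilts are a pure function of the request and
the final patch is deterministic given the user's seed. Non-convergence or
vanishing conditional probabilities raise an infeasibility error with the
attempted target — the constructive counterpart of the fact that some
coordinate combinations cannot be achieved in a real texture (e.g. full
saturation in two groups at once). Near the origin the initial
independence-based tilt is already nearly correct and calibration converges
in a few iterations.

**Stimuli.** The 4AFC array is 64×64 checks with a 16-check-thick strip at
an 8-check margin from the chosen side (0-based rows 8..23 for `top`;
1-based 9–24). One region is the structured texture, the other i.i.d.
uniform, per the `structured_target` flag; sub-seeds for the two regions are
spawned from the user seed.

## Image pipeline

Stage order: log intensity (skipped for log-encoded input) → N×N block
averaging (defaults `N = 2`) → non-overlapping R×R patches (`R = 32`,
partial edges dropped, never padded) → whitening → ternarization → analysis
→ blur rejection.

- **Whitening**: one filter for the whole ensemble, the reciprocal square
  root of the mean patch power spectrum, built from the same patches that
  are subsequently analyzed. The DC gain is set to 0: ternarization is
  rank-based, so the patch mean is irrelevant, and the DC power is
  dominated by luminance rather than spatial structure. By construction the
  post-whitening ensemble-mean spectrum is flat.
- **Ternarization**: rank-order thirds (counts within ±1 of `R²/3`,
  remainder assigned to the lower levels); ties are broken by a seeded
  pseudorandom permutation of the tied indices — deterministic and
  unbiased across levels.
- **Sharpness** is computed per patch on the *raw* linear-intensity region
  (before log and downsampling): divide by the median, convolve with the
  3×3 Laplacian `[[0,1,0],[1,−4,1],[0,1,0]]`, take the median absolute
  response over interior pixels only (no assumption about pixels outside
  the image).
- **Blur rejection**: a two-component Gaussian mixture with full, unshared
  covariances (scikit-learn, k-means++ init, 10 restarts, ridge 1e−6,
  seeded), fit on the 66 independent coordinates; patches go to their
  maximum-responsibility component and the component with the higher median
  sharpness is kept (ties: the larger component). The fit dimension is a
  design choice — the full coordinate vector, not a 2D projection.

## Threshold prediction

A Gaussian is fit to the in-focus coordinate vectors (sample mean and
covariance; variance is taken about the sample mean, the usual sense of
standard deviation). The unscaled prediction along a plane direction is
`(uᵀΣu)^(−η/2)` where `u` is the direction's *unit-contrast* displacement,
so predictions come out in the plane's own contrast units and, within any
plane, lie exactly on an origin-centered ellipse as a function of angle.
`η = 1` is the linear sampling-limited efficient-coding exponent; `η = 0`
decouples predictions from the data entirely (all thresholds equal). The
single global scale is the weighted geometric mean of measured/predicted
ratios with weights `1/ε²` (the closed-form minimizer of the stated
log-space objective); `fit_eta` is a weighted least-squares line in
`(−log σ, log t)`, returning a point estimate only — no posterior interval
machinery.

## Psychophysics

Base-2 Weibull, guess rate pinned at 0.25, lapse rate 0 (the published
variant is not specified; this parameterization makes threshold ≡ λ with
`fc(λ) = 0.625` exactly). Maximum-likelihood binomial fit over
`(log λ, log k)` by Nelder–Mead; bootstrap (default 1000 resamples, seeded;
binomial resampling of trials at each contrast) gives a percentile
confidence interval and a log-space SE of half the central 68% interval.
All-chance data is flagged `unbounded`; a threshold outside the tested
contrast range is flagged `extrapolated` and returned as-is (a
low-sensitivity direction, possibly outside the valid coordinate range).
Subject averaging fits `t[s,d] = m[s]·consensus[d]` by alternating
geometric means (exact for complete coverage), normalizes multipliers to
geometric mean 1, reports the fraction of log-variance explained, and
refuses disconnected subject/direction coverage. Combined error bars are
the exponentiated RMS of per-subject log errors.

## Symmetries

Transformations are a geometry (identity, lrFlip, udFlip, and *clockwise*
rot90/rot180/rot270) composed with an affine gray-level map
`v ↦ a·v + b (mod G)`, `a` a unit. For `G = 3` the six affine maps realize
all of S₃, so exchanges and cycles of levels are exact; non-affine
permutations (possible for `G > 3`) are rejected with a clear error. The
induced coordinate action is computed exactly: the inverse geometry applied
to the stencil, re-canonicalized (translation + unit `u`), with
`h ↦ u·a⁻¹·(h − b·Σsᵢ) (mod G)`. This is verified bit-exactly against the
pixel-level oracle for all 36 combinations. `threshold_change` transports
threshold records through a transformation, pairing by exact direction
vectors, excluding fixed directions and unmatched pairs, and reporting the
log differences with counts.

## Evaluation

Mismatch is `log y − log x` (≈ relative error when small); the headline
statistic is the median absolute log error, symmetric in its arguments. The
permutation test shuffles measured thresholds across direction labels
(globally, or within planes — our reading of the ellipse-aware variant) and
recomputes the statistic; `p = (1 + #{null ≤ observed})/(1 + n_perm)` so p
is never zero, with the central 95% null range reported; default
`n_perm = 10000`. Ellipse fits are origin-centered least squares on
`A x² + B xy + C y² = 1` (predictions are origin-centered by construction);
non-elliptical best fits raise.

## Synthetic fixtures

Image surrogates are Gaussian random fields with power-law spectra
(`P(k) ∝ k^(−2)` by default, i.e. a 1/f amplitude spectrum), exponentiated
to lognormal intensities (`log σ = 0.9`). Scene diversity — the actual
driver of texture-space variance in natural scenes — is emulated by
per-image draws of contrast (lognormal, width 0.35), spectral slope
(normal, width 0.3) and correlation anisotropy (lognormal around 1.5:1
horizontal, width 0.25); the horizontal bias is planted deliberately so
predicted thresholds differ across planes and orientations and recovery
tests cannot pass vacuously. A fraction 0.25 of images is Gaussian-blurred
(σ = 3 raw pixels) with ground-truth labels. Defaults: 24 images of
512×512, chosen so the default pipeline yields 1536 patches — comfortably
more than the 66 fitted dimensions — while the whole chain runs in about a
minute.

What the fixtures do **not** emulate: occlusion and edge structure, the
heavy-tailed non-Gaussian statistics of real scenes, camera demosaicing
artifacts, and real observers' lapses and criterion drift. Passing the
recovery chain therefore shows that the *analysis machinery* is correct and
self-consistent (no systematic bias: |median log error| < 0.05 with
simulated observers whose true thresholds are the predictions), not that
natural images would yield any particular agreement with human data — that
comparison needs the external image database and subject thresholds.

Simulated observers are Weibull (shape 2.5 by default) probed at 3
contrasts geometrically spaced ±1.6× around the true threshold, 360 trials
per direction, 12 directions per plane — the standard session geometry.

## Known limitations

- Mixed-plane synthesis calibrates tilts by Monte Carlo, so axis targets are
  met to ~0.01 rather than machine precision, and extreme-but-feasible
  combinations near the boundary may be declared infeasible (conservative).
- Simple-plane angular geometry is implemented for `G ∈ {2, 3}`; group
  enumeration and analysis work for any `G ≥ 2`, but names and the
  dimension formula assume every nonzero coefficient generates `Z_G`
  (guaranteed only for prime `G`).
- The 4×4-block and larger-glider generalizations, adaptive staircases, and
  hierarchical observer models are out of scope.
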