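# Methods

This note documents the models, parameter choices and numerical decisions
behind the four pipelines, and what the synthetic fixtures do and do not
establish about real data.

## Image model and conventions

All processing is defined on single-plane 2-D images with 8-bit semantics.
Inputs deeper than 8 bits are linearly rescaled (image minimum → 0, dtype
maximum → 255) at read time, because every threshold method operates on a
256-bin histogram. Multi-page stacks are refused with an explicit message;
users split stacks first. Binary masks use 8-connected foreground and
4-connected background, the standard particle-analysis convention.

## Dichromacy filters

The enhanced DAB+ branch conditions color before deconvolution with
dichromat-vision simulations:

* **Deuteranope** (M-cone deficient): the published single-plane projection
  expressed directly in linear sRGB,
  `[[0.29031, 0.70969, 0], [0.29031, 0.70969, 0], [-0.02197, 0.02197, 1]]`.
  Its first two rows coincide, so red and green collapse to a shared
  luminance while blue is preserved; the matrix is algebraically idempotent
  and fixes the neutral axis exactly.
* **Tritanope** (S-cone deficient): a two-half-plane projection in the
  Hunt–Pointer–Estevez LMS space with 485 nm and 660 nm anchors; the
  half-plane is chosen by the pixel's L/M ratio relative to the white
  point, which makes the map continuous across the boundary. Projections
  leaving the sRGB cube are resolved by exact Euclidean projection onto the
  (confusion plane ∩ gamut) polygon. That map is nonexpansive, which is why
  the 8-bit transform stays idempotent to ±1 level even at the gamut
  boundary — hard clipping or ray desaturation would not.

Effect on the two stains: the deuteranope filter shrinks the hue-angle
spread between hematoxylin blue and DAB brown (supporting a single
"all cells" selection), while the tritanope filter re-expresses the pair as
a red-axis difference of ~46 gray levels that survives H&E-DAB
deconvolution. Note the tritanope image is *lower-contrast* for this pair
than the deuteranope image in raw L2 terms; its value is that the residual
difference aligns with the DAB deconvolution axis.

## Stain deconvolution

Beer–Lambert with a 3×3 unit-row stain matrix; concentrations are the OD
vector times the matrix inverse, clamped at ≥ 0, and each stain channel is
re-rendered as `round(255·10^-c)` (stain-dense pixels dark). For 8-bit
input, intensities are floored at 1 before the log; continuous (float)
synthesis uses a 1e-9 floor so the forward/inverse pair is exact, which the
round-trip tests exploit. Presets: `h_e_dab` (hematoxylin, eosin, DAB) and
`feulgen_light_green` (third vector = normalized cross product of the first
two). Channel routing defaults — total selection from the first
Feulgen-light-green channel, DAB+ selection from the third H&E-DAB
channel — are configurable.

## Auto-thresholding

Ten methods, the union of the per-pipeline method lists: Otsu, Huang, Li,
Yen, RenyiEntropy, MaxEntropy, Shanbhag, Moments, Triangle, Intermodes.
Criterion-based methods are implemented as global optimizers of their
published criteria over all candidate cuts with both classes non-empty;
ties break to the lowest index, compared with a 1e-9 relative tolerance so
float path noise over empty-bin plateaus cannot shift the winner. Two
deliberate definitional choices:

* **Li** is the global minimizer of Li & Tam's cross entropy rather than
  the common iterative local search (same criterion, no initialization
  dependence).
* **RenyiEntropy** maximizes the two-class Rényi entropy sum at α = 0.5; at
  α = 2 the criterion is algebraically identical to Yen's, so α = 0.5 keeps
  the ten methods distinct.

Triangle and Intermodes are procedural: Triangle maximizes the distance to
the peak→tail-end line on the longer-tail side; Intermodes smooths with a
3-bin mean (zero-padded ends) until exactly two strict local maxima remain
(cap 10,000 passes) and returns their midpoint. Both run on raw counts, not
the normalized histogram: their float tie-breaking is not invariant under
rescaling. Constant images raise an explicit error at the method level; at
the pipeline level they yield an empty selection.

Every method is tested against an independent loop-based brute-force
optimizer of its criterion on 100 random histograms (bimodal mixtures,
uniform noise, sparse spikes).

## Morphology, particles, foci

Binary cleanup applies in a fixed order — fill holes → watershed → edge
exclusion → size filter — each switchable per branch. The watershed seeds
markers at distance-transform maxima with 0.5 px prominence and cuts 1-px
divide lines. The size filter compares `pixels·scale²` against bounds in
physical units².

**Perimeter.** The crack boundary (pixel-edge polygon, 8-connected pinches
kept joined, holes included) is simplified by Douglas–Peucker at 1 px and
its length taken as the perimeter. Rationale: raw crack length is exact for
axis-aligned rectangles but overestimates smooth shapes by up to 8/2π
(a disc would score circularity π²/16 ≈ 0.62); simplification leaves
rectangle corners untouched (deviation > tolerance) while collapsing
staircases onto secants, so a radius-20 disc measures circularity ≈ 0.96
and converges toward 1 with radius. Circularity is clamped to [0, 1].

**Find-maxima.** Persistence pairing over 8-connected level sets, processed
in descending intensity with a union-find. A peak is emitted iff its
prominence (peak minus the level at which it merges into a higher region)
strictly exceeds the noise tolerance; the final surviving region is
measured against the image minimum, so a constant image yields zero maxima
and a tolerance above the global relief suppresses everything. Plateau
components merge their centroid pools at their own level and contribute a
single point.

**Foci assignment.** Nuclear = inside the nuclei mask; cytoplasmic = inside
cytoplasm and outside nuclei; total = nuclear + cytoplasmic when a
cytoplasm channel exists, otherwise all foci. Foci outside every mask are
reported in a separate `unassigned` column rather than silently folded in.

## Illumination correction

* **Rolling ball**: exact grayscale opening (closing for light backgrounds)
  by a spherical structuring element — no shrink/enlarge approximation.
  Light-background output is re-anchored at 255 so dark features on white
  keep their polarity. Default radius 50 px (40 px in the colony
  defaults, ~3× the largest colony radius in the fixtures).
* **Local contrast normalization**:
  `128 + (v − μ_local)·128/(s·σ_local)` over a (2r+1)² window via
  summed-area tables, defaults r = 40, s = 3. Two inherent caveats,
  shared with the reference construction: border windows are cropped, so
  corners of a smooth gradient map dark; and the gain 1/σ varies with local
  structure, so a featureless vignette is not flattened in absolute terms.
  What the colony pipeline actually needs — clean separability of colony
  pixels from non-border background — holds under a 60-level vignette, and
  the NLC route pairs naturally with edge exclusion to discard the border
  band.

Because an auto-threshold must always cut somewhere, each branch also
carries a `min_contrast` guard (default 8 levels on the robust 0.5–99.5
percentile range): a corrected-but-featureless field (e.g. an empty well)
selects nothing instead of thresholding noise.

## Pipelines and defaults

Per-branch parameters are independent (total vs DAB+, nuclei vs cytoplasm).
A batch run is frozen to one config; nothing adapts per image, and the
config is echoed into the run log. Failures skip-and-log; the CLI signals
partial failure through its exit code. Bright-field branches threshold
select-dark, fluorescence select-bright.

The shipped defaults were fixed with the pipelines' own optimization step
on synthetic test images and then left alone. The one non-obvious choice is
the enhanced-DAB selection branch: after the tritanope filter the DAB
channel carries three classes (background ≈ 250, hematoxylin-only cells
≈ 50–90, DAB+ cells ≈ 7–45), and every global auto method lands between
background and cells; the default is therefore a manual cut at 40 with no
blur on that branch, exactly as a user would freeze it from the montage.
Blur defaults elsewhere are σ = 1–2 px; size exclusion defaults are modest
(30–200 px² depending on pipeline) and meant to be re-optimized per cohort
and magnification along with everything else.

## Synthetic fixtures and their scope

The generators are deterministic per seed and emit ground truth consistent
with their own rendering (verified by re-measuring noise-free renders).

* **IHC fields** (default 512², 100 cells): non-overlapping ellipses
  rendered through the package's own stain matrices; positives carry DAB in
  addition to the hematoxylin counterstain. Per-cell concentrations are
  drawn from (0.7, 1.0) — a ±18 % spread modelling the consistent,
  well-optimized staining that batch quantification presupposes; heavily
  variable staining defeats any fixed-parameter method and is out of scope.
  The illumination ramp is multiplicative (calibrated to remove up to 20
  levels at white), as transmitted-light shading physically is; pixel noise
  is additive Gaussian (σ = 5 in the study conditions).
* **PLA triples** (default 448², 10 nuclei): bright nuclear ellipses inside
  dim cytoplasm ellipses; foci are σ = 2 px Gaussian spots of amplitude 200
  placed on jittered ellipse-coordinate rings, guaranteeing the requested
  counts with spacing that keeps maxima detection exact when noise-free.
* **Colony wells** (default 384²): discs (true circularity 1) and 7-point
  stars (analytically ≈ 0.3–0.5) at depth 60 below a 235 background, under
  a radial vignette whose 60-level amplitude makes corner background
  overlap colony intensities — the regime where shading correction is the
  difference between exact and wrong counts.
* **H&E fields**: pixel-exact construction — the tissue mask is the top
  `tissue_fraction` quantile of a smoothed random field and dense nests are
  exactly `round(dense_fraction · tissue_px)` pixels of a finer field, so
  truth ratios are exact by construction.

Passing on these fixtures validates the algorithmic chain — color
separation, thresholding, morphology, measurement, batch plumbing — under
known truth. It does not validate robustness to textured chromatin,
touching nuclei, out-of-focus light, or staining drift across a real
cohort; those are exactly what the per-cohort optimization step exists to
absorb, and they require real images to assess.

## Problem sizes

The validation suite and the acceptance script use 512² IHC fields
(20 images × 2 variants), one 448² PLA triple, 384² colony wells, and
100-histogram oracle sweeps per threshold method — sizes chosen so the full
cycle completes in a few minutes on a laptop-class single core while every
measured quantity remains comfortably inside its tolerance.
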