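# Methods

## 1. Diffusion-limited kill-fraction model

A cytotoxic γδ T cell secretes a small molecule (IFN-γ) that diffuses into
the surrounding tumour tissue and is removed by cellular uptake.  Treating
diffusion and uptake as quasi-steady relative to proliferation and death,
the interstitial concentration σ around one spherical T cell of radius
`R_T = d_T/2` obeys the screened diffusion balance

    D ∇²σ = λ σ ,       L = √(D/λ),

with `D` the interstitial diffusivity, `λ` the uptake rate, and `L` the
*diffusion penetration distance* — the length scale over which uptake
depletes the cytotoxin.  The decaying spherically symmetric solution with
membrane value σ_T is

    σ(r)/σ_T = (R_T/r) · exp(−(r − R_T)/L).

Each T cell serves the `1/ρ` tumour cells sharing its *interaction sphere*,
where ρ is the T-cell : tumour-cell number ratio.  The interaction radius
follows from a volume balance with the tumour-cell radius `R_C = d_C/2`:

    R(ρ)³ = R_T³ + R_C³/ρ,     R → R_T as ρ → ∞.

The predicted kill fraction is the uniform-exposure maximum `f_max` scaled
by the volume average of σ/σ_T over the interaction sphere.  The radial
integral `∫ r·e^{−(r−R_T)/L} dr` is elementary, so the model is fully
closed-form; the implementation evaluates the exponential bracket with
`expm1` so thin shells (large ρ) do not lose precision, and the shell
volume `R³ − R_T³ = R_C³/ρ` is used in that exact form.  The model is
scale-free in length: measuring all lengths in units of L changes nothing,
which a test asserts directly.

### Normalisation conventions

What counts as "the volume" is exposed as a flag because the averaging
volume admits more than one physically defensible choice:

* **`shell`** (default) — average over the tumour-occupied shell
  `R_T ≤ r ≤ R`, normalised by the shell volume.  Tumour cells live only in
  the shell, and `f → f_max` as ρ → ∞.  All defaults use this.
* **`include-core`** — credit the T-cell core as fully exposed and
  normalise by the whole sphere.  Same ρ → ∞ limit.
* **`sphere`** — shell integral normalised by the whole sphere volume with
  no core credit.  This convention vanishes as ρ → ∞ (unphysical in that
  limit) but is the only one of the three whose attainable curve *shapes*
  can pass exactly through the published in-vivo dose–response pair
  (ρ ≈ 0.067, f = 0.221) and (ρ = 15, f = 0.484): under `shell` the ratio
  f(ρ₁)/f(ρ₂) of any model curve is bounded above by ≈ 0.284 (attained as
  L → ∞), and under `include-core` by ≈ 0.271, both short of the observed
  0.457.  The `sphere` shape family reaches 0.616 and interpolates the pair
  at L ≈ 13.7 µm — the same order as the published in-vivo penetration
  lengths — at the cost of an interpolating amplitude slightly above 1.
  It is retained as a documented reconstruction of the published curve
  fits, not as the physical default.

Every convention is validated against adaptive quadrature of its own
volume integral (rel. error ≤ 1e−8 over 200 random parameter draws;
observed ≈ 1e−13), and the concentration profile against a
finite-difference solution of the radial boundary-value problem with a
decaying far field (≤ 1e−4 on `r ∈ [R_T, R_T + 5L]`).

### Fitting

`fit_kill_model` minimises squared residuals over `(f_max ∈ [0,1], L > 0)`
with `d_T`, `d_C` fixed, using bounded trust-region least squares
multi-started from `L ∈ {1, 10, 100, 1000}` µm (`f_max` starts at 0.5) —
the objective is nearly flat in L for saturating designs, and multi-start
avoids the resulting local minima.  `R² = 1 − SS_res/SS_tot`.  The p-value
for L is a two-sided t test of `L̂/SE(L̂)` with the standard error from the
Gauss–Newton covariance `σ̂²(JᵀJ)⁻¹` at `n − 2` degrees of freedom; it is
NaN for exactly identified (two-point) fits.

With exactly two distinct points the model either interpolates exactly or
not at all, so the amplitude is cancelled from the ratio of the two model
values and the remaining scalar equation in L is solved by bracketing plus
Brent iteration (`fit_two_point_exact`; residuals at machine precision).
The amplitude cap defaults to ∞ there: when the shape under-predicts the
more saturated point the interpolating amplitude exceeds 1 and is then an
effective scale, not a fraction.

L can also be projected from a reference compound
(`penetration_from_reference`): `L = √(D/λ)` with diffusivity scaled by
molecular weight to a configurable exponent (default 1/3, Stokes–Einstein
radius scaling), i.e. `L_t = L_r · √((λ_r/λ_t)(M_r/M_t)^{1/3})`.

### Identifiability and the synthetic dose–response design

L enters the curve only through radii comparable to L.  With tumour-cell
diameters of a few µm and L of tens of µm, ratios ρ ≳ 0.5 produce
interaction radii ≪ L and carry almost no information about L: at
measurement noise s.d. 0.02 an 8-point design over ρ ∈ [0.5, 30] yields
median L errors near 40 % for any fitter.  The default synthetic design
therefore spans the diffusion-limited regime: 10 ratios log-spaced over
[0.005, 30], three replicates each (matching the triplicate design of the
motivating experiments), true parameters `f_max = 0.9`, `L = 20 µm`, noise
s.d. 0.02.  Under these conditions the median relative recovery error of
both parameters stays under 15 % (typically 8–14 % for L, < 1 % for
`f_max`).

## 2. Xenograft bookkeeping

Three arithmetic links, each trivial but each an explicit, testable
assumption:

* mass → count: `N = m · c` with `c = 1e9 cells/g` by default.  The
  default reproduces 0.285 g ↔ 285 million cells exactly (1 ng per cell);
  note it is *not* consistent with a 7 µm water-density cell (≈ 0.18 ng),
  which is why `cells_per_gram` is a parameter rather than a constant.
* exponential growth between two anchors:
  `N(t) = N₀ (N_T/N₀)^{t/T}` — monotone and composable.
* tail-vein ratio: injected T cells distribute body-wide in proportion to
  mass, so only the tumour's mass fraction reaches the tumour:
  `ρ = N_T-cells · (m_tumour/m_body) / N_tumour-cells`.  For the default
  scenario (100 M cells, 0.285 g / 25 g, ≈ 17 M tumour cells) this gives
  ρ ≈ 0.067.

Counts are kept as real numbers; rounding to "ca." millions (half-up) is
presentation only.

## 3. CC3 apoptosis quantification

Input: 8-bit sRGB brightfield tiles of DAB/haematoxylin (CC3) stained
tissue with three pixel classes — near-white background, blue nuclei,
brown apoptotic regions.

1. **Colour space.** sRGB → CIEXYZ (D65) → CIE 1976 L\*a\*b\*
   (scikit-image; cross-checked in tests against an independent
   implementation of the standard formulas).
2. **Initial clustering.** k-means, k = 3, on per-pixel (L\*, a\*, b\*)
   with k-means++ seeding under a fixed seed (runs are bit-reproducible).
   Centroid-based labelling: the *background* cluster is the one with the
   smallest chroma √(a\*² + b\*²) — both stains carry chroma while the
   background is near-achromatic; of the remaining two, the higher-b\*
   centroid is brown.  Lightness is deliberately not used for the
   background rule: the class lightness means this pipeline is designed
   around (105/120/124 for blue/white/brown on the 8-bit scale) put brown
   *above* white, so a max-lightness rule would mislabel even perfectly
   separated classes.
3. **PCA projection.** Pixels form an N×3 matrix; after mean-centring they
   are rotated onto the eigenvectors of the 3×3 sample covariance, ordered
   by descending eigenvalue.  Channel 1 tracks overall stain/lightness
   contrast; channel 2 carries the blue-vs-brown contrast; channel 3 is
   noise and is ignored.  Eigenvector signs are fixed deterministically
   (channel 1 along +L\*; channel 2 so brown-candidate pixels score above
   blue-candidate ones, with +b\* as fallback; channel 3 along +a\*).
   Decorrelation (off-diagonal ≤ 1e−8 of total variance) and variance
   conservation are asserted.
4. **Entropy-threshold refinement.** The initial brown class usually
   over-segments — it contains genuinely brown pixels plus bluish nuclei
   whose shade confused the 3-D clustering.  Its channel-2 values are
   linearly rescaled to 8-bit levels and split at the maximum-entropy
   (Kapur) threshold: the level t maximising the sum of Shannon entropies
   of the renormalised distributions ≤ t and > t (natural log, 0·log 0 = 0,
   empty-sided splits excluded, ties to the lowest t; verified equal to
   exhaustive search).  The lower-mean side is reassigned to blue.
   A *bimodality guard* applies the split only when Ashman's
   D = |μ₁ − μ₂|/√((s₁² + s₂²)/2) between the two sides reaches 3: the
   maximum-entropy threshold of a unimodal class falls near its centre
   (D ≈ 2.7 for a Gaussian), so an uncontaminated brown class would
   otherwise lose about half its pixels; genuinely two-component classes
   give D ≳ 3.6.
5. **Morphology.** Holes smaller than 64 px are filled and 8-connected
   components smaller than 64 px removed (idempotent; both sizes are
   configuration).  This also clears the sparse noise-tail pixels that
   survive the entropy split.
6. **Index.** `AI = 100 · Br/(Area − W)` — brown as a percentage of
   non-background tissue (the only reading in which the white count plays
   a role); `100 · Br/Area` is selectable.  Masks partition the image
   exactly at every stage.

## 4. Synthetic CC3 tiles

`gen_histology` paints non-overlapping ellipses (rejection placement) on a
uniform background in CIELAB, adds i.i.d. Gaussian pixel noise, and
converts to 8-bit sRGB; ground-truth masks are exact by construction.
Class lightness means default to 105/120/124 (8-bit scale) and the
blue-vs-brown b\* separation to 10 — the published statistics of real CC3
tiles, under which lightness alone cannot separate the classes.  The
misclassification regime is produced by *shade variability*: each nucleus
is drawn from one of two hue modes, pure blue or partially-DAB
"brownish blue" (default 45 % of nuclei, displaced (Δa\*, Δb\*) = (1, 4.5)
toward brown, with the class mean chroma preserved).  Brownish nuclei are
close enough to brown in 3-D colour that k-means merges them into the
brown cluster (initial contamination well above 5 %) while remaining
separable along the PCA hue axis, so the entropy refinement recovers them.
This follows the mechanism the pipeline was designed against — high
variability in the shades of blue and brown — rather than pixel-noise
overlap, which would be statistically irreparable downstream.

What the generator does **not** emulate: scanner optics and focus
blur, anti-aliased object boundaries, slide-thickness and stain-batch
variation within one tile, textured chromatin, touching/overlapping
nuclei, and realistic apoptotic-area fractions (default tiles carry
~15–20 % brown-of-tissue so segmentation metrics are stable; real CC3
indices in this setting are 1–4 %).  Passing the end-to-end criteria
(brown-mask Dice ≥ 0.95, index within 0.5 points) therefore demonstrates
correctness of the algorithm chain in its intended regime, not
performance on real slides.

## 5. Numerical and design notes

* Degenerate inputs raise typed errors: ρ ≤ 0 (the per-T-cell geometry is
  undefined without a T cell), constant images, single-bin histograms,
  all-background images (undefined index), < 2 fit points, identical ρ.
* The dose-response generator clips noisy kill fractions to [0, 1].
* Kapur ties break to the lowest level within 1e−12 of the maximum, making
  the vectorised implementation agree exactly with brute force.
* Default problem sizes: 256×256 tiles, ~110 nuclei + 14 apoptotic blobs;
  200 quadrature draws; 50 fit replicates; 1000 threshold histograms.
* Batch quantification logs and skips failing tiles instead of aborting;
  every CLI run writes a `run_record.json` with the effective parameters
  and seed, making outputs exactly reproducible.

## 6. Known limitations

* Single-source concentration field only: the scarce-T-cell assumption
  ignores overlapping diffusion fields, so the high-ρ regime (ρ ≈ 30) is
  explicitly outside the model.
* No convection, no time dependence beyond the quasi-steady balance.
* The published in-vivo curve fits are reconstructable only up to the
  normalisation ambiguity discussed in §1; the in-vitro dataset exists
  only as plotted points and is not reproducible from printed inputs.
* The segmentation carries no stain-vector deconvolution and no nucleus
  instance counting; the apoptotic index is a pixel-area measure.
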