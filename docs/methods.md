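# Methods

## The mixing model and FCLS

A map scan is the matrix `D` of shape `(x·y) × L`: one spectrum of `L` bands
(Raman shift 580–3062 cm⁻¹) per spatial pixel.  With `Pᵀ` the `k × L` matrix
of pure-component reference spectra, the linear mixing model is
`D = C Pᵀ + R`.  Each foreground pixel's abundance row is estimated by fully
constrained least squares: minimize `‖d − Pᵀc‖²` subject to `Σc = 1` and
`c ≥ 0`.

The solver is the classic active-set scheme: start from the sum-to-one
constrained least-squares solution (a single Lagrange multiplier on the
normal equations), clamp the most negative abundance to zero, re-solve on
the free set, and release any clamped component whose KKT multiplier turns
negative.  For `k ≤ 4` this converges in a handful of iterations; the tests
verify agreement with an independent SLSQP quadratic-programming solve to
≤ 1e-6 on random instances, and a dense simplex-grid search to ≤ 2e-3 on
`k = 3` mixes.  Rank-deficient reference sets trigger a warning and a
minimum-norm compromise rather than an exception.

**Normalization for unmixing.**  Reference rows are stored max-normalized
to [0, 1].  When `unmix_map` adjusts data into [0, 1] it applies a *single
global scale* to the cube (computed over foreground pixels only) and a
single global scale to the reference matrix, rather than per-row maxima.
The reason is structural: if a mixed pixel `d = Σ cⱼ pⱼ` is divided by its
own maximum, the exact coefficients of the rescaled pixel no longer sum to
one, so the sum-to-one constraint forces a biased compromise.  A shared
scalar preserves the mixing relation exactly.  (The per-row `max_normalize`
operation is still provided for spectra and reference sets, where each row
is an independent acquisition.)  Masked background pixels are excluded from
the scale because they are never despiked and may retain cosmic spikes.

**Calibration.**  Abundance fractions are converted to concentrations
(% dry base) by `C_cal = C × W`, with `W` the wet-chemistry total content of
the k components (defaults 77.2 untreated / 53.4 alkali-treated rice straw).
Every calibrated row sums to `W` by construction.

**Residuals.**  The per-pixel residual norm `‖d − Pᵀc‖` is retained;
pixels above a configurable quantile (default 99th) are *flagged* as
unmixing failures, never dropped.

## Noise-reduction chain

Order: segmentation → despike → PCA denoise → airPLS.

* **Segmentation** thresholds a per-pixel score (mean intensity over a
  configurable band window, default the full axis).  Otsu's criterion is
  the default; quantile and manual thresholds are available.  Degenerate
  outcomes (all pixels on one side) warn and fall back to all-foreground.
  Note that a hypothetical tissue with *no* fluorescence and sparse sharp
  peaks can score as low as resin; in practice plant tissue fluoresces and
  separates cleanly.
* **Despiking** flags bands whose modified z-score against a running median
  (0.6745·residual/MAD, window 7) exceeds `z = 8` *and* whose residual
  rises above half the local median level.  The second guard matters on
  clean data: a noiseless smooth peak's curvature towers over a near-zero
  global MAD, and without the guard the despiker would clip real peaks.
  Cosmic rays are several-fold brighter than their surroundings and always
  pass it.  The operation is idempotent.
* **PCA denoising** reconstructs spectra from the leading principal
  components — the smaller of (components reaching 99.99% cumulative
  variance, 3).  Foreground pixels of a k=3 scene live on a ~3-dimensional
  affine manifold (two simplex degrees of freedom plus one fluorescence
  amplitude), so three components capture essentially everything but noise.
* **airPLS** solves the iteratively reweighted Whittaker system
  `z = argmin Σ wᵢ(yᵢ−zᵢ)² + λ Σ(Δ²z)²` with weights zero where `y ≥ z` and
  `exp(t·|dᵢ|/|d|)` on the negative part `d` of the residual, terminating
  when `|d|₁ < 0.001·|y|₁` or after 15 iterations (λ = 1e5 on the ~1000-band
  axis).  Non-convergence returns the best iterate with `converged=False`.
  The baseline is equivariant to constant shifts (the second-difference
  penalty annihilates constants).

**Why denoise before baseline correction.**  airPLS zero-weights positive
residuals, so on a *noisy* spectrum its baseline tracks the lower envelope
of the noise and the corrected signal keeps a broadband positive offset of
roughly the noise amplitude.  Downstream, that offset is cheapest to absorb
by the weakest-amplitude reference (hemicellulose), biasing its abundance
by an order of magnitude more than the offset itself.  Running PCA
denoising first makes the spectra essentially noise-free, after which the
baseline estimate is clean.  This is the one place the pipeline order is
opinionated; both stages remain independently callable.

**Matching references.**  When a map has been baseline-corrected, the
references must be corrected the same way (`preprocess_references`), or the
fluorescence-dominated hemicellulose reference no longer resembles any
pixel and its abundance collapses to zero.  The CLI does this automatically
by reading the map's provenance metadata.

**Normalizations.**  Area normalization divides each band by the band sum
(negatives clipped to zero first so the intensity mass stays well-defined);
it is idempotent and the output sums to one.  Max normalization divides
each row by its maximum.

## Wavelet features

`decompose_branches` runs a level-8 DWT (default family `db4`: orthogonal,
compact support, standard for spectra; symmetric boundary padding,
reconstruction truncated to the input length) and reconstructs each of the
nine coefficient sets separately.  The branches are an additive
decomposition: they sum back to the input to ≤ 1e-8 relative error, and the
transform is linear.  On the default axis (~2.45 cm⁻¹ per band) the D6
branch passes structure of roughly 2⁶ bands per oscillation — the width
scale of Raman peaks — which is why it retains chemistry while rejecting
both noise and the fluorescence ramp.  The level-8 precondition is
`L ≥ 256`; shorter spectra get an error naming the maximum feasible level.
The family and level are recorded in output metadata.

Branch extraction is applied after any despiking/baseline work the caller
chooses; the default classification grid feeds it the spectra as given
(see below).

## Classification grid

`run_feature_grid` crosses algorithms (LDA, KNN) × input signals (raw or
one wavelet branch) × band sets (full range, or explicit wavenumbers such
as 1620 + 1089 cm⁻¹) over a single stratified 3:1 train/prediction split
shared by all cells, and reports train and test accuracy separately
(both are kept because the two can diverge and the grid's consumer should
see which is which).  LDA uses Ledoit–Wolf shrinkage of the within-class
scatter (full-range spectra are strongly collinear); KNN uses Euclidean
distance with k = 5 — an odd k cannot tie in a two-class vote.

The grid default does **not** area-normalize: dividing
fluorescence-dominated spectra by their total area injects the highly
variable background magnitude into every band and measurably destroys the
two-band fingerprint.  Area normalization exists to correct optical-path
differences; enable it with `normalize=True` when that is the dominant
nuisance.

PCA clustering uses mean-centered SVD with a deterministic sign convention
(largest-magnitude loading positive).  Loading-weight band analysis selects
axis points where |loading| > 0.025 on PC1/PC2, merges contiguous runs, and
reports each run by its apex wavenumber.

## Synthetic data

The generator emulates what matters to this pipeline, not Raman physics:

* **Component models** — Gaussian peaks at standard lignocellulose band
  positions: cellulose 1089/1121/1376/2895 cm⁻¹ with negligible
  fluorescence; lignin 1508/1620/1660/2940 cm⁻¹ over a moderate background;
  hemicellulose (xylan-like) weak 1089/1739/2930 cm⁻¹ features under a
  strong background.  Component fluorescence is a power-law ramp rising
  with wavenumber; each reference row is max-normalized.
* **Scenes** — `cube = abundance @ references + nuisance` on a
  580–3062 cm⁻¹ axis with L = 1015 (~2.45 cm⁻¹ steps; the acquisition range
  is standard, the sampling density an implementation choice).  Layouts:
  `tiles` (pure-component and mixed cell-type blocks plus resin background),
  `cells` (an idealized transection: resin border, lignin-rich epidermis
  ring, parenchyma ground tissue, round vascular bundles with sclerenchyma
  sheaths and xylem cores), `random-simplex` (Dirichlet rows).  Cell-type
  abundance priors give epidermis 60% lignin, parenchyma 50% hemicellulose,
  xylem/sclerenchyma cellulose+lignin rich; per-pixel Dirichlet jitter
  (concentration 300) adds within-tissue texture.  Foreground truth rows lie
  exactly on the simplex; background is flat resin-like signal (0.02).
* **Nuisance** — a shared logistic fluorescence ramp with per-pixel
  amplitude randomized ±20% (`baseline_scale` 1.0 ≈ peak maxima by
  default), Gaussian noise (`gaussian_sd`, default 1–2% of the normalized
  peak scale), and Poisson-placed cosmic spikes 1–2 bands wide at 5–20×
  the local signal.  All randomness flows through one seeded generator.
* **Spot datasets** — untreated composition follows the dry-base
  wet-chemistry ratios 39.5 : 33.2 : 4.5 (cellulose : hemicellulose :
  lignin); the treated class multiplies weights by the measured retention
  factors 0.87 / 0.47 / 0.75 and renormalizes.  Within-class composition
  jitter is log-normal with sd 4.5% — the mean relative sd of the
  wet-chemistry measurements; each spot sample averages many raw spectra,
  so spreads are modest.  Because spot scans cover nine tissue types with
  very different chromophore content, each spot draws its own fluorescence
  amplitude (log-normal, σ = 0.5) *and* ramp shape.  This spot-to-spot
  background heterogeneity is what degrades raw-spectrum classifiers while
  leaving mid-level wavelet branches nearly untouched — the pattern the
  classification grid reproduces.

**What the generator does not model** — and hence what passing tests do not
establish about real data: instrument response and wavelength-dependent
sensitivity, peak shape asymmetry and treatment-induced band broadening or
shifting, nonlinear mixing (self-absorption, multiple scattering),
spatially correlated noise, and fluorescence whose spectral shape correlates
with composition in more complex ways than the shared ramp.  Recovery
errors measured here are best-case figures for data obeying the linear
mixing model.

## Numerical choices and degenerate inputs

* Band lookup is by wavenumber with nearest-point resolution; exact ties go
  to the lower wavenumber.
* FCLS tolerances: constraint satisfaction 1e-9 (tested), active-set
  clamping tolerance 1e-10, iteration cap 200.
* airPLS endpoints are anchored by the maximum weight so the baseline
  cannot drift free at the boundaries.
* `fcls` with `k = 1` returns [1.0] (forced by the sum constraint)
  regardless of fit quality; all-background maps unmix vacuously; all-zero
  spectra are rejected by area normalization with the offending pixel named.
* Problem sizes in the test and acceptance runs — 40×50 scenes, 24×24 tile
  scenes, 574-spectrum spot datasets, 200 oracle instances at L = 1015 —
  are chosen so the full suite completes in well under a minute of compute
  per heavy test while leaving every statistical margin wide.

## Known limitations

* Abundances are relative to the supplied references; no endmember
  extraction is attempted, and a missing constituent biases the others
  upward (sum-to-one).
* airPLS is quasi-linear, not linear: baseline(mixture) differs slightly
  from the mixture of baselines, which contributes ~1e-3 absolute abundance
  error on clean data.
* The despiker's local-median guard can miss a cosmic ray that lands
  exactly on a strong peak apex; such pixels are caught downstream by the
  residual-norm flagging.
* Tissue with genuinely negligible fluorescence can be misclassified as
  background by mean-intensity segmentation; use a band-window score or a
  manual threshold there.
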