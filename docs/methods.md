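# Methods

`sparsespect` is a simulation and evaluation pipeline for sparse-view
⁹⁹ᵐTc-PSMA SPECT of the pelvis.  It answers one question end to end: how
much diagnostic image quality is lost when the number of angular views in
a 360° acquisition is cut from 60 to 30, 15 or 10, and how much of that
loss a post-reconstruction filter (Gaussian vs nonlocal means) recovers.
This note documents the models, their assumptions, the tunable parameters,
and what the synthetic experiments do and do not show.

## Emission model and projector

Measured projection counts are modelled as independent Poisson variables
with means p = A x, where x ≥ 0 is the per-voxel emission rate and
a_ij is the sensitivity of detector bin i to voxel j.  The system matrix
is a 2D parallel-beam projector applied independently per transaxial
slice: a_ij is the exact intersection length (mm) of ray i with pixel j,
computed by parametric (Siddon-style) grid traversal and materialised as a
`scipy.sparse` CSR matrix.  Back projection is the literal matrix
transpose, so ⟨Ax, y⟩ = ⟨x, Aᵀy⟩ holds to machine precision — the
multiplicative OSEM update depends on this pairing being exact.

Conventions (the physical protocol leaves these open, so they are fixed
here once): rotation counterclockwise with angle 0 along +x; detector
axis t = (cos θ, sin θ), ray direction (−sin θ, cos θ); detector bins at
voxel pitch, n_bins = nx.  Attenuation, scatter, collimator-detector
response and depth-dependent resolution are deliberately not modelled:
the study's comparisons are all relative to a reference reconstruction
made with the same projector, so these physics terms would cancel to
first order while making the dense-matrix oracle intractable.

**Count calibration.**  The clinical protocol fixes time per view
(~17.5–20 s) but not counts.  Expected sinograms are therefore scaled so
the full 60-view scan totals a configurable budget, default 2×10⁶ counts
— a moderate-count SPECT regime (≈30 counts per bin on the default
grid) chosen once so the Poisson noise level is explicit and tunable.
Decimation keeps every k-th view starting at index 0 with per-view counts
untouched, so total counts scale linearly with views (30 views at 12°
steps, 15 at 24°, 10 at 36°).

## Reconstruction

Ordered-subsets expectation maximization maximises the Poisson
log-likelihood ℓ(x) = Σᵢ (yᵢ ln p̂ᵢ − p̂ᵢ) subject to x ≥ 0:

    x_j ← x_j · [Σ_{i∈S_b} a_ij y_i / p̂_i] / [Σ_{i∈S_b} a_ij]

cycling subsets S₁…S_B within each iteration; B = 1 is MLEM.  The shipped
default protocol is 9 iterations × 5 subsets.  Choices the protocol does
not specify, fixed here for determinism:

* **Subset assignment** — view k joins subset k mod B, so each subset's
  angles are maximally interleaved around the circle; subsets are visited
  in natural order.
* **Initialisation** — uniform ones on voxels with positive full-scan
  sensitivity, zero elsewhere (zeros are fixed points of the
  multiplicative update and no data can revive them).
* **Guards** — p̂ is clamped at ε = 1e-12 only where y > 0 (y = 0 terms
  vanish identically); voxels with zero subset sensitivity skip that
  subset's update.  No relaxation, resolution modelling or post-scaling.
* **Dimensionality** — reconstruction is slice-wise 2D, matching the
  slice-independent projector.

Numerically verified properties: non-negative iterates; after each subset
update, Σ_j s_j^b x_j = Σ_{i∈S_b} y_i (count conservation); MLEM
likelihood monotonicity; invariance to view order within a subset; a
uniform phantom's noiseless data reconstructs to a uniform image.

## Post-reconstruction filters

**Gaussian** — convolution with a unit-sum isotropic kernel,
σ = FWHM/2.3548, default FWHM 2 voxels, mirror boundaries.

**Nonlocal means** — each voxel becomes a normalised weighted average over
a search window (default radius 3, i.e. 7³), with weights
w(j,i) ∝ exp(−d²(j,i)/h²) where d² is the squared patch difference
(patch radius 1, 3³) weighted by a unit-sum Gaussian patch kernel of
spread α = 1 voxel.  The self term i = j is included uncapped.  Windows
are 3D by default; a slice-wise 2D option exists.  Because the patch
kernel is normalised, d² is a per-voxel weighted mean squared difference
and h is directly comparable to the image noise SD.

**Bandwidth default.**  The noise SD σ is estimated robustly as
1.4826·MAD of the discrete Laplacian (coefficient-norm corrected),
restricted to body voxels (> 2% of the maximum) because the empty
background of an emission volume is noise-free and would collapse the
median.  For two noisy realisations of the same underlying patch the
expected distance is E d² = 2σ², so the weight formula with no noise
offset makes h a sharp similarity threshold: with N ≈ 342 search
neighbours, the aggregate neighbour weight balances the self weight when
N·e^(−2σ²/h²) ≈ 1, i.e. h ≈ 0.6σ.  Smaller h degenerates toward the
identity; much larger h approaches a box average that erodes edges.  The
default is h = 0.7σ, which a bandwidth scan on seeded replicates confirms
sits in the flat optimum (0.6–0.8σ) of reconstruction NRMSE.

## Evaluation metrics

All comparisons use the unfiltered 60-view OSEM reconstruction of the
same noise realisation as the reference.  Definitions follow the study's
metric suite literally, including two non-standard conventions that are
kept as the contract (with conventional variants behind flags):

* **NRMSE** is the ratio of sums Σ(x_red − x_ref)²/Σ(x_ref − μ)² with
  *no square root* by default (`sqrt=True` for the rooted variant).
* **PSNR** is 10·log₁₀(max(x_reduced)²/Σ(x_red − x_ref)²): the peak is
  taken over the *reduced* image and the error term is the total, not
  mean, squared norm (`standard=True` for the textbook form).  Its value
  is therefore scale- and size-dependent; only relative changes are
  comparable across datasets.
* **NB** uses the population variance (divide by N) of the reference ROI.
* **ICC** is (MSB − MSE)/(MSB + (K−1)·MSE) from a one-way subjects ANOVA
  (between df n−1, within df n(K−1)); each rated image is one subject.

"Improvement" is reported under two labelled definitions, matching how
such studies summarise results: the maximum |percent change| per metric
between filter conditions (used for NRMSE/PSNR/NB), and the maximum raw
percentage-point reduction (used for MAPE).

ROI masks are taken from the generating ellipsoids (ground truth), not
drawn on reconstructions: manual ROI placement is not reproducible, and
ground-truth masks make every metric deterministic given the seed.

## Synthetic phantom

Patient data is not available, so the generator builds additive
constant-activity ellipsoids on a voxel grid (origin at the grid centre,
membership at voxel centres): background 1.0, prostate lesion 8.0
(ROI1), two renal cortices 6.0 (ROI2), bladder 10.0 (excluded from both
ROIs).  This reproduces the qualitative ⁹⁹ᵐTc-PSMA contrast ordering;
the clinical study reports no organ sizes or uptake ratios, so these
values are package defaults, configurable via YAML.  The default grid is
a desk-scale 64×64×16 at 4.43 mm voxels; the clinical 128³ matrix is
supported through configuration.

"Cases" in the pipeline are seeded Poisson noise replicates of one
phantom: the reduced-view sinograms are decimations of the same
realisation (exactly the clinical decimation protocol), which isolates
the angular-sampling effect from anatomical variation.

**What passing tests do and do not show.**  The synthetic study
reproduces the mechanism-level findings: reconstruction error grows as
views drop (severely at 10 views, consistent with angular-Nyquist
fold-over), and NLM beats both no filtering and Gaussian filtering on
NRMSE in nearly all replicates at 30 views while preserving ROI means
far better than the Gaussian.  It does not reproduce patient-level
numbers: real lesions vary in size, uptake and heterogeneity, and real
acquisitions include attenuation, scatter and collimator blur.  One
visible artefact of the simplification is that the small synthetic
lesion loses ROI mean under any smoothing (partial-volume effect), so
filtered MAPE does not improve over unfiltered MAPE here the way it does
in the patient tables.  The published per-patient tables ship as
fixtures, and every study-level aggregate (mean MAPE, maximum
improvements under both definitions) is recomputed from them by the same
aggregation code the pipeline uses.

## Problem sizes and determinism

Default experiments run 10 replicates on the 64×64×16 grid — about 40 s
on one CPU core, with the full test suite near half a minute.  All
randomness flows through `numpy` Generators seeded from the run seed via
`SeedSequence((seed, case))`; identical configurations are
bit-reproducible.  Degenerate inputs are handled explicitly: empty ROI
masks, constant reference images (NRMSE undefined), identical image
pairs (infinite-PSNR condition raised, reported as `inf` by the
pipeline), zero-variance ROIs, zero-mean Poisson bins, incomplete rater
layouts, and search radius 0 (NLM warns and returns the identity).

## Known limitations

* No attenuation, scatter or resolution modelling; absolute metric
  values are not comparable to clinical reconstructions (PSNR especially,
  being scale-dependent).
* The projector is 2D parallel-beam; fully-3D system models and
  fan/cone geometries are out of scope.
* NLM is a denoiser, not an anti-aliasing method: at 15 and 10 views it
  cannot remove angular undersampling streaks and may sharpen their
  boundaries; the pipeline flags 10-view results as not recommended.
* The ICC operation is validated on constructed tables; the bundled
  reader-score fixture has identical rater columns and yields ICC = 1 by
  construction.
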