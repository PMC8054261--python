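# Methods

This note documents the models, the synthetic-data generators, the
numerical choices and the known limitations of `ecmscreen`.

## Growth model and fitting

Live-cell counts are modeled as N(t) = N₀·e^(rt) with r the specific
growth rate (per hour; unconstrained in sign, since cytotoxic doses can
shrink a population). Fitting minimizes the **unweighted** residual sum
of squares on raw counts by Levenberg–Marquardt (lmfit's `leastsq`
backend), initialized at N₀ = first count (floor 1) and r = the OLS slope
of ln(max(count, 1)) against time. Convergence requires optimizer success
*and* no RSS increase relative to the initialization; tolerance 1e-8 on
relative parameter change, at most 500 iterations — artifact choices, not
empirical constants.

Because the counting noise is multiplicative, unweighted least squares is
increasingly heteroscedastic over long horizons. The rate estimate stays
essentially unbiased (< 0.5% at 5% CV over 0–72 h in the test suite), but
the covariance-based standard error is calibrated only when the count
range is modest (within ~25% over 0–36 h at 5% CV; it understates the
spread over 0–72 h). A log-space OLS fallback (`fit_exponential_log`)
handles curves containing zeros.

## IC₅₀ by log-linear interpolation

Relative rate = treated r / untreated r of the same condition and
replicate. Positive doses are scanned in increasing order for the first
adjacent pair bracketing 0.5 and log₁₀(IC₅₀) is linearly interpolated
between them; an exact 0.5 hit returns that dose. Dose 0 cannot sit on a
log axis, so it serves only as the normalization anchor. Curves that
never reach 0.5 are censored `above_max`; curves already below 0.5 at the
lowest positive dose are censored `below_min`; negative relative rates
participate unchanged. On a 3-fold dilution ladder with Hill slope 1 the
interpolation bias is below 15% of the true IC₅₀ (checked by direct
evaluation), and it vanishes when the IC₅₀ is the geometric mean of a
symmetric bracket. Replicates can be handled per-replicate (default, so
downstream models see per-experiment IC₅₀s) or by averaging curves before
interpolation.

## Disc segmentation

Core texture detection: local **population** standard deviation in an odd
window (population rather than n−1 is the convention of image STD
filters; after thresholding the choice is immaterial), reflection border
handling, followed by a median filter and a threshold. Default texture
input is the raw image; an illumination-corrected mode (image − profile)
is available. Candidate pixels are those deviating from the empty-well
light profile by more than a threshold. Refinement: union with
candidates, dilation by a disk, binary morphological reconstruction with
the texture core as marker (removing structure not connected to the
core), hole filling, erosion by the same disk (undoing the dilation
bias), largest connected component. Reconstruction is binary rather than
grayscale for determinism and testability. An empty core yields an empty
mask flagged `no_disc`, never an exception.

Defaults (SD kernel 5, median 3, texture threshold 60, candidate
threshold 120, disk radius 7 at 20 μm/px) were chosen so the SD window's
boundary halo — inflated by the intensity step at the disc edge — stays
narrow; they give median IoU ≈ 0.95 against ground truth on the default
synthetic scenes.

The sweep scores each candidate mask S = |area − expected|/expected +
w·(1 − circularity), with circularity 4π·area/perimeter² (Crofton
perimeter, clipped at 1, since raster perimeters of small discs
overestimate). Expected area comes from the known 6 mm disc diameter and
the pixel size. Lowest S wins; ties break to the earlier grid entry; the
full ranking is returned so a human can override the automatic choice.

## Registration

A centroid is on-disc iff the mask pixel at its round-half-up (x→column,
y→row, 0-based) coordinates is foreground — one deterministic rule for
boundary cells. Growth curves count live on-disc cells per timepoint;
dead cells are tallied but never fitted. Off-disc and dead tallies are
reported alongside.

## Bayesian models and sampler

**Hierarchical growth model.** y = μ + β_cell + β_plate + u_e + ε with
reference-level coding (first level alphabetically pinned at 0),
u_e ~ N(0, σ_exp²) shared within an experiment date and sampled
non-centered (u = σ_exp·z), and ε ~ N(0, σ²_plate) grouped by plate type.
Priors: zero-centered Cauchy on μ and the βs, half-Cauchy on all scales —
"Cauchy priors on variances" is realized on the SD scale, where the
distribution is proper. Prior widths default to 10× the empirical SD of
the response (weakly informative, scaled loosely to the data) and are
configurable.

**IC₅₀-difference model.** log IC₅₀ ~ N(α_cell + δ_{cell,hypoxia}, σ²),
δ ≡ 0 for normoxia. Differences are modeled on the log scale so each δ is
reported as a fold change e^δ with a symmetric 95% credible interval.
Gaussian priors on α and δ, half-Cauchy on σ, widths again 10× the data
SD. Censored or non-positive IC₅₀ inputs are excluded with a warning.

**Sampler.** Adaptive random-walk Metropolis-within-Gibbs, vectorized
across chains: componentwise Gaussian proposals with per-chain,
per-parameter step sizes adapted toward 0.44 acceptance (Robbins–Monro)
during warmup and frozen afterwards. Scales are sampled as logs with the
Jacobian included. Two volume-tracked block moves repair the geometry
that plain componentwise updates traverse slowly: a ridge shift
(μ → μ+δ, z → z − δ/σ_exp; likelihood-invariant) and a funnel rescale
(log σ_exp → +δ, z → z·e^(−δ); log-Jacobian −E·δ). Defaults: 4 chains,
500 warmup, 2000 draws. Every reported parameter carries split-R-hat and
bulk ESS (via arviz); the `converged` flag gates on R-hat < 1.05 and
ESS > 400 and is reported honestly rather than enforced. With degenerate
zero-noise inputs the scale posteriors pile up near zero and mix slowly —
the flag may trip — but location contrasts remain pinned to the
deterministic differences.

Simulation studies (`ecmscreen.simulation`) batch many simulated datasets
into one sampler run (all datasets share a design, so rows =
simulations × chains), using the identical model code; the calibration
studies use 2 chains × 400 warmup × 700 draws per dataset, enough for
stable 95% interval endpoints of the well-mixing contrast parameters.

## Synthetic generators

All randomness derives from one top-level seed through named
`SeedSequence` substreams, so every generator is bit-reproducible and
pipelines are reproducible end to end.

- **Counts:** N(t) rounded, clipped at 0, with multiplicative lognormal
  noise of specified CV (mean exactly 1); counting error in confluent
  imaging scales with the count, hence multiplicative. A Poisson
  resampling flag exists. Default horizon 0–72 h every 12 h.
- **Dose ladders:** rate(d) = r·(1 − d^h/(d^h + IC₅₀^h)) on the study's
  3-fold ladder (0, 0.062, 0.185, 0.555, 1.667, 5 μM), so the true IC₅₀
  of the relative-rate curve equals the Hill parameter by construction.
- **Well scenes:** radially symmetric quadratic vignette (the simplest
  smooth field consistent with an empty-well light profile) + uniform
  disc offset + per-region Gaussian texture (on-disc SD > off-disc SD —
  the premise of the segmentation; equality is allowed but flagged
  `no_texture_contrast`) + Gaussian nuclear spots + camera noise.
  Defaults: 512×512 px at 20 μm/px with a 150 px disc radius (a 6 mm
  disc); the imaging platform's true pixel geometry is not claimed,
  only configurable. Centroids carry exact on/off labels and are placed
  a configurable margin (default 3 px) away from the boundary.
- **Effects tables:** y = μ + β_cell + β_plate + u_e + ε with defaults at
  study scale — rates of a few 0.01/h, a planted 0.006/h contrast between
  the 2 kPa and 0.2 kPa substrates, σ_exp = 0.002/h, per-plate residual
  SDs of 0.002–0.004/h, 4 experiment dates × 3 replicates.

What the generators deliberately do **not** emulate: optics (PSF,
z-stacks, spectral channels), cell morphology and segmentation errors of
the upstream nuclear-detection software, spatial crowding, drug
pharmacokinetics, or non-exponential growth phases. Passing tests
therefore demonstrate that the algorithms are correct under their stated
models, not that those models capture every property of real wells.

## Design choices that were genuinely open

- Best-mask selection replaces the original manual choice with an
  area+circularity score, keeping the ranked list for manual override.
- IC₅₀ replicate handling defaults to per-replicate estimates consumed by
  the downstream Bayesian model.
- The texture filter runs on raw intensities by default (matching the
  order light-profile comparison is applied in); corrected mode is a flag.
- Sign-test two-sidedness is the doubled smaller tail capped at 1.
- The sampler contract is the converged posterior (R-hat/ESS gates), not
  a particular sampler brand.

## Known limitations

- IoU degrades for discs clipped by the image border (`allow_clipped`
  scenes) and for texture contrast near zero; no multi-disc wells.
- Covariance-based rate SEs understate spread for strongly heteroscedastic
  long-horizon curves (see above); use replicate spread when it matters.
- The hierarchical model assumes a balanced-enough design that every
  factor level is observed; a missing level raises an explicit error
  rather than silently dropping a coefficient.
- Censored IC₅₀s are excluded from the difference model rather than
  modeled (no interval-censored likelihood).
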