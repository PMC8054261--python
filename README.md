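# ecmscreen

Quantitative analysis of high-content screens of colorectal-cancer (CRC)
cells grown on liver extracellular-matrix (ECM) scaffolds under
multifactorial microenvironmental perturbations — oxygen tension (21% /
1% / 0.1% O₂), substrate stiffness (plastic, 0.2 kPa and 2 kPa
polyacrylamide), and oxaliplatin dose.

It is written for experimentalists and computational biologists who have
per-well scan images and nuclear-segmentation exports (centroid +
live/dead tables) from a high-content imaging platform and want to turn
them into condition-level growth rates, IC₅₀ values and calibrated
statistical comparisons.

## What it computes

1. **Disc segmentation.** A decellularized liver disc (6 mm diameter)
   shows higher local intensity variance than the bare well. The disc
   mask is found by a local standard-deviation filter + median filter +
   threshold, augmented with candidate pixels where the image deviates
   from an empty-well light profile, then refined by
   dilation–reconstruction morphology. A parameter sweep scores each
   candidate mask by area and circularity against the known disc
   geometry and returns a ranked list for manual override.
2. **Cell co-registration.** Each detected centroid is labelled on-disc
   or off-disc by mask lookup; only on-disc live cells enter growth
   curves.
3. **Growth kinetics.** Live-cell counts over 0–72 h are fitted with the
   exponential model N(t) = N₀·e^(rt) by Levenberg–Marquardt nonlinear
   least squares on raw counts; r (per hour) is the specific growth rate.
4. **Dose response and IC₅₀.** Relative growth rates (treated / untreated)
   across a 3-fold oxaliplatin dilution ladder (0, 0.062, 0.185, 0.555,
   1.667, 5 μM); IC₅₀ is the concentration where the relative rate
   crosses 0.5, located by linear interpolation on a log₁₀-dose axis,
   with explicit censoring when the curve never crosses.
5. **Comparative statistics.**
   - exact two-sided sign test for monotone trends across ordered O₂
     levels: p = min(1, 2·min P(X≤k), P(X≥k)), X ~ Binomial(n, ½);
   - hierarchical Bayesian model of growth rates,
     y = μ + β_cell + β_plate + u_experiment + ε, with a random
     experiment-date effect, per-plate-type residual variances, Cauchy
     priors on coefficients and half-Cauchy priors on scales;
   - empirical Bayesian model of log-IC₅₀ differences between hypoxia
     and normoxia, reported as fold changes e^δ with symmetric 95%
     credible intervals;
   - two-sided Welch t-tests.
6. **Synthetic data.** Seeded generators emulate every input — well
   scans with a textured disc, detection tables, exponential count
   series, Hill-suppressed dose ladders, and multi-experiment rate
   tables with known random-effects structure — each returning ground
   truth, so the whole pipeline is testable end to end.

## Worked example

`examples/02_dose_response_ic50.py` plants a Hill dose response with
IC₅₀ = 0.32 μM, fits every curve and interpolates:

```
   0.000 uM -> relative growth rate 1.000
   0.062 uM -> relative growth rate 0.838
   0.185 uM -> relative growth rate 0.634
   0.555 uM -> relative growth rate 0.366
   1.667 uM -> relative growth rate 0.161
   5.000 uM -> relative growth rate 0.060

IC50 = 0.3201 uM (true 0.32 uM), bracketing doses (0.185, 0.555)
```

The relative rate halves at the IC₅₀; the 0.0001 μM residual against the
planted value is log-interpolation bias. `examples/05_bayesian_models.py`
plants a 0.006/h stiffness contrast and a 1.7-fold hypoxia IC₅₀ shift and
recovers both:

```
stiffness contrast: posterior mean 0.0074 /h (95% CI 0.0054 to 0.0094), truth 0.0060 /h
diagnostics: R-hat 1.002, ESS 1635, all-parameter gate converged = True

IC50 fold change (0.1% vs 21% O2): posterior mean 1.63 (95% CI 1.29 to 2.00), truth 1.70
```

Both truths sit inside their 95% credible intervals; a fold change whose
CI excludes 1 indicates hypoxia changed drug sensitivity. The other
examples cover growth-rate fitting, segmentation + registration, the
sign/Welch tests, and the end-to-end pipeline.

## Command line

A thin CLI wraps the library:

```bash
ecmscreen segment --image well.tif --profile empty.tif --out mask.png --report seg.json
ecmscreen fit-growth --counts counts.csv --out fits.csv --group-by dose_uM
ecmscreen ic50 --fits fits.csv --out ic50.csv
ecmscreen stats sign-test --rates deltas.csv
ecmscreen stats hier --rates rates.csv --out posterior.json
ecmscreen pipeline demo            # synthesize + run every stage
ecmscreen pipeline run --config run.yaml
```

`pipeline run` validates a YAML config up front and writes a manifest
with per-artifact SHA256 checksums; identically-seeded reruns are
bit-identical.

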