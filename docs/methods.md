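# Methods

## The readout model

A single-particle sandwich immunoassay with microscopy readout does not
integrate fluorescence over a well; it counts discrete bright events on the
glass surface. The package's readout is the *pixel count*: the number of
pixels in a well's accepted images whose intensity is **strictly greater**
than an intensity cutoff anchored in the blank control (BC, unspiked sample
buffer). The cutoff is the smallest integer *c* such that the fraction of
pooled blank pixels above *c* is at most the target fraction (default
1×10⁻⁵, i.e. 0.001% of blank pixels remain positive). Ties at the cutoff
count as negative; this strict-inequality dialect is applied consistently
in cutoff determination and pixel counting, so the achieved blank-positive
fraction can never exceed the target.

Pooling scope: the cutoff is computed per plate from all QC-accepted blank
images pooled. Per-image thresholds would make the cutoff noisier for no
benefit at 25 images/well; per-plate pooling matches the way blanks are
run (one BC set per plate).

## Image QC

Exclusion of unusable frames is automated with two operators:

* **Artifact**: the saturated-pixel fraction (at the bit-depth maximum)
  exceeds 0.001, or a connected component of pixels above 90% of range
  spans more than 500 px. This catches dust, fibres and large aggregant
  clumps.
* **Defocus**: the focus score — variance of the 5-point Laplacian divided
  by the image variance — falls below 0.08. Pure i.i.d. read noise scores
  ≈ 20 (the Laplacian kernel's coefficient-square sum); a spot field at the
  in-focus PSF (σ = 1.5 px) asymptotes to ≈ 0.33 however dense or bright
  the spots; a 4×-defocused field falls below ≈ 0.02. The default 0.08 is
  the geometric middle of those two regimes and detects the simulator's
  corruption modes at ≥ 95% (in practice 100%). Constant images score +∞
  (no focus information, never flagged).

A well readout sums pixel counts over accepted images and rescales by
n_total/n_accepted so wells with exclusions stay comparable; wells with
fewer than 60% accepted images (or none) are marked invalid rather than
silently zeroed. Replicate aggregation uses the sample SD (n−1); the CV
gate is strict ("below 20%/25% accepted"), and the CV of a non-positive
mean is flagged undefined rather than computed.

## Calibration and LoD

Nanoparticle standards enter the curve only if their replicate pixel counts
exceed the BC's by a one-sided Mann–Whitney U test at α = 0.05 (exact null
for groups of ≤ 8 tie-free observations, tie-corrected normal approximation
otherwise) *and* they lie within the linear range. "Linear range" is
resolved algorithmically: starting from all significant points, the highest
concentration is dropped while its relative residual from a weighted refit
on the remaining points exceeds 20%. This captures the saturation roll-off
at the top of a dilution series (spot overlap caps the pixel count) without
touching the linear portion; at least two points are always retained.

The curve is weighted least squares of mean pixel count on nominal
concentration with weights 1/ȳ per point (the observed mean readout), so
the top of the series does not dominate; points with non-positive mean
readout are unweightable and dropped. Concentrations are recovered as
(pixel count − intercept)/slope; negative inversions are clamped to 0 fM
and flagged `below_blank` rather than reported negative.

LoD follows the blank-plus-two-sigma convention: LoD(pixel) = mean(BC) +
2·SD(BC), with σ the **well-level** sample SD (n−1) of the BC readouts
(nominally 24 replicate wells), not the pixel-level SD — the LoD is a
statement about readout repeatability, not camera noise. It is converted to
fM through the curve inverse and clamped at 0.

## Validation metrics

* Percent signal reduction = 100 − 100·control/reference, used identically
  for selectivity controls and immunodepletion effectivity.
* Percent dilution linearity at point *i* = 100·(readoutᵢ·factorᵢ/factor₀)
  /readout₀ on blank-corrected readouts, anchored at the least-diluted
  point; the mean is over non-anchor points. Tolerance 80–120%, inclusive.
* Spike recovery = 100·(spiked − unspiked)/nominal; negative net signal is
  reported as-is with an over-subtraction flag.
* Stability: condition/baseline ×100 against an inclusive ±25% band.
* Inter-assay agreement: Spearman ρ of paired runs, pass at ρ > 0.9.

Spearman correlations use midranks; the p-value is exact (full permutation
enumeration, vectorised) below n = 10 and the t-approximation at n ≥ 10.

## Cohort statistics

The normality suite runs Shapiro–Wilk, Lilliefors, the classical KS test
against a normal with sample-estimated parameters (listed for completeness;
this naive variant is known to be conservative, and the suite's type-I
calibration test asserts exactly that), and Anderson–Darling; any p < 0.05
flags the sample non-normal and routes downstream analysis to
non-parametric tests. The headline group comparison is a two-sided
Mann–Whitney U (the conservative reading for a reported group difference);
one-sided is available via a parameter.

ROC analysis orients AD as the positive class with the decision rule
"concentration ≥ threshold ⇒ AD". Candidate thresholds are midpoints
between consecutive distinct values plus ±∞; the trapezoidal AUC of this
scan equals the tie-corrected U/(n₁n₂) — an identity the test suite
verifies on random tied data. The Youden-optimal threshold maximises
J = sens + spec − 1 with ties broken toward higher specificity (the natural
choice for a screening biomarker) and then toward the higher threshold.
A degenerate cohort (all concentrations equal) yields AUC 0.5 and is
flagged instead of producing a meaningless threshold.

## Synthetic-data model

The simulator emulates what the analysis consumes, not the optics:

* **Blank frames**: Gaussian read noise (default mean 500, SD 20 ADU) on
  14-bit data in 16-bit containers, 1000×1000 px, 25 frames/well. A
  Poisson shot-noise term is available behind a flag but off by default —
  the cutoff logic is exercised by any unimodal noise; the Gaussian model
  keeps the blank distribution analytically transparent.
* **Spots**: symmetric 2-D Gaussian profiles (σ = 1.5 px; no PSF model is
  prescribed by TIRF itself) at uniform sub-pixel positions, log-normal
  amplitudes (mean 3000, SD 1500 ADU — placeholders, exposed as config,
  since the true aggregate intensity distribution is unknown). A spot
  contributes however many pixels exceed the cutoff; no 1:1 spot↔pixel
  mapping is attempted because the assay readout is pixels, not spots.
* **Concentration response**: spot count per frame ~ Poisson(spots_per_fM ×
  concentration), which makes the expected pixel count linear in
  concentration until spot overlap saturates — exactly the regime the
  linear-range rule must handle.
* **Corruption**: a saturated disk covering ≥ 0.5% of pixels (artifact
  mode) or the PSF inflated ≥ 4× (defocus mode).
* **Cohorts**: per-group log-normal concentrations. Defaults emulate the
  study design: 26 AD vs 31 HC, log-SD 1.5 (57 draws span roughly 1 fM to
  3 pM), group separation Δ = 1.13 log units so the normal-model AUC
  Φ(Δ/(σ√2)) ≈ 0.70, replicate CV 18.7% (the observed mean fecal
  intra-assay variability), and demographic covariates (age, sex, Bristol
  score) drawn to match the published group summaries.

What the simulator does **not** model: evanescent-field optics, EMCCD gain
and camera-specific noise, spatial illumination inhomogeneity, matrix
autofluorescence structure, and spot clustering. Passing tests therefore
demonstrate the correctness of the *analysis* under a controlled generative
model, not the assay's behaviour on real fecal plates — the study-scale
magnitudes (LoD in fM, mean CVs, selectivity percentages) depend on raw
plate data and are deliberately not asserted.

## Numerical and design choices

* Cutoff search is a cumulative histogram over all integer intensities;
  the test suite checks it against an exhaustive per-candidate scan.
* The calibration fit is ordinary WLS (statsmodels); the linear-range
  trimming uses a closed-form weighted line solve.
* Well rescaling (sum × n/k) equals mean-per-image × nominal image count;
  the identity is tested.
* Calibration slope recovery is validated against an *empirical* generative
  slope — the mean pixel response measured from one large
  single-concentration simulation — because pixels-per-spot-above-cutoff
  has no closed form under log-normal amplitudes and an estimated cutoff.
  The mean fitted slope over 50 simulated plates must agree within 10%.
* Inclusive tolerance bounds throughout (80/120, 75/125 pass); strict CV
  gates ("below" the gate passes).
* The 1:5 assay dilution of fecal samples is a config factor applied when
  converting sample readouts to reported concentrations (default 5).

## Problem sizes

Tests and the property suites run the image simulator at reduced geometry
(typically 100–200 px square frames, 3–5 frames/well, 6–24 blank wells) —
the pixel-count statistics scale trivially and nothing in the logic depends
on absolute image size. The study geometry (1000×1000 × 25 frames) is the
generator default and is used where the claim concerns it directly (the
blank-cutoff acceptance check pools 24 full-size frames). Monte-Carlo
checks use 200–1000 replicates: null cohort type-I over 1000 seeds, AUC
recovery over 500 cohorts, Poisson-mean convergence over 1000 wells.

## Known limitations

* QC thresholds are tuned to the simulator's corruption modes; real
  acquisitions will need site-specific retuning (all thresholds are
  config).
* The linear-range rule is a stated algorithmic stand-in for what is, in
  many labs, a visual judgement; alternative rules (e.g. F-tests for lack
  of fit) would be reasonable.
* The naive KS entry of the normality suite is conservative by
  construction; it is retained because the suite's contract is to report
  all four classical tests.
* No covariate-adjusted modelling (age/sex matching) and no longitudinal
  analysis; the cohort layer is deliberately a cross-sectional screen.
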