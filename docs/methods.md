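# Methods

`angiorad` implements an arteriography-derived perfusion-radiomics
analysis: digital-subtraction-angiography (DSA) cine sequences are turned
into five pixel-wise perfusion parameter maps by gamma-variate fitting of
per-pixel time-density curves; a 1,459-feature radiomics bank is extracted
from the aneurysm ROI on those maps; features are filtered for inter-rater
stability, screened univariately, and selected by L1-penalized logistic
regression into a linear radiomics score with a Youden-index cutoff that
discriminates aneurysms that rupture after flow-diverter placement from
those that do not. Because clinical DSA cohorts of this kind are not
publicly depositable, the package includes a first-class synthetic cohort
generator that reproduces the statistical structure the analysis assumes;
everything below is testable end to end from a seed.

## Time-density curves and the gamma-variate model

Contrast darkens a DSA image. For a pixel with intensity series
$I_k$ acquired at $t_k = k/\text{cine rate}$, the contrast density is
$d_k = \max(0, \bar I_{\text{pre}} - I_k)$, with the baseline
$\bar I_{\text{pre}}$ the mean of the first $b$ pre-contrast frames
($b = 2$ by default, configurable). The bolus passage is modelled by the
classical gamma variate
$C(t) = K\,(t-t_0)^{\alpha} e^{-(t-t_0)/\beta}$,
fitted in its peak-referenced ("simplified") form

$$y(t) = y_{\max}\, u^{\alpha} e^{\alpha(1-u)}, \qquad
  u = \frac{t - t_0}{t_{\max} - t_0},$$

which is linear in $(\log y_{\max}, \alpha)$ after taking logs:
$\ln y = \ln y_{\max} + \alpha(\ln u + 1 - u)$. The fit initializes
$(y_{\max}, t_{\max})$ at the raw peak, estimates $\alpha$ and the
amplitude by least squares on this linearization over samples above
`peak_fraction` (default 0.1) of the peak, and finds $t_0$ by a grid
search (step `t0_grid_step_s`, default 0.05 s) with parabolic refinement,
minimizing the residual sum of squares on the raw curve. The amplitude is
then rescaled by linear least squares on the raw scale, since the
log-space intercept underweights the peak. On a noiseless simplified
gamma variate the recovery is exact; under 2% noise the median error of
the peak is below 1% and of the peak time below one frame interval.

A curve whose peak does not exceed `noise_floor_k` (default 3) robust
noise SDs is declared bolus-free and the pixel excluded. The noise SD is
estimated from successive differences (1.4826·MAD/√2, zero differences
excluded); when ≥30% of the samples are zero-clipped the estimate is
divided by 0.654, the asymptotic bias of this estimator on half-clipped
Gaussian noise.

## The five perfusion parameters

From a valid fit: **MAX** $= y_{\max}$ (peak contrast density, a.u.);
**TTP** $= t_{\max}$, measured from the start of the sequence; **CBV**
$= \int y\,dt$ (adaptive quadrature on the fitted form; for the standard
form this equals $K\beta^{\alpha+1}\Gamma(\alpha+1)$, against which the
quadrature is verified to 0.1%); **MTT** $= \int (t-t_0)\,y\,dt / \int
y\,dt = (\alpha+1)\beta$; **CBF** $=$ CBV/MTT. These are AIF-free,
relative definitions — no arterial-input deconvolution is attempted,
because a single ROI sequence does not support one. CBF·MTT = CBV holds
to machine precision by construction. Maps are computed only inside the
ROI (restricted to its bounding box; the optimization is provably
invisible since each pixel's fit uses only its own curve), and invalid
pixels carry NaN and are removed from the downstream feature mask.

## The 1,459-feature bank

Per parameter map: 18 first-order, 24 gray-level co-occurrence (GLCM) and
16 run-length (GLRLM) features on the original map, and the same 58 on
each of four single-level wavelet sub-bands (Coiflet-1; LL/LH/HL/HH),
giving $58 \cdot 5 = 290$ per map; plus 9 two-dimensional shape features
of the ROI computed once (attached to the TTP map):
$5\cdot290 + 9 = 1459$. Names follow
`<MAP><imagetype>_<class>_<FeatureName>`, e.g.
`MAXwavelet.LH_firstorder_Energy`, `TTPoriginal_shape2D_MinorAxisLength`.

Conventions follow the standard image-biomarker definitions: fixed
bin-width discretization referenced to the ROI minimum (translation
invariant); symmetric distance-1 GLCMs at 0°/45°/90°/135° with features
averaged over angles; run-length matrices per direction with masked-out
pixels breaking runs, averaged over the four directions; axis lengths as
$4\sqrt{\lambda}$ of the masked pixel-coordinate covariance eigenvalues
in physical units; perimeter and mesh surface from the marching-squares
boundary. Both texture classes are verified feature-by-feature against
brute-force pair/run enumerators on random images.

Numerical choices worth knowing:

* **Bin widths are per map.** The maps live on different scales (a.u.
  for CBF/CBV/MAX, seconds for MTT/TTP); the defaults are 25 a.u. for the
  amplitude-like maps and 0.25 s for the time maps. A single global width
  would collapse the time maps to one gray level.
* **Wavelet mode is `periodization`.** Each sub-band then has exactly
  ⌈n/2⌉ coefficients per axis — aligning one-to-one with the
  majority-rule 2× downsampled ROI mask — and the orthogonal transform
  conserves energy (Parseval), which the tests assert. Symmetric padding
  is available in config (sub-bands centrally cropped), but its extra
  boundary coefficients have no natural mask alignment. Sub-band
  first-order features use twice the pixel spacing, the physical pitch
  after decimation.
* **Shared geometry across raters.** The crop, the wavelet decimation
  grid, and the discretization reference are anchored to the fitted-map
  region (the union-ROI validity mask), not to the individual contour.
  Otherwise a one-pixel contour difference shifts the decimation grid
  parity and re-bins all gray levels, and the rater-stability ICC of
  every texture feature collapses for reasons that have nothing to do
  with the contours themselves.
* **Degenerate inputs** use documented conventions instead of NaN: a
  single gray level gives Correlation 1, Imc1/Imc2 0, MCC 1; a
  single-pixel mask gives skewness/kurtosis 0 and axis lengths 0. All are
  logged.

## Cohort construction

Propensity scores are a logistic regression of group on age, sex,
aneurysm size, location (ICA/MCA/VA), and device count
(single/multiple), categoricals one-hot encoded. Matching is greedy 1:3
nearest-neighbor on the logit, processing cases in descending propensity,
without replacement, ties broken by case id (making the result invariant
to input row order). No caliper by default; an optional caliper in SD of
the logit is exposed and raises an error listing unmatched cases.
Balance is reported as absolute standardized mean differences before and
after matching. The matched cohort (64 cases, 16 ruptures) is split
stratified by outcome at a 2:1 ratio — 43 training (11 ruptures) and 21
test (5 ruptures) — with the test fraction configurable.

## Selection and the radiomics score

1. **Stability**: ICC(2,1) (two-way random effects, absolute agreement,
   single measurement) per feature between the two raters' contours,
   across all matched cases — rater agreement is outcome-blind, so this
   precedes the split. Features with ICC ≥ 0.8 survive. Zero
   between-case variance yields ICC 0, flagged.
2. **Univariate screen** (training cases only): Shapiro–Wilk per group
   and a two-sided F-test of variance homogeneity route each feature to
   an equal-variance t-test (both normal and homoscedastic) or a
   two-sided Mann–Whitney U (normal approximation, tie-corrected);
   features with p < 0.05 survive. Constant features get p = 1. The
   type-I rate of the screen is verified to sit inside binomial bounds
   of the nominal level on null features.
3. **LASSO**: features standardized on training data (parameters frozen
   into the model); L1-penalized logistic regression over a 100-point
   λ grid descending four decades from $\lambda_{\max} = \max_j |x_j^T
   (y-\bar y)|/n$; λ* maximizes stratified 5-fold cross-validated AUC
   (ties go to the sparser model; a one-standard-error rule is available
   in config). The final refit solves the exact penalized objective
   (coordinate-descent solution polished by SAGA) and satisfies the
   subgradient KKT conditions to 1e-6, which the tests check. Selected
   pairs with |Spearman ρ| ∈ [0.90, 1.00] are reported as redundant
   (reporting only by default; optional pruning keeps the member with
   the smaller univariate p).

The radiomics score is the linear predictor
$\text{score}(x) = \sum_i \beta_i x_i^{*} + \text{intercept}$ on
standardized features; serializing and reloading the model reproduces
scores bit-identically. The cutoff maximizes Youden's
$J = \text{sensitivity} + \text{specificity} - 1$ over all midpoints
between adjacent sorted scores (ties toward higher specificity;
orientation auto-detected from the AUC). Evaluation reports the
tie-corrected empirical AUC with a DeLong 95% CI (cross-checked against
the R pROC implementation) and sensitivity/specificity/PPV/NPV at the
cutoff.

## The synthetic cohort generator

Each case is a 32-frame, 4 fps, 128×128 sequence at 0.154 mm pixel
spacing (frame size reduced from the clinical 1,024² for desk scale;
spacing kept so physically scaled features take realistic values).
Frames are `baseline − Σ region gamma variates + N(0, noise_sd)`:
a weak whole-frame tissue blush, a fast-washout parent-artery band
tangent to the sac, and the elliptical aneurysm sac (default
K = 300, t0 = 1 s, α = 2, β = 0.8 s; peak density ≈ 104 a.u. at 2.6 s;
noise SD 4 ≈ 4% of peak). Rater 1's mask is the exact sac ellipse;
rater 2's is produced by dilating/eroding a random boundary arc
(severity-controlled, one pixel deep), giving Dice ≈ 0.93 at the default
severity — a realistic two-expert disagreement.

Real cohorts are heterogeneous; statistically cloned cases would make
rater-agreement ICCs meaningless (no between-case variance). The
generator therefore jitters each case's bolus parameters log-normally
(SD 0.15 on amplitudes, half that on timing/shape, identically in both
groups) and modulates the sac amplitude by a smooth log-normal spatial
field (SD 0.2), which also gives the texture features something real to
measure. With this, roughly 80% of the 1,459 features pass the ICC ≥ 0.8
filter — comparable to published two-rater radiomics studies.

The rupture-group effect is multiplicative: sac amplitude ×1.6 (stronger
peak contrast retention, raising MAX-map intensity and energy features),
sac minor axis ×1.4 (larger aneurysms), with an optional washout-scale
multiplier (default 1). Covariates take values typical of flow-diverter
cohorts (age ~N(53, 8); size ~N(21.6, 7.5) mm for ruptures vs
N(17.1, 7.5) mm for controls; location and device-count multinomials
near clinically reported frequencies), drawn overlapping so matching is
feasible; under the all-ones null configuration both groups share the
control distributions and are exchangeable. Sac geometry is deliberately
decoupled from the size covariate: the covariates exist to exercise
matching, the image effect to exercise the radiomics chain.

**What passing tests do and do not show.** The generator emulates bolus
kinetics, rater disagreement, cohort heterogeneity, and a plausible
effect structure; it does not emulate X-ray physics (scatter, beam
hardening), vessel overlap, motion, scanner differences, or real
aneurysm morphology. End-to-end recovery on this cohort demonstrates
that the pipeline finds the kind of signal it is designed for and finds
nothing under the null — it says nothing about clinical effect sizes or
about the discrimination achievable on real patients.

## Problem sizes and determinism

Monte-Carlo end-to-end checks (signal power over 20 seeds, null
calibration over 10) run on 64×64 frames with a proportionally scaled
sac (~110 ROI pixels) and a 120-candidate control pool; single-run
checks use the full 128×128 default. These sizes are the package's
desk-scale choices and are exposed in `PipelineConfig`. All randomness
flows from one master seed through SHA-256-derived per-stage seeds;
a fixed seed reproduces every artifact, including the serialized model,
byte for byte.

## Known limitations

* TTP is quantized to the frame grid (the fitted peak time stays at the
  raw-peak sample), so TTP-derived quantities carry up to half a frame
  interval of bias; MTT/CBF inherit up to ~5% from this at 4 fps.
* The 2D analysis ignores the three-dimensional shape of the aneurysm,
  as any single-working-view method must.
* Greedy matching is not optimal matching; with a generous control pool
  the difference is immaterial, and optimal/full matching is out of
  scope.
* With very small ROIs (minor axis of a few pixels) the half-resolution
  wavelet masks become coarse and sub-band texture features degenerate;
  the degeneracy conventions apply and are logged.
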