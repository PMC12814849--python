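# Methods

## The quantification problem

First-pass perfusion CMR observes the transit of a gadolinium bolus through
the myocardium as a time-resolved image series. Under linear time-invariant
tracer kinetics the myocardial concentration curve is the arterial input
function (AIF) convolved with a tissue impulse response function (IRF):

    C_t(t) = [C_a(· − delay) ∗ IRF](t)

Quantification is the inverse problem — model-based deconvolution: fit the
IRF parameters so the forward convolution matches the measured tissue curve,
and report the amplitude parameter as myocardial blood flow (MBF, mL/min/g).
Three IRFs are implemented:

| model          | IRF(t)                                   | parameters |
|----------------|------------------------------------------|------------|
| Tofts          | K_trans · exp(−(K_trans/Ve) t)           | K_trans (min⁻¹), Ve |
| modified Tofts | K_trans · exp(−(K_trans/Ve) t) + Vp δ(t) | + Vp |
| Fermi          | F / (exp(k (t − MTT)) + 1)               | F (mL/min/g), k (s⁻¹), MTT (s) |

The printed Fermi form is typographically ambiguous in parts of the
literature; the standard Fermi–Dirac shape F/(exp(k(t−MTT))+1) is adopted
deliberately rather than guessed silently. Reported MBF is K_trans/ρ for the
Tofts family (tissue density ρ = 1.05 g/mL converts the per-mL-tissue rate
to a per-gram flow) and the amplitude F for Fermi — *not* IRF(0), which
differs by the factor 1/(1 + exp(−k·MTT)); the distinction is documented
because the two readouts diverge for short MTT or small k.

## Numerical treatment

* **Units.** Time is carried in seconds; the Tofts exponent and all
  convolution integrals are evaluated with t in minutes so per-minute rate
  constants keep their conventional units. Fermi's shape parameters k and
  MTT act on seconds.
* **Convolution.** Causal trapezoidal discrete convolution on the uniform
  frame grid. The error is O(dt²); against the closed-form convolution of a
  mono-exponential AIF with the Tofts IRF it is ≈5×10⁻⁵ relative at
  dt = 0.5 s, and halving dt divides it by ≈4 (verified in the tests).
* **Dirac term.** The modified-Tofts Vp δ(t) contribution is added
  analytically as Vp·C_a(t − delay), never as a discretised spike, so the
  forward model is grid-independent at first order.
* **Fitting.** Bounded trust-region least squares (`scipy.optimize.
  least_squares`, method `trf`) on the continuous parameters, combined with
  an exhaustive grid search over the bolus-arrival delay (0–10 s in
  frame-interval steps by default; the delay a pipeline should fit is an
  open modelling choice, so the grid is a config option). Lowest residual
  sum of squares wins; ties break to the smaller delay. Default
  initialisation: K_trans or F = 1.0, Ve = 0.2, Vp = 0.05, k = 0.3 s⁻¹,
  MTT = 5 s; an optional 3-point multistart perturbs the amplitude.
  Bounds: rates and flows ≥ 0, Ve ∈ (10⁻³, 1], Vp ∈ [0, 0.5], k ≤ 10 s⁻¹,
  MTT ≤ 30 s.
* **Model nesting.** Pinning Vp's bounds to (0, 0) drops the parameter and
  routes the fit through the Tofts path, so a Vp-pinned modified-Tofts map
  is bitwise identical to the Tofts map.
* **Degenerate curves.** Identically flat tissue curves short-circuit to
  MBF = 0 with `converged = False`; non-convergent map pixels are missing
  (NaN), never zero.
* **Fit window.** The whole acquisition enters the fit by default. This
  matters: Fermi estimates shift by tens of percent between whole-series
  and first-pass-only fitting because the Fermi IRF does not model delayed
  contrast efflux, so the window is exposed as `FitOptions.fit_window`
  rather than hard-coded.

## Signal model

The dual-sequence acquisition interleaves low-resolution, short
saturation-delay frames (TD = 25 ms, blood pool stays quasi-linear) with
high-resolution TD = 110 ms tissue frames. The implemented conversion is an
ideal saturation-recovery spoiled gradient echo with a single effective
delay:

    S(C) = (1 − exp(−TD(R10 + r1 C))) / (1 − exp(−TD R10)),  R10 = 1/T10

normalised so S(0) = 1, inverted in closed form. Readout-train and
flip-angle corrections, B1 and inversion-efficiency effects are deliberately
out of scope: vendor pipelines implement proprietary corrections that cannot
be reproduced from published descriptions, and the dual-TD nonlinearity is
the behaviour that matters for testing the pipeline. Defaults: r1 = 3.5
L·mmol⁻¹·s⁻¹ (Gd-DOTA at 3 T, literature-typical), baseline T1 = 1.2 s,
3 pre-contrast baseline frames. Signals at or above the saturation ceiling
1/(1 − exp(−TD·R10)) are flagged non-invertible and the pixel is excluded.
The AIF is the mean over a 10-mm circular ROI (a pixel belongs to the ROI if
its center lies within the radius); plasma correction C_b/(1 − Hct) is
applied for the plasma-referenced Tofts family, while Fermi consumes the
whole-blood curve so its amplitude stays interpretable as blood flow — both
arms are returned, and the choice is configurable.

## Segmentation and aggregation

AHA 16-segment labelling partitions each annular short-axis mask into 6
(basal, mid) or 4 (apical) equal angular sectors counterclockwise from the
anterior RV-insertion ray. Territories follow the standard mapping
LAD = {1,2,7,8,13,14}, RCA = {3,4,9,10,15}, LCX = {5,6,11,12,16}. Segment
values are pixel means; vessel values are means over the territory's pixels;
the participant value defaults to the global myocardial pixel mean (the
pixel-weighted mean of segment means — the unweighted variant is available
via `participant_from="segments"`, since published analyses rarely state
which was used). Pixel-wise MPR is stress/rest with rest values below a
0.1 mL/min/g floor excluded; segment-level MPR is the ratio of segment
means, which differs from the mean of pixel ratios on heterogeneous tissue —
the ratio-of-means is the reported quantity.

Exclusion rules: segments flagged for poor registration, or thinner than
5 mm (infarct thinning), are removed; a doubly-flagged segment counts once
with precedence poor_registration > thin_myocardium. Percentages round
half-up to one decimal, matching clinical reporting style. The built-in
thickness estimate is the radial extent of the masked annulus per sector
plus one pixel pitch; an externally measured per-segment table overrides it.

## Agreement statistics

Pairs are (x = reference, y = test); differences d = y − x.

* **ICC.** Two-way random effects, absolute agreement, single measures —
  ICC(A,1) — computed from the two-way ANOVA mean squares, with the
  McGraw–Wong F-based confidence interval (Satterthwaite df for the
  column/error mixture). Absolute agreement is the defensible form for
  method comparison because it penalises systematic bias, which a
  consistency ICC (and Pearson's r) ignores. Interpretation bands:
  < 0.50 poor, 0.50–0.75 moderate, 0.75–0.90 good, > 0.90 excellent, with
  boundaries resolved downward (0.75 → moderate, 0.90 → good).
* **TOST.** Paired two one-sided t-tests against ±margin, df = n − 1;
  reported p is the larger one-sided p, equivalence declared at p < 0.05.
  Default margins (from reference-modality interstudy variability): 0.90
  mL/min/g for MBF and 0.98 for MPR at the participant level; 1.43 and 2.80
  at vessel/segment levels. Zero-variance differences short-circuit:
  equivalent iff |mean d| < margin, flagged degenerate.
* **ROC / DeLong.** Abnormality is low flow, so the perfusion convention is
  `direction="less"` (lower score ⇒ more abnormal); orientation is explicit
  and never auto-flipped. Default reference thresholds: stress
  MBF ≤ 2.3 mL/min/g, MPR ≤ 2.5, boundary inclusive. AUC is the normalised
  Mann–Whitney U with half credit for ties; the DeLong comparison uses
  placement-value covariances and a two-sided normal p, returning p = 1
  with a degeneracy flag when the difference variance vanishes (identical
  or rank-equivalent scores).
* **Sample size.** The Walter–Eliasziw–Donner approximation
  n = 1 + 2k(z_α + z_β)²/((k−1)(ln C₀)²), C₀ = (1+kθ₀)/(1+kθ₁),
  θ = ρ/(1−ρ), ceiling-rounded. For (ρ₀ = 0.20, ρ₁ = 0.60, α = 0.05
  two-sided, power 0.80, k = 2) it returns 34; published planning tools
  differ by ±1–2 subjects depending on the variance approximation, so
  agreement with a printed 35 is expected only to that precision.
* **Clustering.** Segment and vessel rows are treated as independent
  observations; the subject id is annotation only. No mixed-effects CI
  correction and no multiple-testing adjustment are applied — this matches
  the analysis style the suite is meant to emulate, and both caveats apply
  to any interpretation.

## Synthetic data: what it emulates and what it does not

The generator exists so every stage is testable with known ground truth.

* **AIF.** Gamma-variate first pass, c(t) = A((t−t₀)/β)^α exp(−(t−t₀)/β),
  plus a delayed scaled copy for recirculation. Defaults (A = 6 mM,
  t₀ = 5 s, α = β = 2.5, recirculation fraction 0.15 at +20 s) give a
  ~4.9 mM whole-blood peak at t ≈ 11 s — a realistic bolus for a
  0.05 mmol/kg injection. The curve peaks at t₀ + αβ; the first-pass area
  is Aβ·Γ(α+1) analytically. No published curve is being matched: the
  gamma-variate is simply the field-standard smooth first-pass shape.
* **Phantom.** Annular myocardium (defaults: endo 8 mm, epi 16 mm, 1.5 mm
  pixels, 48×48 grid, up to three slices labelled basal/mid/apical) around
  a circular blood pool carrying the AIF; each myocardial pixel's curve is
  its AHA sector's forward-model curve; noise is additive i.i.d. Gaussian
  in the concentration domain (an optional signal-domain path goes through
  the signal module, keeping kinetics tests independent of the signal
  model). Default truth: stress 3.0, rest 1.0 mL/min/g. 60 s acquisition
  at 1 frame/s.
* **Cohort.** Latent true stress/rest MBF per subject (normal, truncated at
  0.05 mL/min/g for physiological positivity; defaults 2.83 ± 0.73 and
  1.46 ± 0.45 mL/min/g); the test arm adds a configurable bias (default
  0.31 mL/min/g) and per-arm Gaussian noise (default 0.495 each, giving a
  paired-difference SD ≈ 0.70).

Not emulated: MR physics (k-space, SENSE, saturation profiles), cardiac or
respiratory motion (inputs are assumed registered), PET count statistics,
between-segment spatial correlation, and realistic pathology patterns
beyond per-segment flow overrides. Passing tests therefore demonstrate that
the estimator chain is correct and stable under noise — not that it is
robust to motion, registration error, or model mismatch in real patients.

## Problem sizes used in the test suite

Curve-level checks run on 60-frame curves; noise-free recovery spans flows
0.5–4.5 mL/min/g × delays 0–6 s for all three models. The noisy-map check
uses a two-slice 48×48 phantom (~540 myocardial pixels) at concentration
peak SNR 20, sized so the Monte-Carlo error of the measured median error is
small relative to the 10% bound. Monte-Carlo statistics use 2000 TOST
replicates (n = 30) and a 20 000-rep paired bootstrap (n = 600) for the
DeLong cross-check; the DeLong oracle is the normal-approximation bootstrap
test (z from the bootstrap SD of the AUC difference) — a percentile
bootstrap additionally captures skewness the DeLong normal approximation
does not model, so it would not be a like-for-like comparison. Cohort bias
recovery uses n = 5000.

## Known limitations

* The saturation-recovery conversion ignores readout effects; absolute MBF
  from real scanner data will carry the corresponding bias.
* The Fermi three-parameter fit is weakly identified at low SNR (F trades
  against k and MTT); its pixel-wise error distribution is heavy-tailed, so
  median error is the robust summary and parametric maps benefit from the
  delay grid staying coarse.
* ICC confidence intervals assume balanced two-rater data; the suite does
  not implement k > 2 raters for ICC estimation (only for sample-size
  planning).
* `run_pipeline` orchestrates the synthetic path end to end; file-based
  studies are driven through the library API (readers, converters, fitters
  and aggregators are all public).
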