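# qpcmr

Quantitative first-pass perfusion CMR: pixel-wise myocardial blood flow
(MBF) mapping by model-based deconvolution, and the method-comparison
statistics used to validate a test modality (quantitative perfusion CMR)
against a reference standard (e.g. ¹⁵O-water PET).

It is written for imaging scientists who need a transparent, testable
implementation of the full quantification chain — from saturation-recovery
signal to MBF maps to agreement statistics — with a synthetic-data module
that generates every input with known ground truth, so the whole pipeline
runs and validates without any patient data.

## What it computes

Under linear time-invariant tracer kinetics the myocardial
gadolinium-concentration curve is the arterial input function (AIF)
convolved with a tissue impulse response function (IRF):

    C_t(t) = [C_a(· − delay) ∗ IRF](t)

Fitting the IRF by constrained nonlinear least squares (with an exhaustive
grid search over the bolus-arrival delay) and reading off the amplitude
gives MBF in mL/min/g. Three IRFs are supported:

* **Tofts** — K_trans·exp(−(K_trans/Ve)·t); MBF = K_trans/ρ (ρ = 1.05 g/mL)
* **modified Tofts** — adds an intravascular term Vp·δ(t), handled
  analytically
* **Fermi** — F/(exp(k(t−MTT))+1); MBF = F

Around the core sit: saturation-recovery signal ↔ concentration conversion
(dual-sequence TD 25/110 ms), proton-density normalisation, 10-mm blood-pool
AIF extraction with plasma correction, myocardial perfusion reserve
(MPR = stress/rest), AHA 16-segment labelling with LAD/RCA/LCX territories
and segment-exclusion accounting, and the statistics suite: Pearson +
regression, Bland–Altman, ICC(A,1) with confidence interval and
interpretation bands, paired TOST equivalence, ROC/AUC against
reference-defined abnormality (stress MBF ≤ 2.3 mL/min/g, MPR ≤ 2.5),
the DeLong test, and ICC-based sample-size planning.

See `docs/methods.md` for the model assumptions, unit conventions, numerical
choices and limitations.

## Worked example

```python
import numpy as np
from qpcmr import *

# simulate a stress acquisition and recover MBF for one myocardial curve
t = np.arange(0.0, 60.0, 1.0)                      # 60 s, 1 frame/s
aif = gamma_variate_aif(AifModelParams(), t)       # ~5 mM first-pass bolus
truth = KineticParams(model="fermi", f=3.0, k=0.35, mtt=6.0, delay=2.0)
tissue = simulate_tissue_curve(aif, "fermi", truth)
fit = fit_curve(tissue, aif, "fermi")
print(f"fitted MBF = {fit.mbf:.3f} mL/min/g (truth 3.0), "
      f"delay = {fit.params.delay:.0f} s, R^2 = {fit.r2:.6f}")

# paired-cohort agreement: CMR vs PET with an injected 0.31 mL/min/g bias
cohort = simulate_paired_cohort(CohortSpec(n_subjects=39, seed=7))
pairs = (cohort.pet_stress, cohort.cmr_stress)
ba = bland_altman(pairs)
icc = icc_agreement(pairs)
tost = tost_equivalence(pairs, margin=EquivalenceMargins().mbf_participant)
print(f"bias = {ba['bias']:.2f} +/- {ba['sd']:.2f} mL/min/g, "
      f"ICC = {icc['icc']:.3f} ({icc['interpretation']}), "
      f"TOST p = {tost['p']:.2e}")
```

Output:

```
fitted MBF = 3.000 mL/min/g (truth 3.0), delay = 2 s, R^2 = 1.000000
bias = 0.29 +/- 0.62 mL/min/g, ICC = 0.587 (moderate), TOST p = 1.53e-07
```

The first line shows exact noise-free recovery of the generating flow and
bolus delay. The second runs the participant-level agreement analysis on a
39-subject simulated cohort: the recovered bias is close to the injected
0.31 mL/min/g, the absolute-agreement ICC is pulled below the correlation
by that bias, and the TOST declares equivalence within the 0.90 mL/min/g
margin.

A command-line surface wraps the same library calls:

```sh
qpcmr simulate-cohort --out cohort.csv --n 39 --seed 7
qpcmr agree cohort.csv --margin 0.9
qpcmr roc cohort.csv --threshold 2.3
qpcmr run --out results_dir --seed 7        # phantom pipeline end to end
```

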