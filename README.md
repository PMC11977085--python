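# renoct

Estimation of **single-kidney glomerular filtration rate (GFR)** and
**split renal function (SRF)** from non-contrast CT, for patients with
atrophic kidney or hydronephrosis.

Measuring single-kidney GFR normally requires dynamic renal SPECT
(⁹⁹ᵐTc-DTPA, Gates method) — costly, slow and radioactive. This package
implements an image-analysis alternative: given a non-contrast CT volume
and per-kidney label masks separating **renal parenchyma** (label 1) from
**hydronephrosis** (label 2), it estimates each kidney's GFR and its share
of total renal function, and quantifies how well those estimates agree
with reference measurements. Because no public reference dataset exists
for this task, the package ships a seeded **phantom-cohort simulator**
whose ground-truth GFR is generated from measurable image properties, so
the whole chain can be validated end to end.

## The estimation chain

For each kidney *k* with parenchymal region P and hydronephrosis region H:

1. **Preprocessing** — resample to a fixed grid, clip intensities to the
   kidney window (width 260 HU, level 60 HU), z-score normalize.
2. **Radiomics** — extract shape, first-order, GLSZM and NGTDM features
   from P and H on the original and square/logarithm/gradient/wavelet
   filtered volumes (`filter__region__family_Feature` columns).
3. **Selection** — drop features with manual-vs-automatic segmentation
   repeatability ICC(2,1) < 0.9, then remove the more globally correlated
   member of every feature pair with |Spearman ρ| > 0.9.
4. **rGFR** — elastic net on the retained features,
   `rGFR_k = β₀ + Σ βᵢ xᵢₖ`, hyperparameters by patient-grouped ten-fold
   cross-validation.
5. **rcGFR** — backward-eliminated multivariable linear regression of the
   reference GFR on {rGFR, age, sex, BMI} (p-to-stay 0.05).
6. **SRF family** —
   `rcSRF_k = 100·rcGFR_k / (rcGFR_L + rcGFR_R)`;
   `pSRF` regresses SRF on the kidney's fraction of total parenchymal
   volume; `hSRF` on its fraction of total hydronephrosis volume;
   `rcphSRF` combines {rcSRF, pSRF, hSRF} by backward MLR.
7. **Evaluation** — Pearson *r*, MAE/MSE, Lin's concordance correlation
   with Fisher-z CI, reduced-major-axis slope/intercept, Bland–Altman
   limits of agreement, Wilcoxon error comparisons, and diagnostic
   performance (AUC with DeLong CI, accuracy/sensitivity/specificity with
   exact Clopper–Pearson CIs) at five published health-status cutoffs
   (GFR ≤ 30, GFR < 10, SRF < 15, SRF < 45, SRF ≤ 60).

## Worked example

```python
from renoct.phantom import PhantomParams
from renoct.pipeline import (PipelineConfig, build_phantom_dataset,
                             run_training, run_inference, evaluate_estimates,
                             split_patients)

params = PhantomParams(n_patients=100, seed=202, gfr_noise_sd=1.0)
cfg = PipelineConfig(seed=202)
ds = build_phantom_dataset(params, cfg)
train_ids, test_ids = split_patients(ds.patient_ids, 0.6, seed=202)
result = run_training(ds.subset(train_ids), cfg)
est = run_inference(result, ds.subset(test_ids))
print(evaluate_estimates(est, ds.subset(test_ids).reference).round(3))
```

prints (held-out performance against the simulated truth):

```
               r    mae     mse    ccc
estimator
rGFR       0.938  3.321  16.119  0.935
rcGFR      0.976  2.037   6.742  0.975
rcSRF      0.981  1.908   4.903  0.977
pSRF       0.923  3.065  14.824  0.923
hSRF       0.321  7.401  94.044  0.281
rcphSRF    0.981  1.756   4.159  0.980
```

Reading the table: the radiomics-only `rGFR` already tracks the true
single-kidney GFR (r = 0.94); adding age (`rcGFR`) tightens it; among the
SRF estimators the hydronephrosis-share `hSRF` is by far the weakest, and
the combined `rcphSRF` is at least as accurate as every component
(smallest MAE). The backward elimination retains exactly {rGFR, age} for
rcGFR on this cohort.

A command-line interface wraps the same pipeline:

```bash
renoct simulate --n-patients 20 --seed 0 --out scratch/cohort
renoct run-all  --n-patients 20 --seed 0 --out scratch/run
renoct study    --n-patients 60 --replicates 3 --seed 0 --out scratch/study
```

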