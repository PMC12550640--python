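# fusionern

Models of adolescent anxiety development built on EEG-fMRI fusion measures
of error monitoring.

Error monitoring — the detection of one's own mistakes — is indexed by the
error-related negativity (ERN), a frontocentral negative EEG deflection
following erroneous responses, generated mainly in the dorsal anterior
cingulate cortex (dACC) and posterior cingulate cortex (PCC). EEG resolves
when error processing happens; fMRI resolves where. This package implements
a fusion of the two: cortical source (current density reconstruction, CDR)
maps on a tetrahedral mesh are differenced between error and correct
trials at each participant's ERN peak, every fMRI contrast voxel that
overlaps a mesh element is multiplied by that element's CDR-difference
value, and the products are averaged within a priori dACC and PCC regions
of interest. The resulting per-subject scores — for EEG alone, fMRI alone,
and the fusion — feed a longitudinal statistical chain for a two-wave
cohort of adolescents assessed at ages 13 and 15:

* a **latent change score (LCS) model** for anxiety, where each wave's
  latent anxiety factor is measured by parent-reported SCARED, adolescent
  SCARED and a binary diagnosis, loadings are constrained equal across
  waves, and the wave-15 factor decomposes as
  `eta_15 = eta_13 + delta` with the mean and variance of the change
  factor `delta` as the quantities of interest;
* per-ROI, per-modality **neural LCS models** (single indicator per wave,
  zero residual variance), whose factor scores are the baseline/change
  neural predictors;
* a **blockwise incremental-validity model** in the spirit of the
  phantom-variable parameterization: predictors enter as four ordered
  blocks (covariates + baseline anxiety; EEG; fMRI; EEG-fMRI fusion, each
  neural block with behavioral-inhibition interactions), and each block's
  semipartial multiple correlation `gamma_k` — hence its increment
  `delta R^2_k = gamma_k^2` — is estimated with a standard error and test;
* a **focused path model** for the winning modality, with **simple-slopes
  probing** of BI moderation at ±1 SD.

All models are estimated by full-information maximum likelihood (FIML) on
a purpose-built mean-and-covariance structure engine
(`fusionern.sem.SEMModel` / `SEMResults`), so participants with incomplete
data are retained. A configurable synthetic-cohort generator reproduces
the study's data structure end to end (planted ROI signals in mesh, volume
and epoched EEG; MAR missingness elevated for minority-status
participants), making every stage testable without any data download.

## Worked example

```python
from fusionern import (GeneratorConfig, generate_cohort, AnxietyLCS,
                       generate_path_cohort, FinalPathModel)

cfg = GeneratorConfig()                    # n = 176, reference values
cohort, truth = generate_cohort(cfg, seed=1)
res = AnxietyLCS.from_dataframe(cohort).fit()
print(res.params.loc[["delta~1", "delta~~delta"],
                     ["est", "se", "pvalue", "std_est"]].round(3))
print(res.fit_indices())
```

```
                 est     se  pvalue  std_est
param
delta~1       -1.024  0.451   0.023   -0.235
delta~~delta  18.943  4.331   0.000    1.000
FitIndices(chi2=7.528, df=12, rmsea=0.000, srmr=0.031, cfi=1.000)
```

On this cohort the anxiety change factor has an estimated mean of −1.02
SCARED points (95% CI roughly ±0.9; anxiety declined slightly from 13 to
15 in this draw) and a significant variance of 18.9, i.e. adolescents
differ substantially in how their anxiety changes. The model fits its 12
degrees of freedom well (RMSEA 0.000, SRMR 0.031, CFI 1.000).

Moderation by behavioral inhibition (BI) in the focused fusion path model:

```python
frame, _ = generate_path_cohort(cfg, seed=1)
path = FinalPathModel(frame).fit()
print(path.simple_slopes("fusion_dacc_13").round(3))
```

```
               slope     se      z  pvalue  ci_low  ci_high
moderator_sd
-1.0          -9.318  1.404 -6.635   0.000 -12.071   -6.565
 0.0           1.097  1.097  1.000   0.318  -1.054    3.248
 1.0          11.512  1.698  6.779   0.000   8.183   14.840
```

The crossover pattern: among adolescents with high BI (+1 SD), greater
13-year dACC fusion activation predicts *increasing* anxiety (slope
+11.5 SCARED points per SD); among low-BI adolescents the association
reverses (−9.3); at mean BI it is absent.

A one-command synthetic run (simulate → ERN scoring → fusion → LCS fits →
incremental model → report) is available from the shell:

```bash
fusionern simulate --out run/ --seed 1
fusionern score --out run/ --seed 1
fusionern fit --out run/ --seed 1
fusionern incremental --out run/ --seed 1
fusionern report --out run/
```

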