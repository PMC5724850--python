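# normes — kernel-robust CT emphysema scoring and its survival validation

Quantitative emphysema scoring on chest CT is usually the *density mask*:
the percentage of lung voxels below −950 HU,

&nbsp;&nbsp;&nbsp;&nbsp;ES = 100 · |{x ∈ L : I(x) < −950 HU}| / |L|.

That number is badly confounded by reconstruction settings: a sharp kernel
with thin slices pushes noisy parenchyma below the threshold and inflates
the score by tens of points, while a smooth kernel with thick slices
averages real lesions away. In a multi-center or screening setting, where
protocols vary, the raw score (**origES**) can say more about the scanner
than about the patient.

`normes` implements a normalized emphysema score (**normES**) that
harmonizes each scan before thresholding — resampling to a common 3 mm
slice thickness, rescaling the in-lung energy of each frequency band to a
reference-kernel profile, and discarding sub-5 mm² per-slice air clusters
as noise — together with the censored-survival statistics needed to show
that the harmonized score is the better mortality predictor: weighted
Kaplan-Meier curves and pairwise log-rank tests over emphysema severity
categories, IPCW time-dependent ROC/AUC, bootstrap confidence intervals
for AUC differences, and the continuous net reclassification improvement
(NRI) for censored data, all under the case-control sampling design
(every death kept, survivors subsampled and reweighted) typical of large
screening cohorts.

Everything is validated on digital chest phantoms with exact ground truth
and on simulated cohorts whose mortality depends on true emphysema extent
— no patient data are required or included. It is aimed at researchers in
quantitative CT imaging biomarkers and at anyone who needs
sampling-weighted time-dependent discrimination statistics with exact,
oracle-tested semantics.

## Worked example

`examples/01_score_phantom.py` builds a phantom with known emphysema,
renders it as a sharp-kernel scan, segments the lungs, and scores it both
ways:

```
true emphysema extent :  7.39 % of lung voxels
origES (sharp kernel) : 29.56 %  (32481 of 109864 voxels)
normES                :  5.41 %  (5 noise clusters removed)
```

The raw score is inflated fourfold above the truth because sharp-kernel
noise leaks below −950 HU; the normalized score lands near the true
extent. `examples/02_kernel_robustness.py` renders the *same* anatomy
under three kernels:

```
phantom  trueES |   origES by kernel    |   normES by kernel
                | soft  medium  sharp   | soft  medium  sharp
   0      9.76 |  6.12   8.48   31.75 |  9.79   7.64    7.18
   ...
median across-kernel std ratio normES/origES: 0.081
```

— the normalized score's spread across kernels is an order of magnitude
smaller. `examples/03_survival_validation.py` runs the survival side on a
simulated case-control cohort whose markers were measured by the imaging
pipeline:

```
year  AUC origES  AUC normES  diffAUC (95% CI)      NRI
  5      0.61        0.71     +0.10 (+0.04-+0.15)    64.4%
```

A diffAUC CI above zero means the harmonized score discriminates
5-year mortality significantly better than the raw score on the same
subjects.

## Command line

The same pipeline is scriptable from a shell:

```bash
normes segment --input scan.mha --output lungs.mha
normes profile --input ref1.mha --mask m1.mha --output profile.json
normes score   --input scan.mha --mask lungs.mha --mode both \
               --profile profile.json --output scores.json
normes phantom --seed 7 --out phantom_dir/
normes cohort-sim --seed 7 --n 2000 --out cohort.csv
normes validate --cohort cohort.csv --n-boot 6000 --seed 7 --out report/
normes demo --seed 7 --out demo/       # phantoms -> kernels -> tables
```

Scans are read from MetaImage (`.mha`/`.mhd`), NIfTI (`.nii`/`.nii.gz`)
or a single-series DICOM directory. Cohort CSVs carry
`id, time_days, event_all_cause, event_lung_cancer, weight` plus marker
columns.

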