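# radrep

Perturbation-based repeatability analysis of CT radiomic features, and
repeatability-stratified prognostic Cox modeling for esophageal squamous
cell carcinoma treated with definitive (chemo)radiotherapy.

## The problem

Radiomic prognostic models built from contrast-enhanced CT often transfer
poorly between hospitals.  One driver is feature *repeatability*: many of
the 6510 features routinely extracted from a tumor ROI (93 IBSI-style
statistics × 14 filtered images × 5 bin widths) are exquisitely sensitive
to small changes in patient positioning and tumor delineation.  Since
test–retest scanning is impractical for these patients, re-measurement is
*simulated*: each image/mask pair is perturbed by a small rigid rotation
plus supervoxel-based contour randomization, features are re-extracted, and
each feature's repeatability is scored with the one-way random-effects
absolute-agreement intraclass correlation coefficient

    ICC = (MSB − MSW) / (MSB + (k − 1)·MSW)

across the k repeats (original + perturbed).  Volume-independent features
are split at the median ICC into high- and low-repeatable halves, each half
runs through the same selection cascade (redundancy clustering → univariate
Cox screen → cross-validated LASSO-Cox) into a multivariate Cox model for
local recurrence-free survival (LRFS) and overall survival (OS), and the
two models are compared on a held-out validation site with Harrell's
C-index, time-dependent AUC, and Kaplan–Meier risk stratification.  The
scientific claim the pipeline probes: models built from high-repeatable
features keep their discrimination across institutions; models built from
low-repeatable features do not.

The package is for imaging scientists who want to run this workflow on
their own NIfTI cohorts, and it ships a synthetic two-site cohort generator
(phantom CT volumes, Table-1-like clinical covariates, Weibull
proportional-hazards outcomes, and a per-patient cross-site acquisition
shift) so every stage runs and is testable with no external data.

## Worked example

```python
from radrep.pipeline import reduced_scale_config, run_pipeline
from radrep.repeatability import summarize_icc

result = run_pipeline(reduced_scale_config(seed=1))

print(summarize_icc(result.repeatability, "bin_width")[["median"]])
print(result.summary_frame()[["endpoint", "group", "cohort", "c_index"]])
```

prints (seed 1; a 60 + 30 patient two-site cohort, 32³ phantoms, original +
8 wavelet sub-band filter bank, bin widths {8, 128}, 3 perturbation
realizations):

```
             median
bin_width
8.0        0.655545
128.0      0.433626

  endpoint group      cohort   c_index
0     lrfs  high       train  0.728867
1     lrfs  high  validation  0.621083
2     lrfs   low       train  0.726988
3     lrfs   low  validation  0.552707
4       os  high       train  0.702391
5       os  high  validation  0.573099
6       os   low       train  0.713932
7       os   low  validation  0.616959
```

Reading it: fine intensity bins (width 8) are markedly more repeatable
under perturbation than coarse ones (width 128), the median-ICC cutoff
splits the volume-independent features in half, and while the high- and
low-repeatable models are nearly indistinguishable on the training site,
the low-repeatable model tends to lose discrimination on the shifted
validation site (the contrast is stochastic at this scale — the stable
statement is over several seeds, where the median validation C-index of the
high-repeatable model exceeds the low-repeatable one for both endpoints).
`RadiomicsCoxModel(features, times, events).fit()` exposes the same
machinery as statsmodels-style Model/Results objects, with `summary()`
coefficient tables, `predict()` signatures and `evaluate()` reports;
`ClinicalCoxModel` and `FusionCoxModel` add the clinical and combined
models.

A command-line interface mirrors the stages:

```bash
radrep simulate --out cohort/ --n-train 60 --n-validation 30 --seed 1
radrep extract cohort/ --out features.csv
radrep run --out results/ --seed 1
```

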