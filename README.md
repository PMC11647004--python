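# dosurv

Survival-dosiomics modelling of late severe cardiac disease after
radiotherapy for childhood cancer.

Long-term survivors of childhood cancer carry an elevated risk of severe
cardiac disease decades after treatment, driven by the radiation dose
absorbed by the heart and by cardiotoxic chemotherapy. Because events are
late and rare, cohorts of survivors are heavily right-censored (~95%), and
the question of whether *texture* descriptors of the 3D dose distribution
(dosiomics) predict risk better than classical dose-volume summaries
requires survival models and censoring-aware error estimation, not plain
classification. `dosurv` implements that full analysis chain as a reusable,
tested pipeline, together with a synthetic cohort generator that reproduces
the statistical structure of such a cohort so every stage can be exercised
end to end without access to patient data.

## What it does

- **Synthetic cohorts** (`dosurv.synthetic`): voxel-scale heart dose fields
  (sums of randomly placed 3D Gaussian beams, 2 mm isotropic grid, whole
  heart + five subpart masks), multi-session radiotherapy courses, clinical
  and chemotherapy covariates, and a Weibull proportional-hazards event
  process `λ(t|X) = λ₀(t) exp(βᵀX)` calibrated to a 5% event / 95%
  censoring rate over a 60-year horizon, with ~45% of patients receiving
  zero heart dose.
- **Dose preprocessing** (`dosurv.preprocess`): voxelwise summation of
  sessions delivered within six months of the first treatment, and clipping
  of dose outliers above D₂ (the 98% quantile of the in-heart dose).
- **Dosiomics** (`dosurv.features`): per region (whole heart or each
  subpart) the mean dose; 24 dose-volume indicators (D₂…D₉₈, V₁…V₅₀);
  18 first-order statistics; and 93 full dosiomics features adding GLCM
  (24), GLRLM (16), GLSZM (16), NGTDM (5) and GLDM (14) texture features on
  a 0.5 Gy fixed-bin-width discretization.
- **Screening** (`dosurv.screening`): degenerate/duplicate removal;
  chi-square or Fisher association tests (p < 0.01) for the 42
  first-cancer diagnosis indicators; complete-linkage clustering of
  dosiomics features at distance 1 − Kendall τ with a 0.2 cut (so any two
  clustered features have τ ≥ 0.8), each cluster represented by its
  highest-hazard-ratio member from a multivariate Cox fit.
- **Models** (`dosurv.models`): Cox proportional hazards (Efron ties,
  Breslow baseline), Cox Lasso with the cross-validated one-standard-error
  penalty and unpenalized refit, Cox Bootstrap Lasso stability selection
  (100 bootstraps, likelihood-ratio-test penalty relaxation, 90% selection
  rule), and random survival forests; all behind one prediction contract
  `S(t|X)` + scalar risk score.
- **Evaluation** (`dosurv.metrics`, `dosurv.evaluation`): Harrell's C,
  IPCW-corrected C (with optional horizon truncation C_τ), Brier score
  BS(τ) and integrated Brier score over a 1–60-year yearly grid, with the
  censoring distribution estimated on training data only (reverse
  Kaplan–Meier, or a Cox model on the clinical covariates); stratified
  5-fold cross-validation; 100-bootstrap out-of-bag time-dependent error
  curves; rank-sum comparison of fold-wise metrics.
- **Pipeline** (`dosurv.pipeline`, `dosurv` CLI): the full workflow —
  generate → preprocess → extract → screen → fit → evaluate — over the 16
  model × feature-group combinations of the study design, from one master
  seed, byte-reproducibly.

## Worked example

```python
from dosurv.pipeline import ExperimentConfig, PipelineSpec, run_experiment

config = ExperimentConfig(
    seed=7,
    n_patients=1000,
    specs=[
        PipelineSpec(feature_group="mean_dose", model="cox"),
        PipelineSpec(feature_group="dose_volume", model="cox_lasso"),
    ],
    n_boot_selection=4,
    cohort_overrides={"min_region_shape": (8, 9, 9), "max_region_shape": (14, 15, 15)},
)
result = run_experiment(config, out_dir="results/demo")
print(result.summary[["spec", "harrell_c_mean", "ipcw_c_mean", "ibs_mean"]])
```

prints (seed 7; the generated cohort has 1000 patients and 47 events):

```
                                    spec  harrell_c_mean  ipcw_c_mean  ibs_mean
        cox__mean_dose__whole_heart__raw        0.660815     0.663351  0.037649
cox_lasso__dose_volume__whole_heart__raw        0.540480     0.514370  0.039446
```

Each row is one pipeline configuration evaluated by stratified 5-fold
cross-validation: `harrell_c_mean` is the average held-out concordance
(probability that the model ranks the earlier-failing patient of a
comparable pair as higher risk), `ipcw_c_mean` the censoring-corrected
version, and `ibs_mean` the integrated Brier score (mean squared error of
the predicted survival curves over 1–60 years; lower is better). The
mean-dose Cox model sits near C ≈ 0.66 — the generator's hazard really does
depend on heart dose and chemotherapy — while the 24-indicator Lasso, with
only ~38 events in each train split, pays for its extra dimensionality and
barely beats chance at this cohort size. At the desk-profile size (2000
patients) the same configurations reach C ≈ 0.65–0.70 and the ranking
tightens.

The same workflow is available from the shell:

```bash
dosurv simulate --n 200 --seed 1 --out cohort/
dosurv extract --cohort-dir cohort/ --group dosiomics_full --scale subparts --out features.csv
dosurv cv --seed 1 --profile desk --out results/
dosurv report --results results/
```

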