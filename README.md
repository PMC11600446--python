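# virtualckd

In-silico trial machinery for antihypertensive therapy in hypertensive
chronic kidney disease (CKD): a reduced-order whole-body cardiorenal model,
a pressure-threshold glomerulosclerosis model with a 120-day realization
delay, amlodipine PK/PD and RAS-blockade interventions, and a
virtual-population calibration loop that matches simulated patients to a
clinical cohort (synthetic stand-in generated from published summary
moments) in four dimensions: MAP and GFR, before and after 3 years of
calcium-channel-blocker (CCB) therapy.

## What is in the box

| module | role |
| --- | --- |
| `virtualckd.model_core` | vectorized daily-stepped cardiorenal engine (sodium balance, volume/pressure loop, renal network, TGF, RAS/aldosterone/ANP, LV mass) |
| `virtualckd.damage` | delayed, pressure-driven conversion of filtering to nonfiltering nephrons; damage-gain calibration |
| `virtualckd.pharmacology` | one-compartment oral amlodipine PK (closed-form repeated dosing), Emax vasodilatory PD, RAS blockade, salt interventions |
| `virtualckd.synthetic_cohort` | cohort generator reproducing the published MAP/GFR moments with derived pre/post correlations |
| `virtualckd.population` | parameter-space sampling, 1-SD/kNN selection, refinement loop, Mann-Whitney stopping rule |
| `virtualckd.protocols` | CKD induction (70% ± 10% over 9 months), 3-year control / CCB / CCB+RASi arms, endpoints and table summaries |
| `virtualckd.stats_report` | Mann-Whitney, Wilcoxon signed-rank, Spearman with exact small-sample conventions |

The nominal (unperturbed) model is normalized so its healthy operating
point — MAP 94 mmHg, GFR 129 mL/min, glomerular pressure 52 mmHg,
RBF 1,100 mL/min, ECFV 15 L, AngII 12 pg/mL — is an exact fixed point by
construction; the CKD state, drug responses and population spread emerge
from the model dynamics and parameter perturbations.

## CLI

```bash
virtualckd calibrate --seed 1 --scale desk --out pop/
virtualckd trial --arm ccb --population pop/ --out trial_ccb/
virtualckd trial --arm ccb_rasi --population pop/ --out trial_rasi/
virtualckd report --trials trial_ccb/ --trials trial_rasi/ --out table1.csv
```

`--scale desk` uses a 300-candidate pool against a 50-patient synthetic
cohort (minutes); `--scale full` uses 1,500 against 165. Real patient-level
data with the same schema (`patient_id, map_baseline, gfr_baseline,
map_3yr, gfr_3yr`) can be supplied via `--cohort-csv`. Results are tidy
CSV; progress goes to stderr.

## Configuration

All model constants, regulatory-curve shapes, PK/PD parameters and the
perturbable parameter space live in one YAML file
(`src/virtualckd/config/defaults.yaml`); pass an edited copy to the CLI via
`--config` or to `virtualckd.params.load_config`.
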