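# accelbehave

Behaviour classification from collar-mounted tri-axial accelerometers, built
around the domestic cat as a model quadruped.  The package addresses a
question that matters to anyone training machine-learning ethograms from
biologging data: **how do choices made during data processing — which derived
variables to compute, what recording frequency to keep, and whether to
balance behaviour durations in the training set — change the predictive
accuracy of a random-forest behaviour classifier, and how reliable are the
resulting activity budgets for free-ranging animals?**

Because the original collar recordings are not required, the package ships a
seeded synthetic-signal generator that emulates both calibration recordings
(seven labelled behaviours: rest, walk, trot, run, collar shake, feed, groom)
and multi-day free-ranging deployments dominated by rest (~22 h/day).  Every
experiment below runs end-to-end on this synthetic data.

## The method

Raw 40 Hz tri-axial acceleration (sway *x*, heave *y*, surge *z*, in g) is
decomposed into **static** acceleration (a centred 2 s running mean per axis
— the gravity/posture component) and **dynamic** acceleration (raw − static).
From these the 13 **base** variables are computed per sample:

* `accX/Y/Z`, `stX/Y/Z`, `dyX/Y/Z`
* `VeDBA = sqrt(dyX² + dyY² + dyZ²)` (vectorial dynamic body acceleration)
  and `VeDBAs`, its 2 s running mean
* attitude angles `Pitch = atan2(stZ, √(stX²+stY²))` and
  `Roll = atan2(stX, stY)` in degrees

The **extended** set adds eight running 2 s standard errors (of the raw axes,
the dynamic axes, VeDBA and VeDBAs) — 21 variables.  Averaging every
variable over non-overlapping whole seconds yields 1 Hz versions, and
capping every behaviour at 60 s of records ("standardised durations",
2400 records at 40 Hz, 60 at 1 Hz) yields balanced versions: a 2×2×2
factorial of eight training datasets.

Each dataset trains a random forest (500 trees, 3 candidate predictors per
split, terminal nodes ≥ 5, splits ≥ 10) on a random 60 % of records; the
remaining 40 % provide per-behaviour precision, recall and F-measure, with
out-of-bag error and Gini variable importances from the forest itself.

For free-ranging deployments, label streams become **activity budgets**
(percent of collared time per behaviour; 1 % of a day = 14.4 min).  A
hand-editable threshold **rule tree** applied to the first 15 min of each
hour stands in for manual classification, and its budgets are compared with
each forest's budgets by the single-rating absolute-agreement intraclass
correlation ICC(A,1) (two-way model, McGraw & Wong F-based 95 % CI),
categorised by the Koo & Li bands applied to the CI.

## Worked example

```python
import accelbehave as ab

result = ab.run_calibration_experiment(ab.ExperimentConfig(seed=1))
print(result.summary[["variant", "macro_f_complete", "oob_error_pct"]]
      .to_string(index=False))
```

prints (seed 1, default synthetic study):

```
                   variant  macro_f_complete  oob_error_pct
    base_inconsistent_40hz          0.819746       9.481209
extended_inconsistent_40hz          0.910786       5.167484
    base_standardised_40hz          0.849874      16.362613
extended_standardised_40hz          0.924021       8.716216
     base_inconsistent_1hz          0.652492      16.520211
 extended_inconsistent_1hz          0.661517      14.762742
     base_standardised_1hz          0.800720      32.242991
 extended_standardised_1hz          0.724672      34.579439
```

Reading the table: the extended/standardised/40 Hz dataset produces the most
accurate model (macro F ≈ 0.92); adding the running-SE variables helps at
40 Hz (+0.07–0.09 macro F); every 40 Hz model beats its 1 Hz counterpart;
and standardising durations raises macro F while also raising the OOB error
— the signature of a model that is less specialised to the abundant rest
class.  (`macro_f_complete` scores a behaviour the model never identifies
as 0 rather than dropping it.)

The same experiment from the shell:

```bash
accelbehave reproduce-all --seed 1 --out results/
```

writes `model_summary.csv`, `per_behaviour_metrics.csv`, `budgets.csv`,
`icc.csv`, and a seed manifest.  Individual stages (`simulate`, `featurize`,
`derive`, `train`, `evaluate`, `budget`, `compare`) are available as
subcommands sharing `--seed/--config/--out`.

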