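# ecgtb — ECG feature-transformation benchmark

`ecgtb` re-implements, as a reproducible benchmark, a classic study design in
ECG heartbeat classification: take 10-second single-lead ECG segments labeled
**Norm** (sinus rhythm), **AF** (atrial fibrillation), **PVC** (premature
ventricular contractions) or **APB** (atrial premature beats); reduce each
segment to six scalar features; expand each feature through seven algebraic
transforms — f, ln f, 1/f, √f, f², f³, asin f — and measure, feature by
feature, whether the transformation changes how well standard classifiers
separate normal from abnormal rhythm. The headline quantity is the
**D-value**: best-over-classifiers F1 of the transformed feature minus that
of the original, in percentage points.

The pipeline:

1. **Data** — a deterministic synthetic ECG generator (sum-of-Gaussians beat
   morphology, class-specific rhythm models), plus a minimal WFDB
   reader/writer (formats 16 & 212, MIT `.atr` annotations) and a strict
   10-s segmentation rule for real records.
2. **Preprocessing** — 0.5–30 Hz 8th-order Butterworth bandpass, zero-phase;
   every feature is computed on both the unfiltered and filtered signal.
3. **Features** — skewness `fS`, kurtosis `fK`, energy entropy `fE`,
   zero-crossing rate `fZ`, SNR `fN`, relative Welch band power `fR`
   (population moments; two definitions are deliberately literal — see
   `docs/methods.md`).
4. **Transforms** — the 7-fold map above with an explicit out-of-domain
   policy (undefined values become missing, arcsine clips with a count).
5. **Balancing** — none, random under-sampling (RUS), or 1-D SMOTE, per
   binary trial (Norm vs AF / PVC / APB).
6. **Classification** — KNN (k=10), a 10-neuron neural net, a quadratic SVM,
   a Gini tree (≤100 splits), and kernel-density naive Bayes; stratified
   70/30 split, 10-fold CV on the training side, held-out F1.
7. **Reports** — per-cell results, best-over-classifier D-value tables, and
   across-feature / across-balance aggregate tables.

## Quick start

```python
from ecgtb import StudyConfig, run_study, generate_dataset, feature_table

# generate labeled synthetic segments and inspect features
segments = generate_dataset({"Norm": 4, "AF": 4}, seed=0)
table = feature_table(segments)
print(table[["record", "label", "fS_filtered", "fZ_filtered", "fR_filtered"]])
```

```text
       record label  fS_filtered  fZ_filtered  fR_filtered
syn-Norm-0000  Norm       2.8716       0.6647       0.4819
syn-Norm-0001  Norm       1.3336       0.6464       0.4677
syn-Norm-0002  Norm       2.7884       0.6739       0.4872
syn-Norm-0003  Norm       2.8413       0.6586       0.4875
  syn-AF-0000    AF       1.8306       0.6422       0.5102
  syn-AF-0001    AF       2.2315       0.6456       0.5524
  syn-AF-0002    AF       2.3824       0.6461       0.5000
  syn-AF-0003    AF       2.3473       0.6425       0.4896
```

```python
# a small study grid: one trial, two features, three transforms
config = StudyConfig(
    class_counts={"Norm": 30, "AF": 15, "PVC": 14, "APB": 7},
    trials=("AF",), balances=("unbalanced",),
    features=("fS", "fZ"), transforms=("identity", "log", "reciprocal"),
    classifiers=("knn", "tree"), seed=0,
)
result = run_study(config)
print(result.dvalues[result.dvalues.variant == "filtered"]
      [["feature", "transform", "best_f1", "best_classifier", "d_value"]].round(1))
```

```text
feature  transform  best_f1 best_classifier  d_value
     fS   identity     72.7             knn      0.0
     fS        log    100.0             knn     27.3
     fS reciprocal    100.0             knn     27.3
     fZ   identity     90.9             knn      0.0
     fZ        log     75.0             knn    -15.9
     fZ reciprocal     75.0             knn    -15.9
```

Positive D-values mean the transformation helped that feature; at this toy
size the effect of a monotone transform is mostly which side of a noisy
decision boundary a few points land on, which is exactly what the full-size
study averages over.

## Command line

```sh
# full study grid on synthetic data (3780 result rows, ~40 min)
ecgtb run --source synthetic --seed 0 --out results/full

# leakage-safe variant: balance the training fold only
ecgtb run --seed 0 --out results/safe --split-first

# segment a directory of WFDB records into labeled 10-s windows
ecgtb segment --wfdb-dir /path/to/records --out segments.csv
```

`run` writes `results.csv`, `dvalues.csv`, `fig2_data.csv`, `fig4_data.csv`,
`dvalues_display.csv` and `manifest.json` into the output directory.

## Layout

```
src/ecgtb/
  segments.py       labeled ECG segment container
  synthetic.py      synthetic rhythm generator + log-normal feature model
  wfdb_io.py        WFDB read/write + 10-s segmentation
  preprocess.py     Butterworth bandpass
  features.py       the six scalar features
  transforms.py     the 7-fold transform map + domain policy
  balance.py        RUS and 1-D SMOTE
  classify_eval.py  the five classifiers, split/CV/F1 machinery
  report.py         study driver, D-values, aggregations
  cli.py            `ecgtb` command line
docs/methods.md     model, parameters, deviations, honesty notes
scripts/acceptance.py
tests/
```
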