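# eegcoh — EEG coherence biomarker pipeline

`eegcoh` is an end-to-end, fully testable implementation of a
coherence-based EEG biomarker workflow for two-group (case/control)
resting-state studies:

1. **Synthetic cohorts** with analytically *planted* band-limited
   coherence, so every downstream stage has a ground truth
   (`eegcoh.synthetic`, EDF interchange in `eegcoh.edf`).
2. **Preprocessing** — 10 s settle discard, 50 Hz notch, 0.5–44 Hz
   band-pass, five 30 s sections per subject, class-balanced section
   sampling, strictly subject-level train/test splits with leakage guards
   (`eegcoh.preprocess`).
3. **855 coherence features** — magnitude coherence from Hann-windowed 1 s
   epochs (spectra averaged before the ratio), band-averaged over
   delta/theta/alpha/beta/gamma for all 171 pairs of the 19-channel 10-20
   montage (`eegcoh.connectivity`, `eegcoh.montage`).
4. **Wrapper feature selection** — sequential floating forward selection
   scored by 10×10 repeated subject-level CV of an RBF-SVM
   (γ = 5.1053), with a central-ROI gamma candidate pool and a
   one-standard-error size rule (`eegcoh.selection`).
5. **Evaluation** — held-out-subject metrics, subject-level permutation
   test, Platt calibration with Brier/ECE, covariate subgroup reruns
   (`eegcoh.evaluate`, `eegcoh.pipeline`).
6. **Interpretation** — exact and kernel Shapley values (hand-rolled, with
   an enumeration oracle) and a t-SNE embedding (`eegcoh.shapley`,
   `eegcoh.interpret`).
7. **Cross-domain tools** — 64→19 channel montage mapping, fold-count
   sweep / learning-curve trend, and TrAdaBoost instance transfer
   (`eegcoh.transfer`).

The full model specification is in [`docs/methods.md`](docs/methods.md).

## Worked example

```python
from eegcoh.connectivity import feature_columns
from eegcoh.pipeline import run_experiment, synthesize_features
from eegcoh.preprocess import balanced_sample_indices, subject_split
from eegcoh.selection import restrict_candidates, sffs
from eegcoh.synthetic import CohortSpec

# 30 cases vs 30 controls, gamma coherence 0.8 vs 0.3 planted on the
# five signature pairs Fz-Cz, Pz-P4, Fz-C3, Cz-P4, Cz-Pz.
spec = CohortSpec(n_cases=30, n_controls=30, fs=250.0, seed=2)
table = synthesize_features(spec)          # (subjects x 5 sections) x 855
names = feature_columns(table)

groups = (table.drop_duplicates("subject_id")
               .set_index("subject_id")["group"].to_dict())
plan = subject_split(groups, test_fraction=0.10, seed=2)
train = table[table["subject_id"].isin(plan.train_subjects)]
rows, _ = balanced_sample_indices(train["subject_id"].to_numpy(), groups, seed=3)
balanced = train.iloc[rows]

trace = sffs(balanced[names].to_numpy(), balanced["group"].to_numpy(),
             balanced["subject_id"].to_numpy(),
             candidates=restrict_candidates(names),   # central-ROI gamma pairs
             max_k=5, repeats=10, k_folds=10, seed=2)
subset, cv = trace.best_at(5)
signature = sorted(names[i] for i in subset)
# -> ['Cz-P4:gamma', 'Cz-Pz:gamma', 'Fz-C3:gamma', 'Fz-Cz:gamma', 'Pz-P4:gamma']
#    all five planted pairs recovered; wrapper CV accuracy 1.000

result = run_experiment(table, signature=signature, permutation_B=1000, seed=2)
print(result.report.accuracy)        # 1.0 on held-out subjects' sections
print(result.report.permutation_p)   # 0.002 (add-one permutation p-value)
print(result.report.brier)           # 0.003
```

(Numbers above are from the stated seed; see `scripts/acceptance.py` for a
full reproducible report.)

## Command line

The `eegcoh` console script chains the same stages over files:

```sh
eegcoh simulate   --config cohort.yaml --out raw/          # EDF + labels.csv
eegcoh preprocess --in raw/ --labels raw/labels.csv --out cache/
eegcoh features   --cache cache/ --out features.csv
eegcoh select     --features features.csv --roi F3,Fz,Cz,Pz --band gamma \
                  --max-k 5 --out selection.json
eegcoh evaluate   --features features.csv --signature Fz-Cz:gamma,... \
                  --permutations 1000 --out report.json
eegcoh transfer   --source source.csv --target features.csv \
                  --signature ... --kmin 2 --kmax 24 --out transfer.json
eegcoh explain    --features features.csv --signature ... --out shap.json
```

`cohort.yaml` holds `CohortSpec` fields, e.g. `{n_cases: 30, n_controls: 30,
seed: 1}`.

## Layout

```
src/eegcoh/     library modules (montage, synthetic, edf, preprocess,
                connectivity, selection, evaluate, shapley, interpret,
                transfer, pipeline, cli)
tests/          unit, property-based and acceptance tests
scripts/        acceptance.py end-to-end report
docs/           methods.md — generative model and algorithm specification
```
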