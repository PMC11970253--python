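# glucodyn

Modelling daily continuous-glucose-monitoring (CGM) profiles with a
masked-token transformer encoder, plus everything around it: a synthetic
CGM cohort simulator, CSV parsing and day-splitting, glucose tokenization
with TF-IDF-weighted masking, self-supervised pretraining, an imputation
benchmark against linear/KNN baselines, supervised fine-tuning for
screening labels, cosine-similarity subtyping of non-diabetic samples,
glycemic variability metrics, and an autoregressive postprandial
glucose predictor driven by meal macronutrients.

Everything runs on CPU: the neural models (transformer encoder, gated
recurrent diet model) are implemented on a small NumPy reverse-mode
autodiff layer in `glucodyn.nn`, so no deep-learning framework is needed.

## Layout

| module | what it does |
| --- | --- |
| `glucodyn.simulate` | synthetic cohorts: circadian baseline, gamma-kernel meal excursions, AR(1) noise, missingness, labels, meal logs |
| `glucodyn.io` | CGM/label/meal CSV dialects, calendar-day splitting onto the 288-slot 5-minute grid, clipping to [40, 300] mg/dL, downsampling |
| `glucodyn.tokenizer` | 260-level glucose vocabulary (+PAD/CLS/MASK), 289-token day sequences, TF-IDF mask weights with hypo/hyper boost, mask plans |
| `glucodyn.encoder` | 4-block x 8-head transformer (d_model 128), sinusoidal positions, masked-token head, day/sample embeddings, checkpoints |
| `glucodyn.pretrain` | pretraining loop, linear/KNN imputation baselines, MAE report stratified by hypo/eu/hyper range |
| `glucodyn.finetune` | task-specific transformer layer + classification head, freeze policies, accuracy / one-vs-rest AUROC evaluation |
| `glucodyn.subtype` | two-stage hierarchical clustering into {Normal, Pre_Ia..Pre_IIc}, argmax mean-cosine-similarity assignment |
| `glucodyn.metrics` | mean/SD/CV, TIR/TAR/TBR, MAGE, eA1C, HBGI, fasting SD, postprandial rate, AUC, HV flagging, AR order selection |
| `glucodyn.diet` | pulse-encoded meal input, LSTM teacher+autoregressive rollout, MSE training, in-silico meal-ratio perturbations |
| `glucodyn.cli` | `glucodyn` command with subcommands for the full pipeline |

## CLI

```bash
glucodyn simulate --n-subjects 10 --days-per-subject 3 --seed 7 --out-dir runs/sim
glucodyn tokenize --cgm-csv runs/sim/cgm.csv --out-dir runs/tok
glucodyn pretrain --cgm-csv runs/sim/cgm.csv --epochs 3 --out-dir runs/pre
glucodyn impute-eval --cgm-csv runs/sim/cgm.csv --checkpoint runs/pre/checkpoint --out-dir runs/imp
glucodyn embed --cgm-csv runs/sim/cgm.csv --checkpoint runs/pre/checkpoint --out-dir runs/emb
glucodyn classify --cgm-csv runs/sim/cgm.csv --labels-csv runs/sim/labels.csv \
    --checkpoint runs/pre/checkpoint --out-dir runs/cls
glucodyn subtype-fit --embeddings-csv runs/emb/sample_embeddings.csv \
    --labels-csv runs/sim/labels.csv --out-dir runs/sub
glucodyn metrics --cgm-csv runs/sim/cgm.csv --out-dir runs/met
glucodyn diet-train --cgm-csv runs/sim/cgm.csv --meals-csv runs/sim/meals.csv \
    --embeddings-csv runs/emb/sample_embeddings.csv --out-dir runs/diet
```

Every command logs a JSON event (config hash + package version) to
`run_log.jsonl` in its output directory and never mutates its inputs.

## Data formats

- CGM CSV: `subject_id,timestamp,glucose_mg_dl` (ISO-8601, one row per measurement)
- Labels CSV: `subject_id,label`
- Meal CSV: `subject_id,timestamp,kcal,carb_g,protein_g,fat_g,fiber_g`
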