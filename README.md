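# psychocat

Item-response-theory tooling for screening questionnaires: Partial Credit
Model (PCM) calibration on structurally incomplete response matrices,
outfit-based item filtering, differential-item-functioning (DIF) screening,
a Bayesian computerized adaptive test (CAT) with Fisher-information item
selection and a clinical-decision stopping rule, and ROC-based cutoff
selection and validation — plus a synthetic-cohort generator so the whole
design can be simulated end to end without any external data.

## What it does

1. **synth** — generates an item bank (one long core block A answered by
   everyone, three short blocks B/C/D each answered by about a third of the
   cohort), a right-skewed latent-trait population, PCM responses, a
   criterion sum score over block A and a "clinical" flag for scores
   strictly above the cohort's 90th percentile. Uniform DIF can be injected
   into any item for power studies.
2. **pcm** — marginal-maximum-likelihood EM calibration of the PCM over a
   fixed quadrature grid (normal latent density, mean/variance estimated;
   identification by re-centering item locations to zero), EAP and
   weighted-likelihood person scoring, per-item outfit mean-squares, the
   person separation index, and an outfit < 1.7 retention filter with a
   one-pass refit.
3. **dif** — per item, nested multinomial logistic regressions of the raw
   item score (trait only vs trait + gender + ethnicity + interaction); an
   item is flagged when the added block is significant and raises
   Nagelkerke R² by more than 3.5 percentage points. Flagged items are
   reported, not removed.
4. **cat** — simulates adaptive testing by replaying stored answers: the
   first item is random (seeded), every later item maximizes Fisher
   information at the current estimate, and the trait posterior (shifted
   lognormal prior on a grid) is refreshed after each answer. Stopping
   rules: fixed length, target precision, or clinical decision (stop once
   the 95% CI clears the cutoff; undecided at the item cap).
5. **evaluation** — calibration/validation splits, rank-based AUC with a
   stratified bootstrap CI, cutoff selection at a target specificity,
   sensitivity/specificity with Wilson CIs, Cohen's kappa, and CAT
   efficiency summaries (items to decision, decided-by-k curve, where the
   undecided sit).
6. **pipeline** — the full study: generate (or load) → split → calibrate →
   filter → DIF → 30-item CAT on the calibration half → cutoff at 0.90
   specificity → fixed-length comparison table → decision-rule CAT on the
   validation half → reports. Everything is seeded and deterministic.

## CLI

```sh
psychocat synth --n-persons 2041 --design four_block --seed 1 --out data/
psychocat calibrate --responses data/responses.csv --bank data/bank.csv \
    --outfit-threshold 1.7 --out calibration.json
psychocat dif --responses data/responses.csv --calibration calibration.json \
    --persons data/persons.csv --out dif.csv
psychocat cat --responses data/responses.csv --calibration calibration.json \
    --rule decision --cutoff -1.9 --confidence 0.95 --max-items 100 \
    --seed 1 --out cat/
psychocat evaluate --traces cat/cat_traces.csv --persons data/persons.csv \
    --criterion clinical --cutoff -1.9 --out report.json
psychocat full --config study.yaml --out outputs/   # or just --seed N
```

`psychocat full` writes every intermediate (`bank.csv`, `persons.csv`,
`responses.csv`, `calibration.json`, `dif.csv`, `cat_traces.csv/json`,
`roc.csv`) plus `study_report.json`.

## Notes on conventions

- "Clinical" is *strictly above* the linear-interpolation 90th percentile
  of the criterion score; ties resolve to not-clinical.
- Cutoff selection returns the smallest observed score whose rule
  `positive ⇔ score ≥ cutoff` reaches the target specificity, maximizing
  sensitivity under that constraint.
- The decision CI is θ̂ ± z·SE from the grid posterior (z = 1.96 at 95%);
  item-selection ties break toward the smallest item id.
- Interior categories never observed during calibration are collapsed
  downward (with a warning) and the collapse map is applied consistently
  downstream.
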