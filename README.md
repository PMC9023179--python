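# periopredict

A serial surgery-duration and anesthesia-emergence-duration prediction
pipeline for tabular perioperative records, built around:

- **`periopredict.datagen`** — a seeded synthetic perioperative cohort
  generator (24 input attributes per system, imbalanced 4-class
  surgery-duration labels, monotone dependence of emergence duration on
  surgery duration). No real hospital data is required anywhere.
- **`periopredict.preprocess`** — the automatic preprocessing pipeline:
  cleaning, min–max normalization onto [0.1, 0.9], right-closed duration
  binning into 4 classes, one-hot target coding (1000/0100/0010/0001),
  automatic class balancing (each class replicated by the integer multiple
  that brings it closest to the largest class, ties to the larger
  multiple), ±0.03 uniform-noise enrichment by a multiple M, and a
  60/20/20 train/test/validation split. Both the balance-before-split
  (`paper_faithful`) and split-before-balance (`leakage_safe`) orderings
  are supported.
- **`periopredict.network`** — a seeded NumPy MLP core: configurable
  hidden layers/width/dropout, mini-batch Adam (batch 100) on softmax
  cross-entropy, deterministic under a seed (training for E epochs is a
  prefix of training for 2E).
- **`periopredict.selection`** — the replicate grid-search protocol:
  R seeded replicates per architecture, Mean/Std/Max/Min summaries over
  train/test/validation, one-tailed pooled-variance t-tests at α = 0.05,
  runtime accounting, and the accuracy-then-runtime selection rule with a
  full decision trace; plus the dropout and enrichment follow-up
  experiments.
- **`periopredict.serial`** — the two-stage serial system: the stage-1
  predicted surgery-duration class replaces the A24 input of the stage-2
  emergence predictor (through stage 2's own normalization map), reported
  as a three-way accuracy comparison against the oracle-fed stage 2.

## CLI

```bash
periopredict simulate --n 2000 --seed 1 --out cohort.csv
periopredict preprocess --system surgery --multiple 3 --mode paper_faithful \
    --seed 1 --in cohort.csv --out prep/
periopredict train --arch 4-256 --epochs 200 --seed 1 --data prep/ --out model.npz
periopredict grid --seed 1 --out gridrun/        # simulate+preprocess+grid+select
periopredict serial --seed 1 --out serialrun/    # train both stages, evaluate cascade
periopredict run --config config.yaml --seed 1 --out run/   # full declared stage list
periopredict report --out run/                   # print the run manifest
```

`run` executes the stage list declared in a YAML config (defaults in
`periopredict.cli.DEFAULT_CONFIG`); every artifact directory contains a
`manifest.json` recording the config snapshot, master seed, per-stage
record counts, and wall-clock times. All randomness derives from the
single master seed.

Note: grid replicate accuracy/loss summaries are bit-reproducible under a
fixed seed; the architecture *selection* step consults measured wall-clock
runtimes, so its demotion decisions can vary across machines and runs.

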