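# p300decode

Decoding pipeline for P300 oddball EEG experiments: a synthetic oddball
paradigm simulator, continuous-signal preprocessing, a compact
depthwise-separable CNN classifier trained with focal loss, a
logistic-regression benchmark on windowed ERP means, gradient saliency-map
attribution, and the spatio-temporal statistics used to quantify
training-related P300 latency shifts.

Everything is driven by a seeded synthetic-data generator that emulates the
paradigm (8 electrodes C3/Cz/C4/CPz/P3/Pz/P4/POz at 250 Hz, epochs of
8 × 201 samples covering −100..+700 ms, exactly 1 target per 8-trial run,
a parietal-maximal P300 whose social-scenario latency drifts across sessions,
and a frontocentral scenario-dependent P200), so every analysis stage can be
validated against known ground truth.

## Layout

| module | what it does |
| --- | --- |
| `p300decode.sim` | oddball dataset generator (components, scenarios, 1/f noise, subject jitter) |
| `p300decode.preprocess` | zero-phase 50 Hz notch + 2–30 Hz band-pass, segmentation, target-neighbour censoring, detrend + crop to 8 × 201 |
| `p300decode.nn` | the CNN (temporal conv → depthwise spatial conv → separable conv → dense) in pure NumPy with analytic backprop, Adam, focal loss, LOSO evaluation |
| `p300decode.baseline` | logistic regression on 350–400 ms ERP-mean features + model comparison t-test |
| `p300decode.saliency` | input-gradient saliency maps, spatial/temporal profiles, 100 ms/5 ms sliding-window interval search, latency-trend correlation |
| `p300decode.stats` | grand averages, P200/P300 amplitude measures, closed-form paired t and Pearson |
| `p300decode.pipeline` / `p300decode.cli` | seeded, cached stage orchestration and the `p300decode` command |

The CNN is implemented directly in NumPy (no DL framework): the model is
small (~3k parameters) and the analytic input-gradient path the saliency
analysis needs is validated against finite differences in the test suite.

## CLI

```bash
# end-to-end demo run (simulate -> preprocess -> train -> baseline -> saliency -> report)
p300decode all --out runs/demo --seed 1 --subjects 2

# individual stages, resumable from cached outputs
p300decode simulate --out runs/demo --seed 1
p300decode train    --out runs/demo --gamma 2 --epochs 10
p300decode saliency --out runs/demo --electrode Pz --width 100 --step 5
p300decode report   --out runs/demo
```

Stage outputs are plain files under `--out`: an epochs container
(`epochs.npz` + `metadata.tsv` + `epochs.json`), delimited metric and profile
tables, and a final `report/report.json`. A YAML config
(`--config run.yaml`) holds the full run configuration; command-line flags
override it.

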