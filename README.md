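# ktgel

A k-tournament grasshopper extreme learner: an extreme learning machine (ELM)
whose randomly initialized input-weight matrix is pruned by a binary
grasshopper-style swarm optimizer with k-tournament attractor selection.
Pruning individual connections simultaneously yields hidden-node reduction
(a node dies when all of its incoming weights die) and implicit feature
selection (a feature dies when all of its outgoing weights die).  The package
also ships the surrounding pipeline: window-level force-myography (FMG)
feature extraction, a wrapper feature selector, micro-averaged evaluation
metrics, split/CV protocols, and a seeded synthetic FMG generator that stands
in for undeposited sensor recordings.

## Modules

| module | contents |
| --- | --- |
| `ktgel.elm` | ELM training/prediction: random uniform [-1, 1] hidden layer, Moore–Penrose solve of the output weights, JSON/CSV I/O |
| `ktgel.swarm` | Generic binary maximizer: social forces, linear exploration coefficient, k-tournament selection, S-shaped transfer binarization |
| `ktgel.wrapper` | Feature-mask wrapper selection with ELM cross-validation fitness |
| `ktgel.pruning` | Weight masks over the ELM input layer, masked fitness, compaction, the full pruned-ELM trainer |
| `ktgel.features` | Per-channel window statistics (min, max, RMS, var, std, mean) and min–max normalization |
| `ktgel.synth` | Seeded multi-channel gesture-signal generator with subject jitter, AR(1) noise and a class-ambiguity knob; `low`/`middle`/`high` presets |
| `ktgel.evaluation` | Confusion matrices, micro/macro precision-recall, stratified holdout and k-fold |
| `ktgel.cli` | `ktgel` command-line workbench |

## CLI

```bash
# generate a synthetic recording session and extract features
ktgel synth --preset middle --subjects 10 --reps 10 --seed 1 \
    --out raw.csv --manifest trials.csv
ktgel extract --raw raw.csv --manifest trials.csv --out features.csv

# plain ELM / wrapper feature selection / pruned learner
ktgel train-elm --input features.csv --hidden 200 --seed 1 --out elm.json --report elm_report.json
ktgel select-features --input features.csv --hidden 200 --pop 10 --iters 20 --k 3 --seed 1 --out selection.json --trace wrapper_trace.csv
ktgel train-ktgel --input features.csv --hidden 200 --pop 10 --iters 20 --k 3 --seed 1 --out model.json --trace trace.csv

# evaluate any saved model, or run the whole comparison loop from a config
ktgel evaluate --model model.json --input features.csv --out report.json
ktgel compare --config config.yaml --out-dir results/exp1
```

`compare` executes synth → features → split → {ELM | KTGEL} → eval, writing
`elm_report.json`, `ktgel_report.json`, `trace.csv`, `comparison.csv` and a
`manifest.json` with the config hash, derived stage seeds and versions.
Every stochastic stage uses `global_seed + fixed_offset` (synth +0, split
+100, ELM +200, wrapper +300, pruning search +400), so identical configs
reproduce byte-identical artifacts.  Example config:

```yaml
seed: 1
preset: middle
subjects: 10
reps: 10
hidden: 200
pop: 10
iters: 15
k: 3
folds: 3
test_frac: 0.2
feature_selection: false
```

## Notes

* Search scale: the pruning mask has `n_features x n_hidden` bits
  (48 x 3000 = 144,000 at full scale); runs at that scale need patience.
  Tests and examples use small hidden layers.
* `optimize` sharpens the transfer input by the decaying coefficient c
  (`u = (v - 1/2) / c`) so the swarm explores early and freezes late;
  `raw_transfer=True` restores the plain transfer-of-displacement rule.
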