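# fangmark

A desk-scale pipeline for snakebite mark image classification and
edge-deployment planning:

- **synthetic_data** — seeded generation of two visually separable bite-mark
  classes (`cobra`: two fang punctures; `other`: a double tooth row) plus
  per-state epidemiology tables, so everything runs without external data.
- **preprocess** — contrast enhancement by weighted exposure fusion (a
  camera-model brightness transform, illumination weight maps, and
  entropy-driven exposure-ratio selection), canonical resizing, and
  flip/zoom augmentation.
- **classifier** — the CNN calculus (valid cross-correlation, max pooling
  with floor-division shapes) in pure numpy, plus a seeded training harness
  with a tiny two-conv-block backbone trainable offline on one CPU. Named
  transfer-learning backbones (vgg16/vgg19/resnet101) are accepted in
  configuration but raise a labelled error when pretrained weights are
  unavailable.
- **evaluation** — confusion matrix (cobra positive), sensitivity,
  specificity, accuracy, and rank-based AUC.
- **edge_planner** — the profit objective
  `1/k − (k/K − (p+d)/n) − C(k)` for the per-state edge-node count,
  maximized exhaustively (oracle), by particle swarm optimization, or by
  quantum-behaved PSO (contraction–expansion sampling around a local
  attractor).
- **retrain_sim** — simulator of the cloud–edge feedback loop: edges
  classify incoming cases, confirmed misclassifications return to the cloud
  dataset, and the cloud model is warm-start retrained each round.
- **pipeline / cli / config** — YAML-configured orchestration of the whole
  flow with one global seed deriving per-stage seeds.

## CLI

All stages are subcommands of the `fangmark` entry point:

```sh
fangmark synth --n-cobra 30 --n-other 30 --seed 0 --out data/
fangmark enhance --in data/ --out enhanced/
fangmark augment --in enhanced/ --out augmented/ --seed 0
fangmark train --data augmented/ --backbone tiny --epochs 15 \
    --lr 0.001 --batch 32 --seed 0 --out model.npz
fangmark evaluate --model model.npz --data augmented/ --out metrics.json
fangmark plan-edges --epi states.csv --budget 20 --cost-per-node 0.01 \
    --method qpso --seed 0 --out plan.json
fangmark simulate-loop --seed 0 --out rounds.csv
fangmark run-all --seed 0 --out pipeline_out
```

`run-all` accepts a YAML config (`--config pipeline.yaml`) whose sections
(`generator`, `preprocess`, `augment`, `train`, `evaluation`, `planner`,
`loop`) override the defaults; unknown keys are rejected with the offending
dotted key name.

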