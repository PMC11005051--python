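# hyperqsar

Task-conditioned QSAR modeling with hypernetworks.  A hypernetwork maps a
protein-target embedding — optionally enriched against an associative memory
of training-target embeddings — to the full parameter vector of a small
per-target feed-forward network that predicts drug–target interaction
strength from the drug embedding.  Because the per-target network is a pure
function of the target embedding, the model performs zero-shot inference on
protein targets never seen during training.

Main ingredients:

- **Context module** (`hyperqsar.context_module`): a continuous
  modern-Hopfield retrieval layer.  The query target embedding attends over
  the layer-normalized embeddings of all training targets and retrieves an
  enriched embedding (softmax attention with scale `beta`; query/key and
  optional value projections and all LayerNorm affines are trained
  end-to-end).
- **Hypernetwork + main network** (`hyperqsar.hyper_qsar`): a fully
  connected trunk with one linear head per weight matrix / bias vector of
  the main network.  Heads follow a principled weight initialization: the
  head for a main-net weight matrix of fan-in `d_in` gets variance
  `g / (2 * d_in * c_in * var_t)` (relu gain `g = 2` on hidden layers) and
  bias heads get `1 / (2 * c_in * var_t)`, so the predicted parameters give
  the main network a distribution-preserving forward pass at initialization.
  `var_t` is measured empirically at the head input.
- **Episodic training** (`hyperqsar.training`): meta-batches of targets,
  each paired with a mini-batch of drug interactions (sampling with
  replacement only when a target has too few), oversampling of
  underrepresented targets, Adam with decoupled weight decay,
  plateau learning-rate decay and early stopping on validation performance
  (concordance index for regression, MCC for classification).
- **Chemogenomic splits** (`hyperqsar.splitting`): random, temporal,
  leave-cluster-compound-out (k-means over Morgan fingerprints), leave-
  protein-out / cold-target, cold-drug and cold, with machine-checkable
  leakage audits (`validate_split`).
- **Metrics** (`hyperqsar.metrics`): MCC, tie-corrected AUC, concordance
  index (tied predictions count 1/2, tied truths excluded from the
  normalizer), ROC enrichment at fixed FPR thresholds, MSE/MAE.
- **Synthetic benchmark** (`hyperqsar.synthetic_data`): embeddings and
  labels generated so each target's labeling function is an exact (linear)
  function of its embedding — zero-shot transfer is possible by
  construction and closed-form recovery oracles exist.

Everything runs on numpy; a small reverse-mode autodiff core
(`hyperqsar._tensor`) provides end-to-end gradients.

## CLI

```bash
# generate a synthetic benchmark (TSV interaction table + embedding stores)
hyperqsar synth --n-targets 30 --n-drugs 40 --d-target 16 --d-drug 16 \
    --noise-sd 0.1 --seed 1 --out-prefix bench

# hold out whole protein targets (zero-shot split) and audit leakage
hyperqsar split --interactions bench.interactions.tsv --strategy lpo \
    --fractions 0.8,0.1,0.1 --seed 1 --out split.json

# train, predict, evaluate
hyperqsar train --interactions bench.interactions.tsv \
    --drug-embeddings bench.drugs.tsv --target-embeddings bench.targets.tsv \
    --split-file split.json --max-epochs 100 --seed 1 \
    --checkpoint model.json --history history.csv
hyperqsar predict --checkpoint model.json \
    --interactions bench.interactions.tsv \
    --drug-embeddings bench.drugs.tsv --target-embeddings bench.targets.tsv \
    --out predictions.tsv
hyperqsar evaluate --predictions predictions.tsv --threshold 0.0 \
    --out metrics.json
```

Exit codes: 0 success, 2 usage error, 3 data-validation failure,
4 numerical failure.

File formats are plain text throughout: TSV/CSV interaction tables
(`drug_id`, `target_id`, `label`, optional ISO `date`), TSV embedding
stores (id column + one column per dimension; `.npz` also accepted),
JSON split specs and model checkpoints.

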