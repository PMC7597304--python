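# bnaf — Boolean-network antifragility

Measures antifragility of synchronous Boolean network models of gene
regulation and uses original-minus-mutant antifragility curves to predict the
four-class robustness/evolvability response of a network to mutations,
validated against exhaustive attractor-based ground truth.

## What it does

- **network_core** — synchronous Boolean networks (nodes, per-node input
  lists, explicit truth tables), dynamics, Kauffman N-K random network
  generation, and a BoolNet-style text format (plus an exact truth-table
  dialect).
- **attractor_analysis** — exhaustive enumeration of attractors and basins of
  attraction over all 2^N states (node cap 26), with attractor counts, mean
  cycle length, and normalized basin entropy.
- **mutations** — the four elementary internal perturbations (add / delete /
  re-point a regulatory link, flip one truth-table bit) and balanced sampling
  of pairwise-distinct mutant cohorts.
- **robustness_classification** — four-class labels (not robust & not
  evolvable, not robust & evolvable, robust & not evolvable, robust &
  evolvable) from attractor-set comparison, class distributions, and Cramér's
  V association with mutation kind.
- **antifragility** — complexity `C = 4·E·(1−E)` from Shannon entropy of a
  late observation window, the external-perturbation protocol (flip X random
  nodes every O steps, observe `t = T+1..2T`), fragility `−Δσ·Δx` per X,
  per-network fragility curves, and 30-point interpolated difference curves.
- **prediction_pipeline** — labelled 30-point feature datasets, SMOTE/ADASYN
  oversampling, 1-D CNNs (simple: 2 conv + 1 pool; complex: 4 conv + 2 pool;
  pure numpy, no GPU framework needed), nested k-fold cross-validation with
  inner-loop AUC model selection, and evaluation with accuracy, confusion
  matrix, PR curves / average precision, and prevalence baselines.
- **cli_workflow** — end-to-end experiment orchestration with seeded
  substreams and a hashed artifact manifest.

## CLI

All functionality is exposed through the `bn` command:

```bash
bn generate --n 8 --k 2 --seed 1 --out net.table      # random N-K network
bn step --net net.table --state 10110011 --steps 5    # trajectory
bn attractors --net net.table --out report.json       # exhaustive landscape
bn mutate --net net.table --n 100 --seed 2 --out-dir mutants/
bn classify --net net.table --mutants-dir mutants/ --out labels.tsv
bn assoc --labels labels.tsv                          # contingency + Cramér's V
bn fragility --net net.table --t 200 --s 1000 --seed 3 --out curve.tsv
bn diffcurve --orig curve.tsv --mut mutant_curve.tsv --n 8 --out diff.tsv
bn predict train --features features.tsv --seed 4 --out model
bn predict eval --model model --features features.tsv --report report.json
```

A full experiment (networks → mutants → labels → curves → features → CNN →
report) runs from a YAML config:

```yaml
# exp.yaml
out_dir: out
seed: 11
rbn_count: 5      # or network_files: [net1.bnet, ...]
rbn_n: 8
rbn_k: 2
n_mutants: 20
T: 50
s: 100
cv_epochs: 8
```

```bash
bn run --config exp.yaml
bn summarize --manifest out/manifest.json
```

## Conventions

- States are integers; node 0 is the least significant bit. Bitstrings such
  as `"011"` list node 0 first.
- In a node's truth table the first listed input is the most significant bit
  of the row index.
- Fragility sign: negative = antifragile (complexity gained under
  perturbation), zero = robust, positive = fragile.
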