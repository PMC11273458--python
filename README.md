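# armlearn

Active-learning pipeline for machine-learning-guided directed evolution of
artificial metalloenzymes (ArMs), built around the engineering campaign of a
streptavidin-based gold hydroamination catalyst: five residues
(111, 112, 118, 119, 121) are randomized simultaneously, giving a search
space of 20⁵ = 3,200,000 variants, of which only a few thousand can ever be
screened.  The package provides every computational stage of that campaign —
library design, sequence–activity data processing, noise-aware
Gaussian-process modeling, batch selection for screening rounds, and the
plate-barcode NGS demultiplexing that links sequences to activities — plus a
synthetic landscape simulator so the full loop runs and is tested without
any experimental data.

It is intended for protein engineers and computational biologists running
(or studying) model-guided screening campaigns at 96-well-plate scale.

## The model

Variants are five-letter amino-acid codes `v` (e.g. `TFNAQ`, the reference).
Each residue is encoded by 25 z-scored physicochemical descriptors, so
`x(v) ∈ R¹²⁵`.  Log relative activity is modeled as a Gaussian process

    y(v) = f(x(v)) + ε,   f ~ GP(0, k),   ε ~ N(0, σ²)

with a Matérn-5/2 kernel k (ARD lengthscales optional) and — crucially — σ
**fixed** at the pooled standard deviation of replicate log-activities

    σ̂² = Σ_v Σ_i (y_vi − ȳ_v)² / Σ_v (n_v − 1)   over variants with n_v ≥ 2,

not optimized with the kernel hyperparameters: replicate scatter is measured,
and the model is forbidden from explaining it as signal.  Kernel
hyperparameters maximize the log marginal likelihood (multiple restarts);
feature subsets come from a LASSO path followed by automatic relevance
determination (rank features by inverse lengthscale, keep the top k = 20).

Screening rounds are designed from the posterior:

* **Exploration** — greedily pick the candidate with the largest posterior
  standard deviation, condition the covariance on the pick (no label
  needed), recompute, repeat.
* **Exploitation** — rank candidates by posterior mean, keep a top-M pool,
  then run greedy MAP inference for a determinantal point process on the
  kernel Gram matrix, so the batch is both high-predicted and mutually
  dissimilar.

A campaign is: round 1, a mutational-load-constrained random library (at
most 4 substitutions); round 2, exploration; round 3, exploitation.  The
*hit rate* of a round is the fraction of screened variants with activity
above the reference variant.

## Worked example

Run a full synthetic three-round campaign from the command line:

```bash
armlearn campaign --seed 7 --round-sizes 96,64,64 --out campaign_out
```

```
 round strategy  n_variants  hit_rate  max_relative_activity
     1   active          96  0.010417               1.096783
     2   active          64  0.000000               0.820776
     3   active          64  0.218750               2.913935
```

Round 1 screens 96 random triple/quadruple mutants: 1% beat the reference,
and the best is barely above it (1.10×).  Round 2 deliberately chases
*informative*, not active, variants — its hit rate is zero by design.  With
the model refined, the round-3 exploitation batch reaches a 22% hit rate and
a best variant at 2.9× the reference activity.  Per-round measurement tables
land in `campaign_out/`, and rerunning with the same seed reproduces the
files byte for byte.

The same stages are available as a library (`simulate_landscape`,
`estimate_noise`, `fit_gp`, `select_exploration_batch`, …) and as further
commands (`simulate`, `demux`, `join`, `fit`, `crossval`, `select-explore`,
`select-exploit`, `evaluate`).

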