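# Methods

## Scope and data model

The package models a combinatorial protein-engineering campaign over a small
set of randomized residues.  A `VariantSpace` fixes the positions (default
111/112/118/119/121 of streptavidin), the 20-letter alphabet, the reference
variant (`TFNAQ`, the S112F K121Q double mutant) and the wild type
(`TSNAK`).  Activities are unitless relative activities: every 96-well
plate carries the reference in triplicate, and raw signals are divided by
the per-plate reference mean, so the reference is 1.0 on every plate.
Modeling happens on the natural-log scale; values below a floor (default
0.01, i.e. 1% of reference) are clipped and flagged rather than dropped —
inactive variants are informative observations.

## Library design utilities

Degenerate codons are expanded under the standard genetic code (NDT → 12
codons / 12 amino acids / no stops; NNK → 32 codons / all 20 / one amber
stop).  Residue probabilities under a codon scheme are codon-proportional
(NNK serine = 3/31 of sense draws), matching physical library construction.
Statistical coverage of screening N clones over V equiprobable outcomes is
the expected fraction of distinct outcomes, 1 − (1 − 1/V)^N; the
full-coverage probability (every outcome seen at least once) is also
exposed, computed by inclusion–exclusion in exact integer arithmetic because
the alternating binomial sum cancels catastrophically in floating point.
The expected-fraction form gives 95.6% at N = 36, V = 12, the usual "~95%"
design point; which of the two forms a given protocol reference intends is
ambiguous, and we adopt the one that matches that printed value.
Mutational-load-constrained libraries (at most m substitutions from the
reference) are counted in closed form, Σ_k C(P,k)(A−1)^k, and can be
enumerated or sampled; the full space streams in lexicographic chunks so a
3.2M-candidate scan never materializes in memory.

## Encoding

Each residue maps to 25 physicochemical descriptors (hydrophobicity scales,
volume/mass/bulkiness, polarity, charge, hydrogen bonding, secondary-
structure propensities, flexibility, composition counts); a variant is the
concatenation over positions, 125 features for five positions.  The shipped
table is a curated stand-in assembled from classic literature scales and
composition-derived counts — the width and semantics are what matter, and
any user table with the same layout can be substituted.  Properties are
z-scored across the 20 amino acids so lengthscales on different properties
are comparable; feature columns are z-scored again across the training
variants, and those training statistics are frozen and reused for every
later transform (held-out folds, screening candidates).

## Noise model

Measurement scatter between replicate wells of the same variant is treated
as log-normal with constant variance across variants.  The estimator is the
pooled, degrees-of-freedom-corrected standard deviation of replicate
log-activity residuals over all variants with ≥ 2 observations (a plain
residual-RMS variant is available).  Replicates are kept as separate
training rows rather than averaged.  The resulting σ̂ is *fixed* in the GP
likelihood — this is the central noise-handling choice: letting the
optimizer co-adapt the noise term allows it to trade noise for spurious
signal, and the package's noise-sensitivity study (`noise_sensitivity_curve`)
shows cross-validated R² degrading when σ is misspecified by 100× in either
direction.

## Gaussian-process model

Exact GP regression with zero prior mean on centered log activities.
Kernels: Matérn-5/2 (default; 3/2 available), squared-exponential, linear
(with a bias unit — equivalent to Bayesian linear regression with the same
fixed noise; without the bias the centered response has a component outside
the span of the feature Gram matrix), and an additive kernel summing
independent Matérn terms over per-position feature blocks.  The additive
kernel has no cross-position terms and therefore cannot represent epistasis;
it is the structural baseline that the full kernel is compared against.
Hyperparameters (log signal variance, log lengthscales — one shared or one
per feature under ARD) are optimized by L-BFGS-B with analytic gradients,
bounded in log space, from a data-driven start plus seeded log-uniform
restarts (best optimum kept; all restarts failing is an error).  A 1e-8
jitter stabilizes Cholesky factorizations.  Cross-validation is grouped by
variant code (all replicates share a fold, default 15 folds) so replicate
leakage cannot inflate held-out R², Spearman ρ or MSE.

## Feature selection

ARD over a hundred-plus correlated descriptors is slow and multi-modal, so
selection is two-stage: a 100-penalty LASSO path picks the penalty whose
nonzero count lands in a target range (default 20–100, closest to the
midpoint; nearest count with a warning otherwise), then ARD ranks the
surviving features by inverse lengthscale and the top k = 20 are kept.  A
caveat found in simulation: ARD reliably separates informative from
irrelevant features (lengthscales differ by an order of magnitude), but the
ranking *among* flat irrelevant features is arbitrary — conclusions should
rest on the selected set, not on fine rank order in its tail.

## Batch selection

Exploration uses iterative maximum-uncertainty selection: pick the
candidate with the largest posterior standard deviation, condition the
posterior covariance on a noisy observation at that point — the variance
update needs no label, so no fantasy values are involved — and recompute.
Ties break lexicographically by variant code for reproducibility.

Exploitation ranks candidates by posterior mean, keeps the top-M pool, and
runs greedy MAP inference for a determinantal point process whose kernel is
the fitted GP kernel Gram matrix on the standardized descriptors: at each
step the variant with the largest conditional variance (log-determinant
gain) joins the batch.  Greedy MAP is exact on most small instances (~90%
of random 6-choose-3 pools against exhaustive search) and is the standard
scalable approximation.  M defaults to 5× the batch size at the library
level.  In the simulated campaign, where the candidate pool is ~2,000×
smaller than the real 3.2M-variant scan, M is 2× the batch size: at pool
size 1,500 a 5× pool reaches the ~21st percentile of candidates, far less
selective than a top-M slice of a full scan, and measurably dilutes the
exploitation round.

A note on what exploration does and does not optimize: greedy
max-uncertainty selection targets the joint entropy of the batch, not the
average predictive variance elsewhere.  In low-dimensional feature spaces
(where candidates are mutually correlated) it also reduces held-out mean
variance faster than random batches — 20/20 seeds in the 2-D check — but in
the diffuse 125-dimensional variant encoding nearly every candidate is
isolated at the fitted lengthscales, and the mean-variance comparison
against random selection is not discriminative (13/20 at 3-D, ~10/20 at
5-D and above).  Its value in the campaign is realized through the refined
model's hit rate, which is what the campaign benchmark measures.

## Synthetic landscapes

The generator emulates the study conditions rather than any particular
dataset.  Log activity is f(v) = μ + Σ_i a_i(v_i) + Σ_{i<j} e_ij(v_i, v_j):

* additive effects a_i ~ Normal(−0.35, 0.4²) per non-reference residue —
  the deleterious bias is calibrated so a random load-3/4 library has a
  ~3% hit rate, the regime reported for such initial libraries;
* pairwise epistasis: each position pair carries an interaction table with
  probability 0.3 (density); a quarter of its residue combinations get
  heavy-tailed Laplace(0, 0.3) effects; no three-way terms;
* inactivation: every non-reference residue has an Exponential(1)
  destabilization cost; a variant whose summed cost exceeds 4 is dead and
  reports the background level (0.05 relative).  Because costs add, the
  dead fraction rises from ~10% of double mutants to ~65% of quintuple
  mutants — the characteristic activity collapse at high mutational load —
  while deadness remains a deterministic function of genotype.  (An
  earlier design drew deadness as a load-dependent Bernoulli; that makes
  inactivation statistically independent of sequence, i.e. irreducible
  label noise no model could learn, which is neither realistic nor useful
  for benchmarking.)
* measurement: observed log activity is f(v) plus Normal(0, 0.3²) noise;
  simulated plates add a log-normal per-plate scale (sd 0.1) that the
  normalization step must remove, and carry reference and empty-vector
  triplicates.

Reference residues have zero effect and zero cost, so the reference sits at
exactly 1.0 relative activity and "hit" (> 1.0) keeps its meaning.  A
planted-optimum option lifts one chosen variant clearly above the reference
(and keeps it alive) for discovery-rate studies.  All draws are
`numpy.random.Generator`-seeded and bit-reproducible.

What the simulator does not emulate: codon-level biases in real libraries,
position-dependent noise, batch effects between screening rounds, or any
structural realism in the effect tables.  Passing tests therefore
demonstrate that the pipeline's machinery behaves correctly on landscapes
with the study's statistical signatures, not that it will achieve any
particular performance on a real protein.

## Simulated campaign

Defaults: rounds of 96 / 64 / 64 variants; round 1 draws loads 3 and 4 with
equal probability and remeasures 15% of variants for the noise estimate;
rounds 2–3 select from a seeded 1,500-candidate pool stratified uniformly
over loads 1–5 (a miniature of a full-space scan that, unlike a uniform
draw, represents every distance from the reference), excluding tested
variants.  The campaign GP uses the full 125-feature encoding with a shared
lengthscale: at these training sizes (~100–200 rows) the two-stage feature
selection gave no benchmark benefit for an order of magnitude more compute,
so it is reserved for larger datasets.  Strategies: `active`
(explore, then exploit), `greedy` (top-mean both rounds, no
diversification), `random` (the no-model control).  These round sizes are
the package's desk-scale defaults; hit-rate enrichment (round 3 over round
1) is the benchmark statistic, with the random control expected to show
none.

## NGS demultiplexing

The two-step barcoding scheme is combinatorial: 8 row + 12 column barcodes
address 96 wells from 20 primers, and a forward/reverse plate-barcode pair
distinguishes f × (n−f) plates from n second-step primers (36 from 12).
The shipped default scheme uses deterministic synthetic 6-mer barcodes with
pairwise Hamming distance ≥ 3 (any real primer set can be configured), a
40 bp read carrying the forward plate and row barcodes, and a 110 bp mate
carrying the reverse plate and column barcodes plus the five mutated codons
in their gene layout (adjacent pairs at 111/112 and 118/119, isolated 121).
Decoding accepts up to 1 mismatch per barcode (unambiguous by the distance
constraint).  Wells are called by consensus over the *full five-codon
haplotype* — not per-site — so PCR-chimera mixtures appear as reduced
purity instead of being silently recombined; calls require ≥ 10 reads and
≥ 0.8 purity, and a consensus containing a stop codon is `nonsense`.  Those
cutoffs are this package's defaults (the filtering concept — drop nonsense
variants and multi-variant wells — is standard; exact thresholds are
protocol-specific).  The fixture generator writes paired FASTQ (optionally
gzipped) with i.i.d. substitution errors, within-well chimeric reads, and a
ground-truth manifest; an error-free fixture round-trips to 100% correct
(plate, well, variant) assignments.

## Numerical and policy choices

* Jitter 1e-8 on kernel diagonals; Cholesky solves throughout; posterior
  variances clipped at zero.
* Constant feature columns standardize to zero (sd treated as 1).
* Lengthscale bounds [1e-2, 1e3], signal-variance bounds [1e-4, 1e4] in the
  optimizer; initial shared lengthscale √d for d standardized features.
* Ties in every selection loop break by lexicographic variant code.
* Empty-vector background is not subtracted by default (subtraction is an
  option); "ev" rows are excluded from training.
* Undefined precision (no predicted hits) is returned as NaN with a
  warning, never silently as zero.

## Problem sizes used in the checks

The test-suite and acceptance-script studies run at desk scale, chosen as
the smallest sizes at which each effect is stable across seeds: n = 300
variants for the noise-sensitivity study, n = 250 with dense (density 1.0,
scale 0.7) epistasis for the additive-vs-full comparison, 40-variant
training sets for batch-selection comparisons, 20-seed campaigns at
96/64/64, and 96-well × 25-read demultiplexing fixtures.

## Known limitations

* Exact GP solves scale as O(n³); fine for n ≤ a few thousand (the intended
  regime), with no sparse approximation provided.
* The additive kernel shares one signal variance across position blocks.
* The demultiplexer is substitution-only: indels shift the fixed-offset
  layout and surface as barcode mismatches or mixed wells.
* The shipped property table is a literature-style stand-in, not the
  specific descriptor set of any published study.
* Greedy DPP MAP is an approximation; exhaustive subset search is only
  feasible on toy pools.
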