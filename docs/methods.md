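# Methods

## Model

A proteochemometric regression: for an interaction between ligand `l` and
target `t` with measured affinity `a` (Kd or EC50, assumed nM), the row is

```
x(l, t) = [ mol(l) | prot(t) ],    y = log2(a)
```

`mol(l)` is the whitelisted molecular descriptor block, `prot(t)` the
1447-column protein sequence descriptor block. A single model is fitted
across all targets; its assumptions are therefore (i) that affinity is a
smooth function of descriptor space shared across target families, and
(ii) that sequence-derived descriptors carry enough binding-site signal
without any 3D structure.

## Affinity curation

Censored measurements (`<`, `>`) carry no definite value and are dropped.
Replicated (ligand, target) pairs collapse to the median of their linear
values when their log2 spread is within a tolerance (default 1.0 log2 unit
≈ one dilution step); pairs with a larger spread are treated as mutually
inconsistent and removed entirely. The rule is idempotent and never
invents a value outside the observed range. Units are configurable; nM is
the default, matching common bioactivity-database conventions.

## Protein descriptors

Nine families; sizes 20/400/240/240/240/21/126/60/100 = 1447 per target.

- **Composition (G1, G2):** residue frequencies and adjacent-pair
  frequencies.
- **Autocorrelations (G3–G5):** over 8 z-normalised AAindex property
  scales (hydrophobicity CIDH920105, flexibility BHAR880101,
  polarizability CHAM820101, free energy of solution CHAM820102,
  accessible surface area CHOC760101, residue volume BIGC670101, steric
  parameter CHAM810101, relative mutability DAYM780201), lags 1–30:
  - Moreau-Broto (normalised): `AC(p,d) = Σ_{i≤N-d} p_i p_{i+d} / (N-d)`
  - Moran: `I(p,d) = [(1/(N-d)) Σ (p_i-p̄)(p_{i+d}-p̄)] / [(1/N) Σ (p_i-p̄)²]`
  - Geary: `C(p,d) = [(1/(2(N-d))) Σ (p_i-p_{i+d})²] / [(1/(N-1)) Σ (p_i-p̄)²]`

  Zero-variance convention: a property that is constant along the sequence
  (e.g. any homopolymer) yields 0 for Moran and Geary rather than a
  division by zero; the variance test uses a 1e-12 floor to absorb
  floating-point residue.
- **CTD (G6, G7):** 7 three-class physicochemical partitions
  (hydrophobicity, van der Waals volume, polarity, polarizability, charge,
  secondary-structure propensity, solvent accessibility). Composition = 3
  class frequencies; transition = frequencies of the 3 unordered adjacent
  class pairs over N−1 positions; distribution = for each class the
  1-based position (percent of N) of its 1st, 25%, 50%, 75% and 100%
  occurrence, the occurrence index being `ceil(fraction × class count)`
  (minimum 1); an absent class contributes zeros.
- **Sequence order (G8, G9):** coupling numbers
  `τ_d = Σ d(r_i, r_{i+d})²` for d = 1–30 over two residue-pair distance
  matrices, and quasi-sequence-order terms — per matrix, 20 residue terms
  `f_r / (Σf + w Στ)` and 30 coupling terms `w τ_d / (Σf + w Στ)` with
  weight w = 0.1 (the 50 values per matrix sum to 1 by construction).

Distance matrices: Grantham, computed from the published
composition/polarity/volume table with α = 1.833, β = 0.1018,
γ = 0.000399 and the mean pair distance normalised to 100 (reproduces the
printed exemplars Leu–Ile = 5, Arg–Lys = 26, Ala–Arg = 112); and a
Schneider–Wrede-style physicochemical distance reconstructed as the
Euclidean distance over min-max-normalised hydrophobicity, hydrophilicity
and residue volume — a synthetic stand-in built on the same principle as
the published matrix, shipped as `schneider_wrede_synthetic.csv`. All
scales, partitions and matrices are editable text fixtures under
`pcmaffinity/data/`.

The maximum lag of 30 forces a minimum sequence length of 31; shorter
targets are rejected with a named error. Note the family sizes sum to
1447 even though 1437 is sometimes quoted for this descriptor set; the
per-family counts are authoritative here.

## Molecular descriptors and the vibration whitelist

The default engine is RDKit-based and purely 2D, hence deterministic: the
stock 2D descriptor list (~210 columns) plus an atom-type E-state block —
for each of RDKit's 79 E-state atom types, the count, sum, minimum and
maximum of the per-atom Kier–Hall E-state indices, named in the
`nsCH3 / SsCH3 / minsCH3 / maxsCH3` convention. 3D families (CPSA, RDF,
WHIM, geometrical) would require conformer generation and are deliberately
absent from the default engine.

The whitelist holds 813 descriptor names restricted to families tied to
the physicochemical drivers of molecular vibration (electronegativity,
atomic and bond charge, polarizability, hydrogen bonding): atom-type and
hydrogen E-state, charge/electronegativity/polarizability-weighted
autocorrelations, topological charge indices, Burden-matrix charge
eigenvalues, ETA terms, charged-partial-surface-area names,
electronegativity-based constitutional descriptors and H-bond counts. The
shipped file is a synthetic reconstruction of such a list (the name set is
the operative definition and is fully editable). Matching against the
engine vocabulary is exact-name by default with a small editable alias
map; whitelist entries without an engine counterpart are reported in the
filter's `unmatched` list, never silently discarded. Filtering is a pure
column projection and idempotent; matching zero columns is a hard error
because it indicates the wrong engine or alias map.

## Preprocessing

Responses are log2-transformed. Features are min-max scaled to [-1, 1]
with parameters fitted **on the training partition only** and applied to
held-out rows (out-of-range values clip to the interval ends; constant
columns map to 0); non-finite descriptor values are imputed with
training-partition medians. A `fit_on_all` / `--paper-mode` switch
reproduces the simpler variant that fits the scaling on all rows before
splitting; the partition-fitted default avoids test-set leakage.

## Shadow-feature selection

Per round: every real column gets a shadow — an independent row
permutation of itself, seeded per column name so the construction ignores
column order. A random forest (150 trees, `max_features=sqrt`; a smaller,
more randomised forest than the final regressor, since importance *ranks*
stabilise well before 500 trees) is fitted on the doubled matrix and each
column scored by out-of-bag permutation importance: for every tree with
usable out-of-bag rows, the drop in that tree's OOB R² when the column is
permuted over its OOB rows, averaged over trees. Trees that never split on
a column contribute a drop of exactly zero, so only trees actually using
the column are re-evaluated — this is what makes the 2p-column pass cheap.
The bootstrap draw of each tree is replayed from its recorded seed; a test
verifies the reconstruction against the library's own OOB score to 1e-12.

Scores are then **quantile-normalised** within the round: each real
feature's score is its empirical quantile (averaged ranks) among the real
features; shadow scores are mapped through the same quantile function by
interpolation. Z-max is the largest normalised shadow score. A feature is
*Important* in a round when its score exceeds `max(Z-max, 0.6)` and
*Rejected* when it falls below `Z-max − 0.05` (margin configurable). After
5 rounds, majority vote assigns Confirmed / Rejected / Tentative; only
Confirmed columns enter the regression stage, and confirming nothing is a
hard error.

The quantile scale was chosen over a min-max scale deliberately: with
min-max, a single dominant feature compresses every other informative
feature toward 0 and under the fixed 0.6 threshold almost everything
becomes Tentative, even features whose raw importance exceeds the best
shadow severalfold; on a quantile scale the 0.6 threshold has a stable
meaning (upper 40% of features) across rounds and datasets, and several
top features can share the maximal score of 1.00, as importance tables in
this field commonly show. The fixed-5-round majority vote is the default;
`variant="binomial"` provides the canonical Boruta flow (two one-sided
binomial tests at p < 0.05 over the rounds) for comparison — note it needs
more rounds than 5 to reach significance.

## Regression models

- **RF:** 500 trees, unlimited depth, `min_samples_split=2`,
  `min_samples_leaf=1`, no leaf cap (scikit-learn regression default of
  considering all features per split).
- **SVM:** epsilon-SVR, `C=1000`, `gamma=1e-4`. The kernel is radial
  basis: a gamma of that magnitude is only meaningful for an RBF kernel.
- **ANN:** one hidden layer of 2 units, L2 penalty (weight decay) 0.1,
  linear output, ≤1000 iterations. Fitted with L-BFGS, the closest
  quasi-Newton analogue of the classical `nnet` optimiser — a documented
  deviation from that optimiser, not a re-implementation of it. Two hidden
  units is a very tight bottleneck for a >1000-input problem; it is kept
  as given.

Cross-validation: rows are permuted once (seeded) and split into 10
near-equal folds; scaling and imputation are re-fitted per fold. All five
metrics (SSE, MSE, RMSE = √MSE, MAE, R² = 1 − SSE/SST) are reported per
fold on both partitions; aggregates are arithmetic means over folds
(pooling across folds is available by concatenating the per-fold held-out
predictions, as the acceptance script does for the |d| histogram). R² is
reported as NaN when the actual values have zero variance.

## Evaluation

The |d| histogram bins `|y_actual − y_predicted|` into
`[0,0.5) [0.5,1) [1,1.5) [1.5,2) [2,∞)`; five half-open 0.5-wide parts
cannot cover an unbounded error range, so the fifth bin is open-ended and
the summary statistic is the percentage of predictions within 2.0 log2
units. The importance report ranks Confirmed features by mean normalised
score, split into molecular and protein tables, keeping scores above 0.85
(the conventional reporting cutoff on the [0,1] scale); ties break
lexicographically for determinism.

## Synthetic benchmark

`synth` generates ligands from a segment-concatenation SMILES template
family (chains, rings, carbonyl/amine/halide terminals — every draw is
re-parsed and resampled on failure, and duplicates are rejected on
canonical SMILES), targets as i.i.d.-uniform random sequences, and
affinities from a planted linear model: k descriptor columns (half
molecular, half protein; finite and non-constant over the sampled rows)
are standardised, combined with coefficients ±β, and Gaussian noise σ·ε is
added; the stored affinity is `2^y` nM. Defaults: 120 ligands, 80 targets,
500 pairs, sequence lengths 40–60, k = 10, β = 1, σ = 0.3. The ligand and
target counts were chosen so that both descriptor blocks have substantial
rank: with only a few dozen targets the 1447-column protein block is
rank-deficient (rank ≤ n_targets − 1) and any planted protein column is an
exact linear combination of others, which makes per-feature recovery
ill-posed rather than merely hard. All randomness flows from one seed
through named substreams (targets/ligands/pairs/coefficients/noise).

The matrix-level variant (`planted_selection_benchmark`) plants k = 10
standard-normal informative columns and 100 row-permuted copies as noise,
n = 400 — the configuration used to measure selection recovery.

What the generator does *not* emulate: real chemotype clustering and
activity cliffs, sequence homology between targets, assay noise structure,
censoring, or any physical binding mechanism. Passing tests therefore
demonstrate that the pipeline recovers a known signal embedded in real
descriptor geometry — not that it attains any particular accuracy on
laboratory data.

## Numerical choices and problem sizes

- Descriptor oracle comparisons: 1e-9 absolute; metric formula oracle:
  1e-12.
- Selection recovery is measured over 10 seeds of the matrix benchmark;
  the full-pipeline measurement uses one seed at the default study size
  (500 pairs, ~1770 columns after filtering). The acceptance script's
  pooled |d| histogram refits 150-tree forests per fold for speed; the
  headline CV numbers use the full 500-tree configuration.
- The pure-noise control (β = 0) runs CV on a systematic 1-in-9 column
  subset; with no signal anywhere, the choice of columns is immaterial to
  the conclusion and the thinning keeps the forest fit brief.

## Known limitations

- The default engine's vocabulary covers roughly 320 of the 813 whitelist
  names; the remainder (hydrogen E-state, weighted-autocorrelation, CPSA
  and other families) are reported as unmatched unless a PaDEL-compatible
  engine is supplied.
- SVR training is O(n²)–O(n³); at tens of thousands of rows the RF path is
  the practical default.
- Selection treats correlated descriptor clusters collectively: a planted
  column can be Confirmed alongside (or occasionally instead of) a highly
  correlated surrogate; per-column attribution within a cluster is not
  identifiable in principle.
- Deduplication keeps the median of consistent replicates; it does not
  model qualifier-specific censoring (e.g. treating `>10000` as
  informative right-censoring).
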