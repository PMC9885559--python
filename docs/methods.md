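# Methods

This note documents the models, conventions and numerical choices behind
`tcrlearn`, and what the synthetic-data tests do and do not demonstrate.

## Input model

The unit of analysis is a labeled repertoire: a vector of non-negative
integer clone counts over clonotype CDR3 amino-acid sequences, one label
per sample. All features are computed per sample; nothing is shared across
samples except motif/embedding column unions learned at fit time.
Validation warns (rather than rejects) on characters outside the 20-letter
amino-acid alphabet, since some upstream tools emit `*` or `_` in
out-of-frame junctions. Duplicate clonotype columns are summed with a
warning — identical sequences are one clone. The first CSV column is
auto-detected as a sample-id index when its header is empty or its values
are non-numeric; `index_col` overrides the guess.

## Diversity indices

All indices are computed on the proportions of *observed* clones (zero
counts dropped), so every index is invariant to rescaling all counts by a
positive factor and to column order.

- Shannon and Pielou use the natural logarithm by default; a `base`
  argument switches to bits. The choice only rescales `H`, and cancels in
  `J = H/ln S`.
- Simpson is reported in its dominance form `λ = Σ p_i²` (higher = more
  clonal), with `1/λ` reported separately.
- Pielou's `J = H/ln S` is `0/0` for a monoclonal sample; we define
  `J := 0` and clonality `1 − J := 1` there, so clonality is maximal for a
  single-clone repertoire.
- Hill orders default to `q ∈ {0, 1, 2, 3}`; `q = 1` uses the limit form
  `e^H` exactly rather than a numerically fragile power form.
- Gini is computed over observed-clone proportions with the sorted-rank
  identity `G = (2 Σ i p_(i) − (S+1)) / S`, which equals the pairwise
  mean-absolute-difference definition (tested against a brute-force double
  sum); `G = 0` for perfect evenness and for `S = 1`.

Rarefaction and coverage-based richness estimators (Chao1 etc.) are out of
scope; reported richness is observed richness and therefore depends on
sequencing depth.

## Repertoire graphs

Nodes are the distinct clonotype sequences present in a sample, unweighted
by abundance (clone counts are kept only as a node attribute for export).
An edge joins `u, v` iff `1 ≤ lev(u, v) ≤ t` with `t = 2` by default — an
inclusive threshold, not "exactly 2". Distances come from edlib's banded
Myers bit-vector algorithm with cutoff `k = t`, behind a length-difference
prefilter; a pure dynamic-programming oracle in the test suite verifies
100% agreement on random pairs. Candidate pairs are generated by length
bucketing (only length gaps ≤ t can connect). Graph summaries use
networkx: density `2E/(N(N−1))` (0 for a single node), mean local
clustering (0 for degree < 2 nodes), transitivity `3·triangles/triples`
(0 when no triples), and connected components. The edge count corresponds
to what repertoire-network figures sometimes call the "number of arrows";
in an undirected graph the two counts coincide. Graphs beyond 50 000 nodes
raise an explicit resource error instead of silently subsampling.

## Motifs

k-mer windows never span two sequences. The default weighting is
abundance: a sequence's window counts are multiplied by its clone count
before normalizing, so motif frequencies describe the repertoire's reads,
not its sequence list; presence weighting (each distinct sequence once) is
available. Frequencies are normalized within each k separately — a 2-mer
column and a 4-mer column do not share a denominator. Only observed k-mers
become columns (the 20⁴ universe is never materialized); an optional
minimum-frequency filter prunes rare columns. Motif counting runs over the
full provided string; whether germline-encoded flanks are included is
decided by upstream preprocessing, not here.

## Embeddings

Embeddings are fitted on the raw counts (normalization of derived feature
tables is a separate, downstream option). Components are exposed as named
feature columns. PCA/ICA/SVD/ISOMAP/UMAP store a fitted transformer that
maps unseen samples into the same space, which is what external validation
requires; t-SNE has no out-of-sample map, so models whose selected
features include t-SNE axes refuse external validation with an explicit
error. Library hyperparameter defaults are used, with two small-sample
accommodations: t-SNE perplexity defaults to `min(30, (n−1)/3)` and
ISOMAP/UMAP neighbor counts are capped at `n − 1`. All stochastic methods
take an explicit seed (default 42), recorded on the fitted object.

## Normalization

Three per-feature affine maps, with statistics learned on training data
only and frozen:

- standard: `(x − mean)/sd` (population sd);
- min–max onto `[−1, +1]` (deliberately not the more common `[0, 1]`);
  unseen values outside the training range map outside `[−1, 1]` without
  clipping;
- robust: `(x − median)/IQR`, with linear-interpolation (type-7)
  quartiles, matching numpy/sklearn defaults.

Constant features map to 0 with a warning. Inside cross-validation the
scaler is refitted on each training fold (no leakage); a
`leakage_safe=False` switch reproduces the normalize-before-split flow of
GUI-style analyses for comparison.

## Feature ranking

Rank encoding: per method, selected features carry ranks `1..k`, all
others 0. The default `k` is `min(class sizes) − 1`, a deliberately
conservative cap against overfitting in the small-cohort regime these
analyses live in.

- Pearson ranks by `|r|` with the 0/1 label, one feature at a time —
  duplicated informative features both rank highly, by construction.
- mRMR uses the FCQ scheme for continuous features: relevance is the
  one-way ANOVA F statistic, redundancy the mean `|r|` with the selected
  set (floored at 1e−6), and the greedy step maximizes their quotient;
  the MID difference scheme is available. The greedy output is verified
  exactly against an exhaustive evaluation of the same objective on small
  instances.
- Ridge standardizes features, fits an L2-penalized linear model of the
  0/1 label (penalty 1.0 by default, recorded) and ranks by
  `|coefficient|`.
- XGBoost ranks by gain importance of a seeded boosted-tree fit
  (100 trees, depth 3, learning rate 0.3); zero-importance features rank
  0 even inside the top-k.

Ties break lexicographically by feature name everywhere, so rankings are
deterministic. The positive class defaults to the second label in sorted
order and is recorded in every downstream artifact; rankings are invariant
to the choice up to identical absolute statistics.

## Classification and evaluation

The four classifiers are intentionally transparent models (GNB, LDA,
logistic regression, decision tree) with sklearn defaults apart from
explicit seeds and `max_iter=1000` for LR. A trained model stores its full
prediction contract — ordered feature names, frozen normalization
statistics, positive class, seed — and aligns prediction inputs by column
name, refusing missing non-motif columns; motif columns absent from an
external cohort are zero-filled with a warning (an unseen k-mer is a zero
frequency, not missing data).

Internal validation is stratified k-fold (default k = 3) repeated 100
times with reshuffled folds; metrics are means (with dispersion) over all
fold evaluations rather than pooled predictions, and the confusion matrix
is summed over all evaluations (total = samples × repeats). AUC uses the
mid-rank tie convention (constant scores give 0.5); precision is defined
as 0, with a warning, when nothing is predicted positive. External
validation applies the frozen model once; its confusion-matrix total
equals the test-cohort size.

Model files are self-describing versioned containers (schema version and
library version embedded); corrupted or incompatible files raise an
explicit error on load.

## Synthetic cohorts

The generator emulates two-group repertoire studies in which the groups
differ in clone-abundance *evenness*: per sample, clone proportions are
drawn from a symmetric Dirichlet with group concentration α (α = 100 ≈
even, α = 0.1 ≈ clonal; a power-law alternative with a per-group exponent
covers heavy-tailed repertoires), and counts are multinomial with N reads,
so per-sample read totals are conserved exactly. The default conditions —
8 + 8 samples, 200 clonotypes, 5 000 reads, α = 100 vs 0.1 — give a strong
between-group Shannon/Simpson contrast of the kind reported in
TReg/TConv breast-cancer case–control comparisons, at a size that keeps
the full pipeline fast. Sequences are CDR3-like strings (`CASS` + random
core + `F`, lengths 8–18); an optional cluster mode derives part of the
pool as 1–2-edit variants of seed sequences so repertoire graphs have
nontrivial edges.

What passing tests on this generator show: the pipeline recovers a known
between-group diversity difference, transfers it across independently
generated cohorts, and returns to chance under label permutation. What
they do not show: performance on real repertoires, whose abundance
distributions are heavier-tailed, whose clonotype universes overlap across
samples in structured ways, and whose group differences are far subtler
than α = 100 vs 0.1. VDJ-recombination realism (OLGA/IGoR territory) is
explicitly out of scope.

The label-permutation null in the acceptance checks averages over 10
independent permutations: with 16 samples a single permutation's chance
overlap with the true grouping has standard deviation ≈ 1 (hypergeometric),
so a single-permutation AUC is a noisy estimate of the null; the
10-permutation mean estimates the same quantity precisely.

## Problem sizes and determinism

Test and acceptance problem sizes (1 000 abundance vectors, 10 000 string
pairs, 50 brute-forced graphs, 16-sample cohorts with 100×3 CV folds) were
chosen so the entire suite runs in well under a minute on one CPU while
still exercising every code path at non-toy sizes. Every stochastic step —
cohort generation, fold shuffling, t-SNE/UMAP, XGBoost — is driven by an
explicit integer seed, and CLI runs write a JSON manifest (resolved
options + library version) next to their outputs, so a run is reproducible
from its manifest and inputs alone.

## Known limitations

- Observed richness and graph statistics are depth-dependent; no
  rarefaction is applied.
- The Levenshtein graph treats all edits equally; biochemically
  conservative substitutions are not privileged.
- mRMR is the continuous-feature FCQ variant; mutual-information variants
  for discretized features are not implemented.
- The feature cap `min(class sizes) − 1` is a heuristic, not a guarantee
  against overfitting, especially with feature selection performed outside
  the CV loop (as in the GUI-style protocol this pipeline mirrors; the
  internal CV here re-trains the classifier per fold but takes the feature
  list as given).
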