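# Methods

This note documents the models and procedures implemented in `claimscope`,
the assumptions behind them, the defaults that matter, and what the
synthetic benchmark does and does not establish.

## Data model and activity filter

Claims are long-format: one row per medical act with a pseudonymous entity
(practitioner) ID, categorical columns treated as opaque tokens, and
numerical columns in domain units (e.g. currency for billed amounts).
Missing numerical cells are *excluded* from aggregation statistics rather
than imputed as 0, which would bias sums and minima; missing categorical
cells map to the reserved token `__missing__`, which participates in
embedding like any category so row dimensionality stays fixed. The activity
filter keeps entities with strictly more than `min_actions` acts
(default 50), optionally per period, in which case every period the entity
is active in must exceed the threshold — the stricter of the two readings,
exposed as a flag rather than hard-coded.

## LSA categorical embeddings

The co-occurrence matrix X is binary presence (not counts), with one pooled
vocabulary over all categorical columns; tokens are namespaced by column so
identical strings in different columns stay distinct. Row order is schema
column order with tokens sorted lexicographically, making the vocabulary —
and hence the embedding — independent of action-row order. Category i's raw
embedding is row i of CS = XP from the rank-k SVD; rows are l2-normalized so
cosine similarity is a dot product. A category can be orthogonal to the
top-k subspace, in which case its raw row is zero and stays zero.

Numerical choices:

* **k = 3** by default; larger k buys little separation on claims-like data
  while growing every downstream profile.
* **Sign convention.** Each singular direction is flipped so the
  largest-magnitude entry of its P column is positive (ties → lowest
  index), making embeddings bit-reproducible across runs and backends.
  Exact invariance to action order additionally requires a simple
  (non-degenerate) singular spectrum; with repeated singular values the
  truncated subspace itself is not unique.
* **Solvers.** Dense SVD for small matrices (and as the test oracle),
  iterative sparse SVD otherwise; requesting k beyond min(c, p) clamps with
  a warning.
* **Unseen tokens** embed to the zero vector — a neutral contribution to
  mean aggregation.

The one-hot baseline aggregates indicator vectors by the mean, i.e. a
within-entity relative-frequency vector over each column's vocabulary,
accumulated sparsely so high-cardinality columns stay tractable.

## Profiles and standardization

Profile layout is numerical blocks first (six statistics per column:
sum, mean, median, std, min, max), then categorical blocks (k dimensions
per column), both in schema order; d = 6·m + k·q. The population (ddof = 0)
standard deviation is used throughout — it is defined for single-action
entities. Standardization is the conventional z-score (subtract the column
mean, divide by the column standard deviation); constant columns get scale
1 and become all-zero rather than being dropped, keeping the
column-to-feature map stable. The fitted (mean, scale) pairs are stored so
held-out entities can be projected onto the same scale.

## Detectors

Native scorers are deliberately simple, deterministic, and verifiable
against brute-force oracles:

* **kNN** (default k = 20): mean Euclidean distance to the k nearest other
  rows of the standardized profile matrix. Standardization is what makes
  unweighted Euclidean distance meaningful here.
* **Histogram** (default 10 bins): per dimension, an equal-width histogram
  over the observed range; score = Σ_d −log(density_d + ε) with ε = 1e-12
  guarding empty bins; assumes independence across dimensions; zero-range
  dimensions contribute nothing.
* **ECDF tail**: parameter-free; per dimension the smaller of the left and
  right empirical tail probabilities at the sample's value, aggregated as a
  summed negative log. On training points tails are ≥ 1/n, so the 1e-12
  clip only matters for out-of-range query rows (as produced by the
  Shapley engine's perturbations).

External detectors attach through an adapter: fit on the full profile
matrix, return one score per entity, higher = more anomalous. Built-in
adapters wrap scikit-learn's LocalOutlierFactor, IsolationForest and
OneClassSVM (sign-flipped `score_samples`). A failing adapter drops its
column with a logged warning rather than aborting the run. Stochastic
detectors are seeded from the run seed via stable stage-name hashing.

AUROC is computed exactly in Mann–Whitney form (ties counted ½) and is the
probability that a random positive outranks a random negative.

## Consensus ranking

Each detector nominates its top-k entities (default k = 50 — a plausible
expert-review workload; score ties at the boundary break by lexicographic
entity ID). Entities are ordered by nomination count, ties by mean
per-detector rank, then ID. Raw scores are never averaged across models:
scales are incommensurable, counts are not.

## Shapley explanations

The payoff of a coalition S of feature groups is the mean detector score
over a background sample with S's columns overwritten by the explained
entity's values (interventional replacement). The background is 100 rows
sampled without replacement from the standardized profile matrix, seeded.
Attribution is computed directly at the level of original-feature groups —
toggling a feature's expanded columns together — which coincides with
per-column attribution followed by within-group summation for the exact
estimator (additivity) while cutting enumeration cost from 2^d to 2^g.
Exact enumeration is refused beyond 12 groups; the permutation-sampling
Monte-Carlo estimator (one random group order and one background row per
iteration) is unbiased and reports per-group standard errors
(sample std / √T). Cross-model consensus first rescales each model's
grouped importances to unit l1 norm — making models with different score
scales commensurable while preserving sign — then averages.

## Reports

For each flagged entity: consensus importances ordered by magnitude, and
for the top-m features (default 5) a population comparison — categorical
features as entity-vs-population relative frequencies *over actions*
(an entity-weighted alternative is a config option), numerical features as
the entity's six statistics against their across-entity means with
z-scores (flagged and zeroed where the population is degenerate). The
billing-code feature can be pinned so it always appears regardless of rank.
JSON output round-trips losslessly; HTML embeds an SVG importance chart
with a fixed hash salt so renders are byte-identical.

## Synthetic benchmark

The generator emulates the structure of per-discipline claims data at desk
scale: 2000 entities, negative-binomial action counts (mean 60,
dispersion 5), four categorical columns — discipline (cardinality 3),
location (5), subcategory (20), billing code (5000, Zipf α = 1.0) — and a
log-normal billed amount. The population is a single discipline, as in a
per-discipline analysis of general practitioners; two further specialty
profiles (orthopedic-like, dermatology-like) exist as sources for
off-specialty anomalies. Each entity additionally has an idiosyncratic
repertoire: column probabilities are tilted by per-entity log-normal
preference weights (τ = 1.5 on the code column, 0.4 on location and
subcategory). This practice-style heterogeneity is the mechanism that makes
standardized one-hot distances between *normal* entities noisy at high
cardinality, while the embedding collapses idiosyncratic rare codes into
the same low-dimensional region — the regime in which the embedding
pipeline's kNN outranks the one-hot pipeline's.

Planted anomalies total 0.3 % of entities:

* **excessive_code** (0.15 %): the sampling odds of three common billing
  codes are multiplied by 60, lifting them to roughly 10–25 % of the
  entity's acts — overconsumption of legitimate, widely used acts rather
  than exotic rare codes (boosting rare codes instead creates singleton
  one-hot columns whose z² ≈ n makes the one-hot baseline trivially
  strong, the opposite of the high-cardinality regime of interest);
* **off_specialty** (0.15 %): half of the entity's actions are resampled
  from the orthopedic-like profile — higher amounts, hospital locations,
  surgical subcategories, foreign codes;
* **inflated_amount** (used in the explanation-fidelity checks): the billed
  amount is scaled ×5, a gross-overbilling signature whose cause the
  consensus attribution should recover.

Determinism: one global seed; each entity has its own substream keyed by
entity index, so growing the population never perturbs existing entities;
anomaly injection, detector seeds, backgrounds and per-entity explanation
seeds all derive from the run seed by stable stage-name hashing.

What the benchmark does *not* model: temporal burstiness or seasonality,
correlations between categorical columns within a normal action (columns
are sampled independently given the specialty and repertoire), real billing
tariff structures, and any attempt to fit the restricted insurer data's
actual distributions. Passing the benchmark therefore shows the pipeline
mechanics recover planted, aggregation-surviving signals under realistic
cardinality, imbalance and heterogeneity — not that the specific AUROC
levels transfer to real claims data.

## Problem sizes used in the checks

The acceptance script runs the benchmark at 2000 entities for 10 seeded
replicates per encoding, the explanation-fidelity runs at 500 entities with
5 replicates, and the determinism check at 300 entities; the pytest
acceptance suite uses 5 fixed-seed replicates for the benchmark criterion.
These sizes keep the full suite in the low tens of seconds while leaving
the anomaly prevalence and cardinality regime intact.

## Known limitations

* Exact Shapley cost grows as 2^g payoff evaluations; beyond 12 original
  features the Monte-Carlo path is mandatory and its error is statistical.
* The ECDF-tail scorer treats dimensions independently; anomalies that are
  only jointly unusual (central in every marginal) are invisible to it, as
  to the histogram scorer.
* kNN scoring is O(n·d) per query against the training matrix; at very
  large n an approximate index would be needed.
* The LSA embedding reflects co-occurrence in the *observed* data; a
  category appearing only in anomalous contexts embeds accordingly — the
  embedding is not robust to contamination of the training sample.
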