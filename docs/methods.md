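# Methods

## Problem setting and model

`micnet` compares two conditions (tumor vs. matched normal tissue) of a
two-layer molecular system: miRNAs in one layer, proteins in the other.
The working hypothesis is that disease reorganizes the dependence
structure — which molecules co-vary, and which cross-layer couplings
exist — and that this reorganization is informative beyond marginal
differential expression. The analysis therefore builds one binary
co-expression network per layer and condition, joins the layers with
cross-layer edges, and scores every node by how much its network role
differs between conditions:

    S_k = |B*_k| + |D*_k|

with B\*_k the standardized absolute difference in within-layer
shortest-path betweenness centrality between the normal and cancer
networks, and D\*_k the standardized absolute difference in cross-layer
degree. The two components are deliberately complementary: betweenness
captures a node's routing role *inside* its own layer; cross-layer
degree captures its coupling to the other layer. Interlayer edges enter
the score only through D — betweenness is computed per single layer, not
over multilayer paths, because the score is defined per layer and a
multilayer-path variant would change its meaning.

## Dependence measure: MIC

Pairwise dependence is the Maximal Information Coefficient: maximize,
over all grids with `s` columns and `t` rows subject to
`s·t ≤ B(n) = floor(n^0.6)` (with B never below 4 so a 2×2 grid is
always admissible), the mutual information of the gridded scatter
divided by `log2 min(s, t)`. MIC is in [0, 1], detects non-monotone
relationships, and — because cuts are placed between *distinct* sorted
values only, with ties sharing cells — is exactly invariant under
strictly monotone transforms of either variable. A constant input has no
defined dependence and returns 0 with a warning.

Two estimation paths:

* **Exhaustive (n ≤ 25).** At these sizes the budget admits only 2×2
  and 2×3 grids, so all cut placements can be enumerated and the exact
  maximum returned. This also makes the estimator provably equal to the
  brute-force oracle used in the tests for all n ≤ 14. The pure
  approximation cannot guarantee that: it pins one axis to an
  equipartition, which misses the optimal 2×2 grid whenever neither
  optimal cut is at a median.
* **Approximate (n > 25).** The standard scheme: equipartition one axis
  into t rows (never splitting ties), collapse the other axis into
  clumps (points with equal values merged; adjacent clumps confined to
  the same single row merged losslessly; at most `clump_factor ·
  max_columns` superclumps, default factor 5), then dynamic programming
  over clump boundaries minimizes the weighted conditional row entropy
  for every column count — equivalently maximizes mutual information
  since the row entropy is fixed. Both orientations are computed and the
  maximum taken, which also makes the estimate symmetric in its
  arguments by construction.

All logs are base 2. The budget exponent (default 0.6) is exposed as
`b_exponent`.

## Networks and threshold choice

Edges require MIC strictly greater than τ; the strict inequality is
stated so edge counts are reproducible at boundary values. Networks keep
isolated nodes as objects (they remain scoring entities with B = D = 0)
while scan tables count *active* nodes (degree ≥ 1), which is the count
that falls as τ rises. One shared τ applies to intra- and inter-layer
edges.

The threshold scan evaluates a τ grid (default 0.2 / 0.35 / 0.5) per
layer and condition and derives curve Y1 (normal-minus-cancer edge
difference, the between-condition contrast the scoring needs) and Y2
(the smaller of the two conditions' active-node counts, the "richness"
still available). `recommend_threshold` codifies two principles as a
deterministic rule: keep only thresholds losing at most `node_loss_cap`
(default 5%) of each network's active nodes relative to the most
permissive τ scanned, then maximize the total |Y1| over layers, ties to
the smaller τ. Since the most permissive τ loses nothing by definition,
a feasible threshold always exists; the cap-violating fallback (argmax
with a warning) is defensive.

## Score computation

Betweenness is the standard pair-normalized shortest-path estimator with
fractional counting over multiple shortest paths (computed via
networkx); an unnormalized raw-count variant is available through
`normalized=False`, but only relative differences enter the score, so
the choice cancels for most uses. Standardization uses the population
(divide-by-n) standard deviation so small hand-worked examples are
exact; a zero-spread component standardizes to all zeros with a warning
rather than erroring, which also makes "identical networks in both
conditions" yield S = 0 everywhere. The two layers are standardized and
ranked independently. The Jarque–Bera normality check (n/6·(skew² +
(kurt−3)²/4), χ² with 2 df) is run diagnostically on the *signed*
betweenness differences; it gates nothing, but a strong rejection warns
that the standardized differences are dominated by a few outliers.

Score tables report every intermediate (B and D per condition, raw and
standardized differences, the betweenness/degree parts of S, per-layer
rank with ties broken by node id) so each quantity can be audited from
the CSV alone.

## Feature selection

Each layer is reduced independently and the two learners' picks are
merged by union:

* **Random forest.** Filter: per-feature standardized tumor-vs-normal
  mean difference on log1p counts (simple, monotone in separation).
  Wrapper: stratified k-fold CV (default 10-fold, capped at the minority
  class size) of forest classifiers over the top-k sets for each k in
  the grid plus a budget of random subsets from the ranked pool; the
  reported table holds fold-mean accuracy and Cohen's kappa with SDs per
  k. Two selection policies exist: the min-error/fewest-features rule,
  and a pinned `select_k` (the analyst's chosen CV row). The pipeline
  defaults pin k = 20 (miRNA) and 10 (protein) — generous sizes near the
  CV plateau, proportionate to the retained feature counts — because the
  min-error rule can collapse the candidate set to a handful of
  top-separating features and starve the network stage of the
  co-expression structure it is meant to analyze.
* **XGBoost.** Additive tree ensemble with logistic loss; per-iteration
  error rate, log-loss, AUC and RMSE on the training and held-out
  splits; features ranked by gain, top_k kept. The minority class is
  up-sampled to parity *inside the training split only* — up-sampling
  before splitting would leak duplicated samples into evaluation, which
  the permutation-null test guards against. A stratified 25% holdout is
  used for the held-out series (leave-one-out is statistically similar
  here but orders of magnitude slower and yields no per-iteration test
  curves worth the cost at these cohort sizes).

All stochastic stages derive their RNG seed from the single run seed
plus a stage-name hash, so stages are individually reproducible and
runs are deterministic end to end (manifests from replicate runs are
byte-identical).

## Synthetic data

The generator emulates a paired TCGA-style cohort in both on-disk CSV
dialects. Log-expression is baseline + marker shift (δ, tumor samples)
+ module loadings (λ·z with z a per-patient latent factor active in one
condition only) + N(0, σ²) noise, exponentiated — log-normal-like
positive marginals. Zero contamination hits a configurable fraction of
non-planted features to exercise the zero filter. Every patient has a
tumor sample; the first `n_normal` patients also contribute a matched
normal sample, so cross-layer MIC has same-patient pairs per condition.

The reference cohort (`default_spec`): 300 tumor / 30 normal (~10:1,
the imbalance regime of paired breast-cancer cohorts, which exercises
the up-sampling path by default), 60 miRNAs / 25 proteins, δ = 2
markers against σ = 1 noise, one normal-specific miRNA module, one
normal-specific cross-layer module, one weaker tumor-specific module
(so normal networks are denser — the regime the differential scoring
targets), zero_rate 0.25. Module members also carry δ = 1 marker
shifts: differentially co-expressed molecules in real cohorts are
usually also differentially expressed, and without some marginal signal
the selectors would (correctly) discard them and the network stage
would see no planted structure.

What the generator does *not* emulate: count-type mean–variance
relationships, batch effects, miRNA–target biology, missingness, or
correlated noise between non-module features. Passing tests therefore
demonstrate that the pipeline recovers the statistical structure it
assumes — condition-specific dependence plus class-separating shifts —
not that it is robust to every artifact of real TCGA data.

## Problem sizes and numerical choices

Tests and the acceptance script run scaled-down cohorts (tens of
features, 100–330 samples) chosen so the full pipeline, the 20-seed
hub-recovery study and the 20-permutation null band all complete in
minutes on one CPU; the statistical regime (class imbalance, δ/σ,
λ/σ, MIC sample sizes) matches the reference conditions rather than the
raw dimensions of a full TCGA cohort. Degenerate inputs are handled as
stated contracts, not crashes: constant variables (MIC 0, standardized
0), empty zero-filter results (warning + empty matrix), degenerate kappa
marginals (0 with warning), missing values and negative expression
(errors at load). CSV writers use `%.17g` and readers round-trip float
parsing, so write→read is bit-exact.

## Known limitations

* MIC at n ≈ 30 (a 10:1 cohort's normal arm) has a high noise floor;
  normal networks are denser partly for that reason. The scan and the
  per-layer standardization keep the comparison interpretable, but
  edge-count *ratios* between conditions conflate biology with sample
  size, as they do in any hard-thresholded co-expression comparison at
  unequal n.
* The score has no significance calibration; the permutation machinery
  used in the null test is available as a pattern but not wrapped as an
  API.
* The approximation's `clump_factor` trades accuracy for speed on heavily
  tied or very large inputs; the exhaustive path bounds n at 25 by
  design.
* Threshold recommendation implements two stated principles; with very
  coarse τ grids it degenerates to the smallest τ (ties rule), which is
  the conservative choice.
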