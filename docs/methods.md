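# Methods

`templex` estimates directed interactions between brain regions from
discretized resting-state activity and characterizes the resulting networks
as a four-layer multiplex.  This note documents the model, the estimators,
the synthetic ground-truth generator, the numerical choices, and what the
validation experiments do and do not establish.

## From signal to states

Each ROI's time series is z-scored within ROI (population SD, `ddof=0`) and
thresholded into three states: `1` above `+theta`, `-1` below `-theta`, `0`
between, with values exactly at the threshold assigned to `0` (the
"between thresholds" band is read inclusively — a conservative event-calling
convention).  `theta` is a fraction of the SD; the conventional sweep is
0.25, 0.5, 0.75 and 1.0, and the package default is 1.0, where the event
process carries the most information per event.  The chosen threshold is
recorded in every output because downstream numbers are not comparable
across thresholds.

## Local transfer entropy and the interaction rules

For an ordered pair A→B with one-step histories (k = l = 1, matching a
2-second sampling interval where one step is one TR), transfer entropy
decomposes over the 27 combinations c = (A_n, B_n, B_{n+1}):

    T_{A→B} = Σ_c P(c) · ln [ P(B_{n+1} | A_n, B_n) / P(B_{n+1} | B_n) ]

The log-ratio λ_c is the *local* transfer entropy of combination c; its
probability-weighted term t_c = P(c)·max(0, λ_c) is the combination's
contribution, with negative local values (misinformative transfer) set to
zero before aggregation.  All quantities are plug-in estimates from the
empirical triple counts; unseen conditioning events contribute zero (no
pseudo-counts), which keeps the joint normalized and the count conservation
Σ_c N_c = T−1 exact.  Units are nats.

Two totals are exposed and they differ at finite T:

* `total_raw` — the plain plug-in sum Σ P·λ.  Under independence its bias
  is the classic χ²-type term, df/(2T) ≈ 6·10⁻⁴ nats at T = 10⁴, and it is
  the quantity with clean analytic limits (copy channel → ln 3;
  independence → 0).
* `total` — the rectified sum Σ t_c used for edge weights.  Rectification
  can only *increase* the sum; under independence each λ_c is a zero-mean
  fluctuation and the positive parts add ≈ Σ_c P(c)·σ_c/√(2π) ≈ 0.018 nats
  at T = 10⁴.  This bias is intentional and harmless for rule weights
  because every significance decision is made against nulls carrying the
  same bias, but analytic-limit checks must use `total_raw`.

Eight combinations define the four rules, each pairing the two sign-mirrored
transitions of one mechanism: ActS (1,0,1)/(−1,0,−1), TfS (1,−1,0)/(−1,1,0),
ActO (1,0,−1)/(−1,0,1), TfO (1,1,0)/(−1,−1,0).  Rule-layer edge weights sum
the rule's two contributions per ordered pair; diagonals are zero
(self-transfer is outside the rule framework).

## Which combinations carry signal

Significance is decided at the combination level on the cohort-pooled
summary (mean t_c over all ordered pairs and subjects) — pooling is
deliberate: per-edge testing at 105×104 pairs and T ≈ 150 has no power.
The null reshuffles every ROI's sequence independently in time, preserving
marginal state counts exactly while destroying temporal and cross-ROI
structure; each permutation replicate yields one null summary per
combination.

With m = 27 combinations, per-combination Bonferroni on the +1-corrected
permutation p-value needs n_perm ≥ m/α − 1 = 539 replicates before any
decision is possible at α = 0.05; at the conventional 100 replicates the
Bonferroni threshold is unattainable (the implementation logs a warning).
The family-wise decision therefore uses the single-step max-T procedure on
studentized summaries: a combination is significant when its studentized
observed summary exceeds the null distribution of the *maximum* studentized
summary across combinations.  Max-T controls the family-wise error rate
strongly at any number of replicates and is the permutation-native
counterpart of Bonferroni; Bonferroni-corrected p-values are still reported
for reference, as is the mean squared deviation between observed and null
summaries as a descriptive.

Surviving combinations are grouped by average-linkage hierarchical
clustering on correlation distance between their edge-wise contribution
profiles (the vector of t_c over all pairs and subjects), cutting the
dendrogram at the largest gap between consecutive merge heights.  On
planted cohorts this pairs each rule's two sign-mirrored combinations.

## The multiplex analytics

**Density and total weight** are per layer: the fraction of realized
off-diagonal directed links and the sum of weights.

**Null model.**  The network null rewires a layer's directed topology with
degree-preserving edge swaps (10 × link-count proposals; a proposal is
rejected if it would create a self-loop or a duplicate link) and then
reassigns each node's incoming weights as a random permutation of its
original incoming weights.  In-degree, out-degree, per-node in-strength and
total weight are preserved exactly; out-strengths and weight–topology
correlations are randomized.  100 replicates by default.

**Reciprocity.**  The raw index is the reciprocated weight fraction
r = Σ min(w_ij, w_ji)/Σ w_ij; across two layers the numerator pairs w_ij in
one layer with w_ji in the other and the denominator is the mean of the two
layer totals (the cited literature admits several denominators; this choice
makes the cross-layer index symmetric and reduce exactly to r when the two
layers coincide).  Raw values are normalized against the rewiring null with
a two-piece map — (r−⟨r⟩)/(1−⟨r⟩) above the null mean, (r−⟨r⟩)/⟨r⟩ below —
so the printed range [−1, 1] is attainable on both sides; a single-piece
scaling cannot reach −1 when ⟨r⟩ < ½.  A degenerate null mean (0 or 1)
yields nRI = 0 with a warning.

**Triad motifs.**  Subgraphs follow the graphlet convention: no
bidirectional dyads.  Closed triads (3 links): Cycle and Flux — exhaustive
enumeration of the 27 reciprocal-dyad-free 3-node digraphs confirms these
are the only closed classes (2 and 6 labeled configurations) and counts 6
Chain, 3 Source and 3 Sink open configurations.  Intensity for a motif
class and a layer multiset sums, over all decorated instances (node triple +
link directions + layer-per-link assignment, each counted once), the
geometric mean of link weights, with the exponent equal to the link count
(1/3 closed, 1/2 open).  Both the reciprocal-dyad exclusion and the
openness requirement for the missing dyad of open triads operate on the
union of the layers in the assignment.  The fast path evaluates traces and
Hadamard products of element-wise-rooted, cleaned layer matrices (cleaned =
reciprocated dyads zeroed; open motifs use the block matrix of absent
dyads), with combinatorial prefactors 1/3 (Cycle), 1 (Flux, Chain) and 1/2
(Source, Sink) fixed by the requirement that each instance count exactly
once; the brute-force enumerator is kept in the package as the reference
and the two agree to 10⁻⁹ on random instances (this equivalence is the
module's primary test).  Motif order = number of distinct layers − 1, so
open motifs admit orders 0–1 and closed motifs 0–2.  Significance compares
the observed intensity with layer-wise independently randomized networks
(z-score and two-sided +1-corrected permutation p).  The coherence index is
omitted.

**Centrality.**  In-/out-strengths are column/row sums.  Hubs are nodes
*strictly above* the 90th percentile of the strength distribution (linear
interpolation; ties at the cutoff excluded; the percentile is
configurable).  Hubs are classed by layer occurrence: 1 layer local, 2–3
intermediate, all 4 multiplex.

**Modularity.**  The quality function is directed weighted modularity with
the out×in strength null term, optimized by multi-restart Louvain
(networkx's directed implementation; the reported Q is recomputed from the
matrix so it is optimizer-independent; 100 restarts by default, best Q
kept, ties broken by first found under the seed).  A partition is
significant when its Q exceeds the 95th percentile of optimized Q on
strength-preserving randomizations.  Note the exact size of this
percentile rule under exchangeability is slightly above 5% — with n nulls
the interpolated threshold sits near the 95th order statistic, so ≈ 6 of
the n+1 ranks exceed it (0.059 at n = 100) — which is what "non-significant
at ≈ 95%" should be compared against.  Significant modules of at least 4
nodes are re-partitioned recursively on their induced subnetworks while
splits remain significant; nested module labels are reported as dotted
paths ("4.2").  Within-module connectivity is the mean off-diagonal weight
inside a module (undefined for singletons); between-module connectivity is
the mean weight over ordered module pairs; both are computed per subject
per rule on the group-level partition.

**Group statistics.**  Two-sample comparisons use the rank-sum
(Mann–Whitney) test — the signed-rank variant is inapplicable to unpaired
groups — two-sided throughout, exact enumeration for tie-free combined
n ≤ 12 and the tie-corrected normal approximation otherwise, with
Bonferroni correction over the explicitly declared family (recorded in
every output).  All-identical samples give p = 1 by convention.

## The synthetic cohort generator

The generator produces the ground truth every stage is validated against.
Baseline states are i.i.d. per ROI and timepoint with configurable marginal
frequencies (p₊, p₋); an optional first-order persistence parameter makes
sequences more fMRI-like at the cost of the analytic i.i.d. limits, and is
off by default.  A planted rule A→B overrides the target's baseline draw at
n+1 with probability ε (the transfer probability) whenever its precondition
holds at n; both sign-mirrored transitions are always planted together.
Simultaneous firings on one target are resolved by a uniform random choice,
which keeps each rule's conditional probability interpretable.  Continuous
signals are emitted as state × amplitude + Gaussian noise.  Two-group
cohorts shift every planted ε by `effect_delta` in group 2.

Multiplex fixtures draw each unordered dyad independently: linked with
probability 2·density/(1+ρ), reciprocated (both directions, equal weights)
with probability ρ — so link density equals `density` and the
reciprocated-dyad fraction equals ρ exactly in expectation, with ρ = 1
giving a symmetric matrix and ρ = 0 none.  Planted partitions multiply the
within-module link probability by `module_ratio` (default 10) at fixed
overall density.

**What the generator does not emulate:** hemodynamics, autocorrelated
noise, spatial correlation between ROIs, scanner artifacts, and
inter-subject variability in coupling strength.  Passing tests therefore
establish estimator correctness and calibration under the stated model,
not performance on real BOLD data.

### The demonstration cohort and its side channels

The standard demonstration cohort (10 ROIs, T = 150, 20 subjects per
group, ε = 0.6) plants the rules on a single directed ring — each ROI
sources one edge and targets one — because layouts where one node drives
several others create common-driver dependences that leak transfer entropy
into unplanted pairs.  Two properties of the generative model shaped the
design and are worth knowing:

* **Quiescent-source side channel.**  Conditioning on A_n = 0 genuinely
  informs the target — no rule can fire — so combinations such as (0,0,0)
  carry *real* transfer entropy, proportional to the probability mass of
  the non-firing source state.  This is a property of the model, not an
  estimator artifact.
* **Rule-strength asymmetry.**  Per edge, turn-off rules (conditions on
  ±1 states of both nodes) concentrate far more transfer entropy than
  activation rules (condition B_n = 0) when quiescence is rare, and
  vice versa.

The demonstration cohort therefore uses activation-rich marginals
(p₊ = p₋ = 0.45, 10% quiescence), which shrinks the quiescent-source
channels to negligible mass, and allocates four edges each to ActS/ActO
against one each to TfS/TfO so the pooled signal is comparable across
rules.  Under these conditions the max-T test typically recovers exactly
the eight rule combinations (planted studentized summaries ≈ 4–17, side
channels ≈ 1–3, decision threshold ≈ 3.5); across independent replicate
cohorts exact recovery held in roughly three quarters of draws and all
eight planted combinations were recovered in five sixths, the deviations
being single combinations at the decision boundary (one borderline side
channel admitted, or the weakest planted mirror missed).  With
quiescence-heavy marginals the side channels are comparable
to the weaker planted rules and exact recovery is not expected — a caveat
that applies equally to interpreting rule analyses of real data.

## Validation experiments and problem sizes

The `experiments` module runs each study end to end; the acceptance script
reports their numbers and the test suite asserts them.  Sizes were chosen
to give stable estimates on a single CPU in minutes: rule recovery at the
demonstration-cohort conditions with 100 permutations; analytic limits at
T = 10⁴; the motif fast-path/oracle equivalence on 50 random multiplexes
(6–10 nodes, 2–4 layers, all motif types and orders); the reciprocity
sweep over 10 generator levels with 50-replicate nulls; modularity recovery
on 45-node, three-module networks (10:1 within:between) with 100-replicate
nulls, and its type-I error over 40 exchangeable null draws; group-test
calibration over 500 null cohorts and power over 200 cohorts with the TfO
transfer probability raised by 0.3 in group 2 (planted on four edges — a
single-edge effect at these sample sizes is ≈ 0.5 within-group SD and
undetectable by design).  Statistical rates are asserted against one-sided
binomial bands at the 0.5% level around the procedure's exact size, never
against the point value.

## Known limitations

* Only k = l = 1 histories are implemented; longer embeddings are out of
  scope.
* The estimator is plug-in; at T ≈ 150 per-edge weights carry substantial
  small-sample bias, which cancels in group comparisons (both groups share
  T) but makes absolute weights threshold- and length-specific.
* The rewiring null preserves in-strength exactly but not out-strength;
  analytic maximum-entropy reciprocity baselines are not implemented — the
  permutation null replaces them, a comparability caveat when numbers are
  set against ensemble-based reciprocity indices.
* Hierarchical module splitting tests each level at unadjusted 5%, so deep
  recursions accumulate type-I risk; splits below 4 nodes are not
  attempted.
* The pipeline computes group-average-network analyses by default;
  per-subject hub calling and modularity are available through the library
  but consensus clustering across subjects is not implemented.
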