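# Methods

## Problem and model

Most mitochondrial proteins in *Arabidopsis thaliana* are encoded by the
nuclear genome, and no single genome-scale predictor of mitochondrial
localization is both sensitive and specific.  `mitoevidence` integrates many
weak binary predictors into one calibrated score with a naive Bayes
likelihood-ratio model, and then carries the resulting protein catalog into
two downstream analyses: function inference on a protein-interaction network
(PIN) and enrichment testing of stress-responsive subnetworks.

### Evidence integration

Each predictor s_i emits a binary call per protein (1 = mitochondrial).
Against a gold standard of experimentally verified mitochondrial positives
and non-mitochondrial negatives, we estimate per-predictor likelihood ratios

    L1_i = P(call=1 | positive) / P(call=1 | negative)
    L0_i = P(call=0 | positive) / P(call=0 | negative)

with class-conditional frequencies smoothed by a symmetric pseudocount
`alpha` (default 1, Laplace): `P(call=c | class) = (count + alpha) /
(n_class + 2*alpha)`.  With `alpha = 0` a zero cell raises an error rather
than yielding an infinite ratio.  Under conditional independence of the
predictors given the class, evidence combines multiplicatively, so the
integrated score is

    logLR(p) = sum_i log10 L_i(call_i(p)),

and posterior odds = prior odds × 10^logLR.  Log base 10 is used throughout;
the conventional decision thresholds in this problem (1.27 ≈ log10 19 at
prior odds of 1 in 19, and the more conservative 1.37) are stated in base
10.  Classification is strict: a protein is called mitochondrial iff
logLR > threshold.  Missing calls are skipped by default (absence of
evidence contributes nothing); an `as_absent` policy that scores them as
0-calls is available for sensitivity analysis.

Predictor groups can be merged before integration either directly (logical
OR of the group's calls) or indirectly (call = 1 iff at least
`record_threshold` group members call 1).  The core protein set is assembled
as (integrated calls ∪ experimental positives) \ known negatives.

### The N50 coexpression predictor

For each expression dataset and each gene g, the N50 count is the number of
gold-standard mitochondrial genes among g's k = 50 nearest neighbors by
Euclidean distance over the dataset's samples.  Two conventions are fixed
here because the metric's informal description leaves them open: the query
gene is excluded from its own neighbor list (otherwise every gold-standard
gene trivially counts itself), and distance ties break by ascending gene id
so counts are deterministic.  Genes absent from a dataset get a *missing*
count, not zero — expression platforms rarely cover the whole genome.

A binary decision tree over the per-dataset count vectors turns counts into
calls.  We use an entropy-split CART tree (scikit-learn) rather than
reproducing C4.5 bit-for-bit: the classifier is an off-the-shelf component
and the pipeline's claims about it are property-based.  The C4.5-style
pruning-confidence knob maps to cost-complexity pruning as `ccp_alpha =
0.01 * (1 - confidence_factor)` (default confidence 0.25 → ccp_alpha
0.0075; 1.0 disables pruning); `min_leaf` (default 2) is the minimum leaf
size.  Missing counts are fed to the tree as the surrogate value −1, an
impossible count, so the tree can branch on absence; genes missing from
*every* dataset receive a missing call.  Training reports pooled stratified
k-fold (default 10) cross-validated metrics.

### Evaluation

Confusion-matrix metrics follow the standard definitions (accuracy,
sensitivity, specificity, FPR = 1 − specificity, FDR = FP/(TP+FP)).
Internal values are exact proportions; percentages are rounded half-up to
two decimals only at the reporting layer.  Ratios with zero denominators are
reported as undefined, never as zero.  ROC curves sweep the unique score
values with tied scores moving as one block and positives defined by strict
`score > threshold`; AUC is the trapezoid area, which equals the
Mann-Whitney pair statistic with ties counted one half.  Threshold selection
supports maximum accuracy, maximum Youden index (ties broken toward the
larger, more conservative threshold) and an FPR cap (smallest feasible
threshold).  Cross-validation of the integration is stratified by label —
the natural reading of "equally sized parts" that also guarantees both
classes in every fold at realistic class ratios — and re-estimates the
likelihood ratios on each training split.

### PIN-based function inference

Functional similarity of two proteins u, v uses the Czekanowski-Dice
distance over *inclusive* neighborhoods N_u = {u} ∪ adjacent(u):

    S1(u, v) = 1 − |N_u Δ N_v| / (|N_u| + |N_v|) = 2|N_u ∩ N_v| / (|N_u| + |N_v|).

Indirect (level-2) neighbors contribute through transitive similarity:
S2(u, v) = min(1, Σ_w S1(u, w)·S1(w, v)) over shared level-1 neighbors
w ∉ {u, v}.  Summing over intermediates (with a cap at 1) rather than
taking the best single path is a design choice — the transitive-association
family it derives from accumulates evidence over paths — and a max-over-w
variant is provided behind the `transitive="max"` flag for sensitivity
analysis.  Level-2 means shortest-path distance exactly 2, so L1 and L2 are
disjoint by construction.

The score of function x for protein p averages neighbor votes with a
background term:

    FunScore(p, x) = [ λ·r_int·π_x + Σ_{v∈L1} S1(p,v)·δ(v,x)
                       + Σ_{w∈L2} S2(p,w)·δ(w,x) ] / Z,
    Z = λ·r_int + Σ_{v∈L1} S1(p,v) + Σ_{w∈L2} S2(p,w),

with λ = 1, π_x the frequency of x among annotated proteins, and r_int the
fraction of edges whose two (annotated) endpoints share at least one
function; edges with an unannotated endpoint are excluded from both the
numerator and denominator of r_int.  Z is shared across terms for a given
protein, so scores lie in [0, 1]; an isolated protein with r_int = 0 has an
undefined score (NaN).

Candidate pairs pass a preliminary score cutoff (default 0.03, the value at
which known protein-function pairs were recovered in the motivating
analysis).  Significance comes from a permutation null: each of `n_perm`
(default 10,000) permutations reassigns the per-protein annotation *sets*
over the annotated proteins — preserving per-protein annotation counts and
global term frequencies — with the network and similarity weights fixed, and
p = (1 + #{permuted ≥ observed}) / (n_perm + 1).  A pair is significant when
p < 0.05 *and* its observed score passes the cutoff (the two-stage
filtration).  The permutation loop is a single matrix product per
permutation (target-weight matrix × permuted membership matrix), so 10,000
permutations over hundreds of pairs take seconds.

### Stress subnetworks

The stress PIN (SPIN) keeps every interaction with at least one endpoint in
the seed list of stress-responsive genes, together with incident proteins —
the only simple induction rule consistent with a SPIN that contains more
proteins than seeds.  Term overrepresentation in a protein set uses the
hypergeometric upper tail (scipy) with Benjamini-Hochberg correction
(statsmodels) over the tested terms; terms with zero overlap are not tested,
which reduces the correction burden without affecting the tested terms'
p-values.  The universe defaults to all annotated proteins and is
overridable.

## Synthetic data: what it emulates and what it does not

All downstream stages are exercised on generated data whose defaults mirror
the motivating study's conditions: 806 gold-standard positives and 1,464
negatives; fourteen predictors at the published (sensitivity, specificity)
operating points; 24 expression datasets of 43 samples each (≈ the study's
1,027 arrays over 24 datasets).

* **Predictor calls** are Bernoulli draws conditionally independent given
  the label — exactly the naive Bayes assumption — with unknown-label
  proteins behaving as negatives.  An optional `coupling` knob adds a shared
  per-protein logit shift, inducing within-class correlation between
  predictors to probe robustness when the independence assumption is
  violated.
* **Expression** uses one latent factor per dataset: a positive gene is
  √ρ·factor + √(1−ρ)·noise, so any two positives have expected pairwise
  correlation ρ (default 0.8); negatives are pure noise.  This is the
  simplest structure that makes the N50 metric informative.  It does not
  emulate microarray artifacts, probe effects or normalization residue.
* **The PIN** is a planted-partition graph (default 8 modules of 25 at
  within-module edge probability 0.9 over background 0.005), each module
  owning a dominant term that members carry with probability `coherence`
  (default 0.9); a fraction (default 0.1) of proteins is left unannotated.
* A single integer seed drives named `SeedSequence` substreams, so each
  generator is independently reproducible.

Passing tests on these cohorts show that the implementation recovers the
generating model when its assumptions hold (and degrades gracefully under
the coupling knob); they do not certify performance on real proteomes, where
predictors are correlated in structured ways, expression modules overlap and
annotation is biased toward well-studied proteins.

## Numerical choices and degenerate inputs

* Squared-distance ranks in N50 are computed via the Gram expansion with the
  diagonal set to +inf (self-exclusion) and clipped at 0; tie-break is the
  lexicographic rank of the gene id.
* Likelihood ratios must be finite and positive; the estimator enforces this
  at construction and directs the caller to `alpha > 0` on zero cells.
* ROC thresholds include a −inf sentinel so the (1, 1) corner is always on
  the curve; the curve's staircase is non-increasing in both coordinates by
  construction.
* Permutation exceedance uses a 1e-12 tolerance when comparing permuted to
  observed scores so that ties (including the identity assignment) count as
  exceedances — the conservative direction.
* Empty edge-list files, all-zero confusion matrices, single-class training
  sets, and group record thresholds exceeding the group size all raise
  validation errors rather than returning degenerate values.

## Problem sizes used in the test and acceptance runs

The distributed checks run at desk scale, chosen so the full suite completes
in seconds while keeping every estimate's Monte-Carlo error well inside its
assertion band: likelihood-ratio recovery at 10^5 proteins per class,
integration dominance over 50 seeds at the 806/1,464 scale, N50-vs-oracle
equivalence on 100 random 200-gene instances, FunScore recovery on
6-module/120-protein networks, permutation calibration on three independent
200-protein cohorts at 1,000 permutations (the method's default of 10,000 is
used when invoked on real inputs), and exhaustive hypergeometric enumeration
up to universes of 30.

## Known limitations

* The decision tree is CART, not C4.5; trees and hence individual calls can
  differ from a Weka J48 model trained on the same counts, although both
  honor the same leaf-size and pruning-strength semantics.
* The group-merge operations treat a missing call as "no record"; a protein
  missing from every predictor of a group gets a missing merged call.
* `r_int` and π are held fixed during permutation (the permutation preserves
  both marginals that define them, so recomputation would only add noise).
* Writing an `InteractionNetwork` to an edge list drops isolated nodes; the
  catalog is the authority on the node universe.
* The hypergeometric test treats annotations as a flat protein-term map; GO
  graph semantics (term ancestry, propagation) are out of scope — levels are
  input tags used only for filtering.
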